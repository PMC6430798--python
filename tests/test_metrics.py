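"""Resolution metrology: FWHM, correlation curves, spectral support, SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import j1

import specklescope as sp

from conftest import LAMBDA, NA, PX, intensity_stack, optical_config


def test_fwhm_gaussian_closed_form():
    sigma = 7.0
    x = np.arange(201)
    profile = np.exp(-((x - 100.0) ** 2) / (2 * sigma**2))
    expected = 2 * np.sqrt(2 * np.log(2)) * sigma
    assert sp.profile_fwhm(profile, 1.0) == pytest.approx(expected, rel=0.005)


def test_fwhm_triangle_exact():
    w = 20
    x = np.arange(81)
    profile = np.maximum(0.0, 1.0 - np.abs(x - 40) / w)
    assert sp.profile_fwhm(profile, 1.0) == pytest.approx(w, abs=1e-9)


def test_fwhm_airy_oracle():
    # analytic Airy intensity (2 J1(v)/v)^2 sampled finely
    x = np.linspace(-2000, 2000, 4001)  # nm
    v = np.pi * 2 * NA / LAMBDA * np.abs(x) + 1e-12
    profile = (2 * j1(v) / v) ** 2
    fwhm = sp.profile_fwhm(profile, x[1] - x[0])
    assert fwhm / (LAMBDA / NA) == pytest.approx(0.514, rel=0.02)


def test_fwhm_error_conditions():
    with pytest.raises(ValueError, match="boundary"):
        sp.profile_fwhm(np.array([3.0, 2.0, 1.0]), 1.0)
    with pytest.raises(ValueError, match="crossing"):
        sp.profile_fwhm(np.array([0.9, 0.95, 1.0, 0.95, 0.9]), 1.0)


@given(st.floats(min_value=0.01, max_value=100.0),
       st.floats(min_value=-50.0, max_value=50.0))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_fwhm_invariant_under_rescaling_and_offsetless_translation(scale, shift):
    x = np.arange(200.0)
    profile = np.exp(-((x - 100.0 - np.round(shift)) ** 2) / 50.0)
    base = sp.profile_fwhm(np.exp(-((x - 100.0) ** 2) / 50.0), 1.0)
    assert sp.profile_fwhm(scale * profile, 1.0) == pytest.approx(base, abs=1e-9)


def test_bead_corrected_width():
    assert sp.bead_corrected_width(200.0, 0.0) == 200.0
    assert sp.bead_corrected_width(100.0, 100.0) == 0.0
    with pytest.raises(ValueError):
        sp.bead_corrected_width(90.0, 100.0)


@pytest.fixture(scope="module")
def dense_stack():
    # 17 planes over +-2 um: resolves the axial correlation peak
    cfg = optical_config(n=128, nz=17, dz=250.0)
    return cfg, intensity_stack(cfg, seed=6)


def test_correlation_curve_self_peak_and_symmetry(dense_stack):
    cfg, stack = dense_stack
    curve = sp.axial_correlation_curve(stack, cfg.z_planes)
    i0 = np.argmin(np.abs(curve.dz))
    assert curve.peak_value[i0] == pytest.approx(1.0, abs=1e-12)
    sym_err = np.abs(curve.peak_value - curve.peak_value[::-1])
    assert np.median(sym_err) < 0.15  # Monte-Carlo symmetry


def test_correlation_width_matches_axial_grain():
    cfg = optical_config(n=128, nz=17, dz=400.0)
    expected = sp.grain_sizes(cfg)["axial"]
    widths = [sp.axial_correlation_curve(intensity_stack(cfg, s), cfg.z_planes).fwhm
              for s in range(10)]
    assert np.median(widths) == pytest.approx(expected, rel=0.30)


def test_saturation_narrows_correlation_curve(dense_stack):
    cfg, stack = dense_stack
    sat = sp.fluorescence_response(stack, 3.7, cfg.reference_plane)
    lin = sp.axial_correlation_curve(stack, cfg.z_planes).fwhm
    nar = sp.axial_correlation_curve(sat, cfg.z_planes).fwhm
    assert nar < lin


def test_correlation_curve_errors(dense_stack):
    cfg, stack = dense_stack
    with pytest.raises(ValueError, match="two planes"):
        sp.axial_correlation_curve(stack[:1], cfg.z_planes[:1])
    flat = np.ones_like(stack)
    with pytest.raises(ValueError, match="constant"):
        sp.axial_correlation_curve(flat, cfg.z_planes)


def _axial_profile(stack, cfg, s_mean):
    resp = (stack if s_mean == 0
            else sp.fluorescence_response(stack, s_mean, cfg.reference_plane))
    obj = np.zeros(resp.shape)
    obj[cfg.reference_plane, 64, 64] = 1.0
    img = sp.scan_image(obj, resp)
    return sp.axial_response_profile(img, resp)


def test_axial_response_peaks_at_true_plane_with_finite_width(dense_stack):
    cfg, stack = dense_stack
    profile = _axial_profile(stack, cfg, 0.0)
    assert int(np.argmax(profile)) == cfg.reference_plane
    fwhm = sp.profile_fwhm(profile, 250.0)
    assert 0 < fwhm < (len(cfg.z_planes) - 1) * 250.0


def test_saturation_narrows_axial_response(dense_stack):
    cfg, stack = dense_stack
    lin = sp.profile_fwhm(_axial_profile(stack, cfg, 0.0), 250.0)
    sat = sp.profile_fwhm(_axial_profile(stack, cfg, 1.4), 250.0)
    assert lin / sat > 1.0


def test_spectral_support_constant_image():
    assert sp.spectral_support(np.ones((64, 64)), PX) == 0.0


def test_spectral_support_linear_speckle_band_limit():
    cfg = optical_config(n=256, nz=1)
    supports = [sp.spectral_support(intensity_stack(cfg, s)[0], PX) for s in range(5)]
    assert np.median(supports) == pytest.approx(2 * NA / LAMBDA, rel=0.10)


def test_saturation_broadens_spectral_support():
    cfg = optical_config(n=256, nz=1)
    wider = 0
    for seed in range(5):
        plane = intensity_stack(cfg, seed)[0]
        sat = sp.fluorescence_response(plane[None], 3.7, 0)[0]
        if sp.spectral_support(sat, PX) >= sp.spectral_support(plane, PX):
            wider += 1
    assert wider >= 4


def test_reconstruction_snr_exact_and_monotone_in_k():
    grid = sp.GridSpec((5, 64, 64), (1500.0, 130.0, 130.0))
    truth = sp.random_sparse(grid, 4, seed=0, min_separation=1500.0)
    exact = sp.reconstruction_snr(truth.density, truth, 345.0)
    assert exact["background_rms"] == 0.0 and exact["snr"] == 1e12

    cfg = optical_config(n=64, nz=5, dz=1500.0)
    snrs = []
    for k in (4, 16, 64):
        per_seed = []
        for seed in range(3):
            resp = intensity_stack(cfg, seed)
            obj = sp.random_sparse(grid, k, seed=50 + seed, min_separation=500.0)
            est = sp.wiener_stack(sp.scan_image(obj, resp), resp)
            per_seed.append(sp.reconstruction_snr(est, obj, 345.0)["snr"])
        snrs.append(np.median(per_seed))
    assert snrs[0] > snrs[1] > snrs[2]


def test_sparsity_budget():
    assert sp.sparsity_budget(0, (8, 64, 64), m=1)
    n_total = 8 * 64 * 64
    k = 10
    m_min = int(np.ceil(k * np.log(n_total)))
    assert sp.sparsity_budget(k, (8, 64, 64), m_min)
    assert not sp.sparsity_budget(2 * k, (8, 64, 64), m_min)
    assert sp.sparsity_budget(2 * k, (8, 64, 64), 2 * m_min)
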