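"""Resolution and orthogonality metrology.

Quantifies the observables that characterize speckle-based 3D imaging:
FWHM of profiles (with bead-size correction W = sqrt(d^2 + w^2)), the
cross-correlation-peak-versus-defocus curve whose width sets the axial
demixing resolution, the axial Wiener response of an in-focus point
source, the radial extent of the transverse power spectrum (which
saturation enlarges), and reconstruction signal-to-noise against ground
truth.

Correlation curves are mean-subtracted before normalization: under
saturation the response acquires a large DC pedestal that would otherwise
mask the narrowing of the correlation peak.  This mean-subtracted,
normalized peak is the curve definition used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wiener import WienerParams, wiener_plane

__all__ = [
    "CorrelationCurve",
    "profile_fwhm",
    "bead_corrected_width",
    "axial_correlation_curve",
    "axial_response_profile",
    "spectral_support",
    "reconstruction_snr",
    "sparsity_budget",
]

SNR_CAP = 1e12  # sentinel for an exactly clean background


@dataclass(frozen=True)
class CorrelationCurve:
    """Normalized correlation peak versus axial offset; peak at dz=0 is 1."""

    dz: np.ndarray
    peak_value: np.ndarray
    fwhm: float


def _fwhm_xy(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM by linear interpolation of the half-maximum crossings."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise ValueError("profile peak lies at the boundary; FWHM undefined")
    if np.count_nonzero(y == y[i]) > 1:
        raise ValueError("profile has no unique global maximum")
    half = y[i] / 2.0
    left = np.nonzero(y[:i] < half)[0]
    right = np.nonzero(y[i + 1:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("half-maximum crossing missing on one side (truncated peak)")
    l = left[-1]
    xl = x[l] + (x[l + 1] - x[l]) * (half - y[l]) / (y[l + 1] - y[l])
    r = i + 1 + right[0]
    xr = x[r - 1] + (x[r] - x[r - 1]) * (y[r - 1] - half) / (y[r - 1] - y[r])
    return float(xr - xl)


def profile_fwhm(profile: np.ndarray, spacing: float) -> float:
    """FWHM of a 1D sampled profile with uniform sample ``spacing``.

    The profile must have a unique global maximum away from both ends and
    cross half maximum on each side.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    x = np.arange(profile.size) * float(spacing)
    return _fwhm_xy(x, profile)


def bead_corrected_width(measured: float, bead_diameter: float) -> float:
    """Remove the bead size from a measured width: w = sqrt(W^2 - d^2)."""
    if measured < bead_diameter:
        raise ValueError("measured width smaller than the bead diameter")
    return float(np.sqrt(measured**2 - bead_diameter**2))


def _norm_xcorr_peak(ref: np.ndarray, other: np.ndarray) -> float:
    """Max over transverse shifts of the mean-subtracted normalized xcorr."""
    a = ref - ref.mean()
    c = other - other.mean()
    na_, nc = np.linalg.norm(a), np.linalg.norm(c)
    if na_ == 0 or nc == 0:
        raise ValueError("constant plane: correlation undefined")
    corr = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(c))).real
    return float(corr.max() / (na_ * nc))


def axial_correlation_curve(response: np.ndarray, z_planes,
                            reference_plane: int | None = None) -> CorrelationCurve:
    """Cross-correlation peak between the reference plane and every plane.

    For each axial offset, records the maximum over transverse shifts of
    the mean-subtracted, normalized cross-correlation; the value at dz = 0
    is exactly 1.  The FWHM of the peak-versus-dz curve is the axial
    correlation width that saturation shrinks.
    """
    response = np.asarray(response, dtype=float)
    z = np.asarray(z_planes, dtype=float)
    if response.ndim != 3 or response.shape[0] < 2:
        raise ValueError("need a stack with at least two planes")
    if z.shape != (response.shape[0],):
        raise ValueError("z_planes must match the number of stack planes")
    if reference_plane is None:
        reference_plane = int(np.argmin(np.abs(z)))
    ref = response[reference_plane]
    peaks = np.array([_norm_xcorr_peak(ref, response[i])
                      for i in range(response.shape[0])])
    dz = z - z[reference_plane]
    try:
        fwhm = _fwhm_xy(dz, peaks)
    except ValueError:
        fwhm = float("nan")
    return CorrelationCurve(dz=dz, peak_value=peaks, fwhm=fwhm)


def axial_response_profile(image, response: np.ndarray,
                           params: WienerParams = WienerParams()) -> np.ndarray:
    """Peak of the Wiener estimate per plane for an in-focus point-source image.

    Deconvolving the single 2D image against every response plane and
    plotting the per-plane peak is the axial-resolution observable of
    plane-by-plane demixing.
    """
    response = np.asarray(response, dtype=float)
    return np.array([wiener_plane(image, response[z], params).max()
                     for z in range(response.shape[0])])


def spectral_support(plane: np.ndarray, pixel_size: float,
                     floor_fraction: float = 1e-3) -> float:
    """Radial extent (1/nm) of the azimuthally averaged power spectrum.

    Returns the largest radial spatial frequency at which the azimuthal
    average of |FFT|^2 still exceeds ``floor_fraction`` times its
    DC-adjacent value (the first nonzero-radius bin).  A constant image has
    support 0.  The default floor of 1e-3 should be reported alongside
    every support value.
    """
    if not (0 < floor_fraction < 1):
        raise ValueError("floor_fraction must lie in (0, 1)")
    plane = np.asarray(plane, dtype=float)
    ny, nx = plane.shape
    psd = np.abs(np.fft.fft2(plane)) ** 2
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx = np.fft.fftfreq(nx, d=pixel_size)
    rho = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    df = 1.0 / (max(ny, nx) * pixel_size)
    bins = np.round(rho / df).astype(int)
    sums = np.bincount(bins.ravel(), weights=psd.ravel())
    counts = np.bincount(bins.ravel())
    radial = sums / np.maximum(counts, 1)
    if radial.size < 2 or radial[1] == 0:
        return 0.0
    above = np.nonzero(radial[1:] > floor_fraction * radial[1])[0] + 1
    if above.size == 0:
        return 0.0
    return float(above[-1] * df)


def reconstruction_snr(estimate: np.ndarray, truth, grain_transverse: float) -> dict:
    """Peak-to-background SNR of a reconstruction against its ground truth.

    ``peak`` is the mean estimate over true source voxels; the background
    RMS is taken over voxels farther than three transverse grain lengths
    (``grain_transverse``, nm) from every source, where out-of-focus
    speckle residue dominates.  A perfectly clean background reports the
    capped sentinel SNR 1e12.
    """
    est = estimate.density if hasattr(estimate, "density") else np.asarray(estimate, dtype=float)
    sources = [g["position"] for g in truth.ground_truth if "position" in g]
    if not sources:
        raise ValueError("ground truth contains no point sources")
    dz, dy, dx = truth.voxel_size
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in est.shape), indexing="ij")
    mindist = np.full(est.shape, np.inf)
    peak_vals = []
    for p in sources:
        d = np.sqrt(((zz - p[0]) * dz) ** 2 + ((yy - p[1]) * dy) ** 2
                    + ((xx - p[2]) * dx) ** 2)
        np.minimum(mindist, d, out=mindist)
        peak_vals.append(est[int(round(p[0])), int(round(p[1])), int(round(p[2]))])
    peak = float(np.mean(peak_vals))
    bg = est[mindist >= 3.0 * grain_transverse]
    background_rms = float(np.sqrt(np.mean(bg**2))) if bg.size else 0.0
    snr = peak / background_rms if background_rms > 0 else SNR_CAP
    return {"peak": peak, "background_rms": background_rms, "snr": float(min(snr, SNR_CAP))}


def sparsity_budget(k: int, grid_shape, m: int, constant: float = 1.0) -> bool:
    """Compressed-sensing measurement budget M >= constant * K * ln(Nx Ny Nz)."""
    if k < 0 or m <= 0 or constant <= 0:
        raise ValueError("k must be >= 0 and m, constant positive")
    n_total = int(np.prod(np.asarray(grid_shape)))
    if n_total <= 0:
        raise ValueError("grid_shape must be positive")
    return bool(m >= constant * k * np.log(n_total))
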