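"""Plane-by-plane Wiener deconvolution of the single 2D scan image.

Deconvolving the one recorded image against every plane of the 3D response
projects it onto each plane: the statistical orthogonality of speckle
patterns at axial separations beyond ~2 n lambda / NA^2 makes the matched
plane light up while mismatched planes contribute only a 1/sqrt(N) residue
(N speckle grains per plane).  The estimate of plane z is

    O_z = IFT[ B(k) Fhat_z(k) / (|Fhat_z(k)|^2 + noise_psd) ],

whose numerator conjugation matches the correlation forward model, so a
point source reconstructs at its true position.  A single flat (white)
noise spectral density is the only tunable; output is unclipped so the
reconstruction noise stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ScanImage

__all__ = ["WienerParams", "wiener_plane", "wiener_stack", "crosscorr_project"]

DEFAULT_NOISE_FRACTION = 1e-3  # noise_psd = 1e-3 * max |Fhat_z|^2 when unset


@dataclass(frozen=True)
class WienerParams:
    """Flat spectral noise density.  ``None`` selects the documented default
    ``1e-3 * max|Fhat_z|^2`` per plane; 0 (pure inverse filter) requires the
    explicit ``allow_inverse`` flag."""

    noise_psd: float | None = None
    allow_inverse: bool = False

    def __post_init__(self) -> None:
        if self.noise_psd is not None and self.noise_psd < 0:
            raise ValueError("noise_psd must be nonnegative")
        if self.noise_psd == 0 and not self.allow_inverse:
            raise ValueError("noise_psd = 0 requires allow_inverse=True")


def _image_values(image) -> np.ndarray:
    return image.values if isinstance(image, ScanImage) else np.asarray(image, dtype=float)


def wiener_plane(image, response_plane: np.ndarray,
                 params: WienerParams = WienerParams()) -> np.ndarray:
    """Wiener estimate of one object plane from the 2D scan image."""
    b = _image_values(image)
    f = np.asarray(response_plane, dtype=float)
    if b.shape != f.shape:
        raise ValueError("image and response plane grids do not match")
    if not np.any(f):
        raise ValueError("response plane is identically zero")
    fhat = np.fft.fft2(f)
    power = np.abs(fhat) ** 2
    npsd = params.noise_psd
    if npsd is None:
        npsd = DEFAULT_NOISE_FRACTION * power.max()
    return np.fft.ifft2(np.fft.fft2(b) * fhat / (power + npsd)).real


def wiener_stack(image, response: np.ndarray,
                 params: WienerParams = WienerParams()) -> np.ndarray:
    """Stack of independent per-plane Wiener estimates (no cross-plane coupling)."""
    response = np.asarray(response, dtype=float)
    if response.ndim != 3:
        raise ValueError("response must be a 3D (z, y, x) stack")
    return np.stack([wiener_plane(image, response[z], params)
                     for z in range(response.shape[0])])


def crosscorr_project(image, response: np.ndarray) -> np.ndarray:
    """Plain cross-correlation projection of the image on each response plane.

    This is the matched-filtering (noise_psd -> infinity) limit of the
    Wiener stack, normalized by the response-plane energy.
    """
    b = _image_values(image)
    response = np.asarray(response, dtype=float)
    if response.ndim != 3 or b.shape != response.shape[1:]:
        raise ValueError("image and response grids do not match")
    bhat = np.fft.fft2(b)
    out = np.empty_like(response)
    for z in range(response.shape[0]):
        fhat = np.fft.fft2(response[z])
        energy = (response[z] ** 2).sum()
        if energy == 0:
            raise ValueError("response plane is identically zero")
        out[z] = np.fft.ifft2(bhat * fhat).real / energy
    return out
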