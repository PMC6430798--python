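"""Shared spectral forward/adjoint operators for the single-scan imaging model.

The scanned excitation samples the object at r = r0 + u, so the canonical
forward model is a per-plane circular *correlation* of the object with the
response, summed over planes:

    b(r0) = sum_z sum_r O_z(r) F_z(r - r0).

Its adjoint is a per-plane circular convolution with the response.  Both
are computed spectrally (periodic boundary), which keeps the forward
model, Wiener deconvolution and FISTA bit-consistent: one source of truth
for A and A^T.  FFTs here are the plain (unnormalized) numpy transforms;
all identities used elsewhere (Lipschitz constant, flux conservation) are
stated in this convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["response_spectrum", "correlate_forward", "correlate_adjoint"]


def response_spectrum(response: np.ndarray) -> np.ndarray:
    """Per-plane 2D FFT of a (z, y, x) response stack."""
    response = np.asarray(response)
    if response.ndim != 3:
        raise ValueError("response must be a 3D (z, y, x) stack")
    return np.fft.fft2(response, axes=(-2, -1))


def _check_grids(x: np.ndarray, response_fft: np.ndarray) -> None:
    if x.shape != response_fft.shape:
        raise ValueError(
            f"object grid {x.shape} does not match response grid {response_fft.shape}"
        )


def correlate_forward(x: np.ndarray, response_fft: np.ndarray) -> np.ndarray:
    """A x: 2D scan image of an object stack under the response stack."""
    x = np.asarray(x, dtype=float)
    _check_grids(x, response_fft)
    spec = (np.fft.fft2(x, axes=(-2, -1)) * np.conj(response_fft)).sum(axis=0)
    return np.fft.ifft2(spec).real


def correlate_adjoint(r: np.ndarray, response_fft: np.ndarray) -> np.ndarray:
    """A^T r: per-plane circular convolution of a 2D image with the response."""
    r = np.asarray(r, dtype=float)
    if r.shape != response_fft.shape[1:]:
        raise ValueError(
            f"image grid {r.shape} does not match response grid {response_fft.shape[1:]}"
        )
    spec = np.fft.fft2(r)[None, :, :] * response_fft
    return np.fft.ifft2(spec, axes=(-2, -1)).real
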