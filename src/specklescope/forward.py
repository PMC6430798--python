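"""Forward imaging: the single 2D raster scan of a 3D object.

During a 2D scan of a 3D sample with a speckle excitation, each object
plane is probed by a distinct transverse pattern, and the recorded image
is the sum of the per-plane correlations of object and response.  A
diffraction-limited point-scan model (Airy spot, one image per plane) is
provided for comparison, as is Poisson shot noise with constant
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._operators import correlate_forward, response_spectrum
from .optics import OpticalConfig
from .phantoms import Object3D

__all__ = ["ScanImage", "scan_image", "point_scan_image", "apply_noise"]


@dataclass
class ScanImage:
    """2D scan image; the scan step equals the response pixel size."""

    values: np.ndarray
    scan_step: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("scan image must be 2D")


def _density_of(obj) -> np.ndarray:
    return obj.density if isinstance(obj, Object3D) else np.asarray(obj, dtype=float)


def scan_image(obj, response: np.ndarray, scan_step: float = 1.0,
               provenance: dict | None = None) -> ScanImage:
    """b(r0) = sum_z sum_r O_z(r) F_z(r - r0), computed spectrally.

    ``obj`` is an :class:`Object3D` or a raw (z, y, x) stack; ``response``
    is the (linear or saturated) response stack on the same grid.  The
    correlation is circular, consistent with the periodic speckle
    statistics of the simulator.
    """
    density = _density_of(obj)
    values = correlate_forward(density, response_spectrum(response))
    return ScanImage(values=values, scan_step=float(scan_step),
                     provenance=provenance or {})


def airy_psf(config: OpticalConfig) -> np.ndarray:
    """Diffraction-limited focal intensity from a uniform NA disk.

    Returned in FFT layout (peak at [0, 0]) and normalized to unit peak.
    """
    fy, fx = config.frequency_grids()
    disk = (fx**2 + fy**2) <= config.cutoff_frequency**2
    field_ = np.fft.ifft2(np.fft.ifftshift(disk.astype(complex)))
    psf = np.abs(field_) ** 2
    return psf / psf.max()


def point_scan_image(obj, config: OpticalConfig, scan_step: float | None = None) -> np.ndarray:
    """Per-plane convolution with the diffraction-limited spot (one image per z).

    Models 3D point scanning of the same object for resolution comparisons.
    """
    density = _density_of(obj)
    if density.shape[1:] != tuple(config.grid_shape):
        raise ValueError("object transverse grid does not match the optical config")
    psf_spec = np.fft.fft2(airy_psf(config))
    return np.fft.ifft2(np.fft.fft2(density, axes=(-2, -1)) * psf_spec,
                        axes=(-2, -1)).real


def apply_noise(image: ScanImage, photons_at_mean: float, background: float = 0.0,
                seed: int = 0) -> ScanImage:
    """Poisson shot noise with constant background, returned as counts.

    The image is scaled so its mean maps to ``photons_at_mean`` photons;
    a constant ``background`` (counts/pixel) is added before drawing.
    """
    if not (photons_at_mean > 0):
        raise ValueError("photons_at_mean must be positive")
    if background < 0:
        raise ValueError("background must be nonnegative")
    values = image.values
    mean = values.mean()
    scaled = values * (photons_at_mean / mean) if mean > 0 else np.zeros_like(values)
    if np.any(scaled < 0):
        raise ValueError("cannot draw Poisson counts from a negative image")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(scaled + background).astype(float)
    prov = dict(image.provenance)
    prov.update({"photons_at_mean": float(photons_at_mean),
                 "background": float(background), "noise_seed": int(seed)})
    return ScanImage(values=counts, scan_step=image.scan_step, provenance=prov)
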