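"""Fourier-optics simulation of fully developed 3D speckle volumes.

A speckle excitation pattern is modelled as the focal field of a random
pupil: uniform amplitude inside the numerical-aperture disk, independent
phases uniform on [0, 2pi).  Propagation to out-of-focus planes uses the
angular-spectrum method with the exact (non-paraxial) axial wavenumber

    k_z = sqrt((2 pi n / lambda)^2 - |k_perp|^2),

valid here because the NA disk never reaches the evanescent boundary
(NA < n is enforced).  The resulting transverse fields are circular
Gaussian, so the intensity of every plane follows the negative-exponential
(Rayleigh speckle) law rho(I) = exp(-I/<I>)/<I> with unit contrast.

Conventions
-----------
* Stacks are ordered ``(z, y, x)``; z positions are in nanometres relative
  to the focal (reference) plane.
* Pupil arrays live on the spatial-frequency grid with DC at the array
  centre (``fftshift`` layout) for human-readable spectra.
* FFTs use the unitary ("ortho") normalization so that per-plane energy
  equals pupil energy exactly (Parseval).
* Boundary conditions are periodic: the speckle is statistically
  homogeneous over the grid and no finite illumination-spot envelope is
  applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "PupilField",
    "SpeckleVolume",
    "build_pupil",
    "propagate",
    "intensity",
    "check_rayleigh",
    "grain_sizes",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Immutable optical and sampling parameters.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in nm.
    na : float
        Numerical aperture, in (0, 1.7].
    medium_index : float
        Refractive index of the propagation medium, >= 1 and > na.
    pixel_size_xy : float
        Transverse sampling step in nm.  Must satisfy the intensity
        Nyquist bound ``pixel_size_xy <= wavelength / (4 na)`` because the
        intensity spectrum extends to 2 NA / lambda.
    grid_shape : tuple of int
        Transverse grid ``(Ny, Nx)``.
    z_planes : tuple of float
        Strictly increasing axial plane positions in nm (0 = focus).
    """

    wavelength: float
    na: float
    medium_index: float
    pixel_size_xy: float
    grid_shape: tuple[int, int]
    z_planes: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        object.__setattr__(self, "z_planes", tuple(float(z) for z in self.z_planes))
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if not (0 < self.na <= 1.7):
            raise ValueError("na must lie in (0, 1.7]")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        if not (self.na < self.medium_index):
            raise ValueError("na must be smaller than medium_index")
        if len(self.grid_shape) != 2 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be two positive integers")
        nyquist = self.wavelength / (4.0 * self.na)
        if self.pixel_size_xy > nyquist * (1 + 1e-12):
            raise ValueError(
                f"pixel_size_xy={self.pixel_size_xy} nm violates the intensity "
                f"Nyquist bound wavelength/(4 na) = {nyquist:.3f} nm"
            )
        if len(self.z_planes) == 0:
            raise ValueError("z_planes must contain at least one plane")
        if any(b <= a for a, b in zip(self.z_planes, self.z_planes[1:])):
            raise ValueError("z_planes must be strictly increasing")

    @property
    def cutoff_frequency(self) -> float:
        """Coherent cutoff NA/lambda in 1/nm."""
        return self.na / self.wavelength

    @property
    def reference_plane(self) -> int:
        """Index of the plane closest to z = 0."""
        return int(np.argmin(np.abs(np.asarray(self.z_planes))))

    def frequency_grids(self):
        """Centred (fftshift layout) spatial-frequency grids FY, FX in 1/nm."""
        ny, nx = self.grid_shape
        fy = np.fft.fftshift(np.fft.fftfreq(ny, d=self.pixel_size_xy))
        fx = np.fft.fftshift(np.fft.fftfreq(nx, d=self.pixel_size_xy))
        return np.meshgrid(fy, fx, indexing="ij")


@dataclass(frozen=True)
class PupilField:
    """Complex pupil on the centred frequency grid, zero outside the NA disk."""

    config: OpticalConfig
    amplitude_phase: np.ndarray
    seed: int
    iris_fraction: float = 1.0

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.amplitude_phase) ** 2))


@dataclass(frozen=True)
class SpeckleVolume:
    """Complex scalar field stack (z, y, x), one transverse field per plane."""

    config: OpticalConfig
    field: np.ndarray
    z_planes: tuple[float, ...]
    polarization_mode: str = "scalar"
    pupil: PupilField | None = None

    @property
    def reference_plane(self) -> int:
        return int(np.argmin(np.abs(np.asarray(self.z_planes))))


def build_pupil(config: OpticalConfig, seed: int, iris_fraction: float = 1.0) -> PupilField:
    """Draw a fully developed random pupil.

    Uniform unit amplitude inside the (iris-scaled) NA disk, i.i.d. phases
    uniform on [0, 2pi), exactly zero outside.  Deterministic for a fixed
    seed.  ``iris_fraction`` scales the effective NA disk radius, mimicking
    an iris stopped down before the phase modulator.
    """
    if not (0 < iris_fraction <= 1):
        raise ValueError("iris_fraction must lie in (0, 1]")
    fy, fx = config.frequency_grids()
    rho2 = fx**2 + fy**2
    cutoff = iris_fraction * config.cutoff_frequency
    disk = rho2 <= cutoff**2

    # sampling check: at least 8 frequency samples across the disk diameter
    ny, nx = config.grid_shape
    df = 1.0 / (min(ny, nx) * config.pixel_size_xy)
    if 2.0 * cutoff / df < 8:
        raise ValueError(
            "frequency grid too coarse: fewer than 8 samples across the NA disk; "
            "increase the grid size or the pixel size"
        )

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=config.grid_shape)
    pupil = np.where(disk, np.exp(1j * phase), 0.0).astype(np.complex128)
    return PupilField(config=config, amplitude_phase=pupil, seed=int(seed),
                      iris_fraction=float(iris_fraction))


def max_propagation_distance(config: OpticalConfig) -> float:
    """Axial validity window of the periodic angular-spectrum model (nm).

    Beyond ``|z| <= N px / (2 tan(theta_max))`` the steepest plane wave
    walks off laterally by more than half the periodic grid and defocused
    planes alias onto themselves.
    """
    tan_max = config.na / math.sqrt(config.medium_index**2 - config.na**2)
    return min(config.grid_shape) * config.pixel_size_xy / (2.0 * tan_max)


def _kz_grid(config: OpticalConfig) -> np.ndarray:
    fy, fx = config.frequency_grids()
    rho2 = fx**2 + fy**2
    k2 = (config.medium_index / config.wavelength) ** 2 - rho2
    # evanescent components are impossible because na < medium_index
    assert np.all(k2[rho2 <= config.cutoff_frequency**2] > 0)
    return 2.0 * np.pi * np.sqrt(np.maximum(k2, 0.0))


def propagate(pupil: PupilField, z_planes=None, polarization_mode: str = "scalar") -> SpeckleVolume:
    """Angular-spectrum propagation of the pupil to each requested plane.

    The plane at z is the unitary inverse Fourier transform of
    ``pupil * exp(i k_z z)``; z = 0 is the direct inverse transform.
    """
    config = pupil.config
    if z_planes is None:
        z_planes = config.z_planes
    z_planes = tuple(float(z) for z in z_planes)
    zmax = max_propagation_distance(config)
    if any(abs(z) > zmax for z in z_planes):
        raise ValueError(
            f"requested plane outside the validity window |z| <= {zmax:.0f} nm "
            "of the periodic angular-spectrum model"
        )
    if polarization_mode not in ("scalar", "circular_vectorial"):
        raise ValueError("polarization_mode must be 'scalar' or 'circular_vectorial'")
    kz = _kz_grid(config)
    stack = np.empty((len(z_planes), *config.grid_shape), dtype=np.complex128)
    for i, z in enumerate(z_planes):
        kernel = pupil.amplitude_phase * np.exp(1j * kz * z)
        stack[i] = np.fft.ifft2(np.fft.ifftshift(kernel), norm="ortho")
    return SpeckleVolume(config=config, field=stack, z_planes=z_planes,
                         polarization_mode=polarization_mode, pupil=pupil)


def _vectorial_intensity(volume: SpeckleVolume) -> np.ndarray:
    """Intensity |Ex|^2+|Ey|^2+|Ez|^2 for circular input polarization.

    Simplified high-NA model: transverse components carry the pupil with
    sqrt(cos theta) aplanatic apodization and amplitudes (1, i)/sqrt(2);
    the axial component is synthesized with a sin(theta) weight and a unit
    vortex factor exp(i phi_k).  The axial field partially fills the zeros
    of the scalar pattern, as circular polarization does at isotropic
    vortices; this is a qualitative stand-in, not a Richards-Wolf solver.
    """
    config = volume.config
    if volume.pupil is None:
        raise ValueError("vectorial intensity requires the generating pupil")
    fy, fx = config.frequency_grids()
    rho = np.sqrt(fx**2 + fy**2)
    sin_t = np.clip(rho / (config.medium_index / config.wavelength), 0.0, 1.0)
    cos_t = np.sqrt(1.0 - sin_t**2)
    apod = np.sqrt(cos_t)
    phi_k = np.arctan2(fy, fx)
    kz = _kz_grid(config)
    out = np.empty((len(volume.z_planes), *config.grid_shape))
    base = volume.pupil.amplitude_phase
    for i, z in enumerate(volume.z_planes):
        kernel = base * np.exp(1j * kz * z) * apod
        ex = np.fft.ifft2(np.fft.ifftshift(kernel / np.sqrt(2.0)), norm="ortho")
        ey = np.fft.ifft2(np.fft.ifftshift(1j * kernel / np.sqrt(2.0)), norm="ortho")
        ez = np.fft.ifft2(np.fft.ifftshift(kernel * sin_t * np.exp(1j * phi_k)), norm="ortho")
        out[i] = np.abs(ex) ** 2 + np.abs(ey) ** 2 + np.abs(ez) ** 2
    return out


def intensity(volume: SpeckleVolume) -> np.ndarray:
    """Nonnegative intensity stack, normalized to unit mean on the reference plane.

    The reference plane is the one closest to z = 0; its mean intensity
    defines <I> so that downstream saturation levels are expressed relative
    to the illuminating spot at the sample plane.
    """
    if volume.polarization_mode == "circular_vectorial":
        stack = _vectorial_intensity(volume)
    else:
        stack = np.abs(volume.field) ** 2
    ref_mean = stack[volume.reference_plane].mean()
    if not (ref_mean > 0):
        raise ValueError("reference plane has zero mean intensity")
    return stack / ref_mean


def check_rayleigh(plane: np.ndarray) -> dict:
    """First- and second-order statistics of a speckle intensity plane.

    Returns ``contrast`` (std/mean, = 1 for fully developed speckle) and
    ``pdf_distance``, the sup-norm (Kolmogorov) distance between the
    empirical intensity CDF and the exponential law with the same mean.
    The caller is responsible for providing >= ~1e3 independent grains
    (heuristic: grid area / (lambda/2NA)^2).
    """
    plane = np.asarray(plane, dtype=float)
    if np.any(plane < 0):
        raise ValueError("intensity plane must be nonnegative")
    mean = plane.mean()
    if mean == 0:
        raise ValueError("degenerate all-zero plane")
    contrast = float(plane.std() / mean)
    samples = np.sort(plane.ravel())
    n = samples.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    model = 1.0 - np.exp(-samples / mean)
    pdf_distance = float(max(np.max(np.abs(ecdf_hi - model)),
                             np.max(np.abs(ecdf_lo - model))))
    return {"contrast": contrast, "pdf_distance": pdf_distance}


def grain_sizes(config: OpticalConfig) -> dict:
    """Characteristic speckle grain extents (nm).

    transverse = lambda / (2 NA); axial = 2 n lambda / NA^2, the minimal
    axial separation beyond which transverse speckle planes decorrelate.
    """
    return {
        "transverse": config.wavelength / (2.0 * config.na),
        "axial": 2.0 * config.medium_index * config.wavelength / config.na**2,
    }
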