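# Methods

## Model

### Speckle generation

A fully developed 3D speckle is modelled as the focal field of a random
pupil: unit amplitude inside the disk |k⊥| ≤ 2πNA/λ, i.i.d. phases uniform
on [0, 2π), zero outside. Out-of-focus planes are obtained by the
angular-spectrum method with the exact axial wavenumber
k_z = √((2πn/λ)² − |k⊥|²); the non-paraxial form matters at NA 0.77, where
the paraxial approximation visibly distorts axial correlation lengths.
Evanescent components cannot occur because NA < n is enforced at
construction. FFTs are unitary, so per-plane energy equals pupil energy
exactly (Parseval), and the transverse field of every plane is circular
Gaussian, giving the negative-exponential intensity law
ρ(I) = exp(−I/⟨I⟩)/⟨I⟩ with unit contrast.

Boundary conditions are periodic: the speckle is statistically homogeneous
over the grid and no finite illumination-spot envelope is simulated. The
statistical claims tested here (exponential PDF, grain sizes, axial
orthogonality, saturation narrowing) are envelope-independent; an envelope
would only add a parameter. The periodic model is valid for
|z| ≤ N·px/(2 tanθ_max); larger defocus aliases and is rejected with an
error.

Sampling requirements: the transverse pixel must satisfy
px ≤ λ/(4NA) (Nyquist for the intensity spectrum, which extends to 2NA/λ),
and the NA disk must span at least 8 frequency samples.

### Vectorial mode

Circular input polarization suppresses perfect intensity zeros because the
axial field component fills them. The optional `circular_vectorial` mode
synthesizes E_z from the pupil with a sinθ weight and a unit vortex factor
e^(iφ_k), with √cosθ aplanatic apodization on all components. This
reproduces the zero-filling qualitatively but is *not* a Richards–Wolf
vector diffraction solution; scalar mode is the default everywhere and all
quantitative tests run scalar.

### Saturation

The two-level-dye pulse response is used in its short-pulse limit
F = 1 − e^(−s) (τ_p ≪ τ_f); no pulse-shape library is provided because the
analysis throughout relies on this limit. The saturation level of a stack
is set by s_mean relative to the mean intensity of the *reference plane*
(the plane closest to focus), not the volume mean: s is defined over the
illuminating spot at the sample plane, and per-plane normalization would
distort axial comparisons. Whether that average should run over the focal
plane or the full 3D spot is a convention; the reference-plane choice is
ours and is applied consistently.

### Forward model

The scanned excitation samples the object at r = r₀ + u, so the canonical
forward operation is a per-plane circular **correlation** of object and
response, summed over planes. It is computed spectrally with periodic
boundaries, consistent with the speckle statistics; forward model, Wiener
deconvolution and FISTA share one operator implementation, so adjointness
and matched conventions hold to machine precision (bit-consistency across
the pipeline was preferred over edge realism). The scan step equals the
response pixel size; resampling between grids is out of scope.

### Reconstruction

**Wiener.** Each object plane is estimated independently as
Ô_z = IFT[B·F̂_z/(|F̂_z|² + β)] with a single flat noise density β. The
conjugation convention matches the correlation forward model, so a point
source reconstructs at its true position. The default
β = 10⁻³·max|F̂_z|² is stated so results are reproducible (in practice this
parameter is tuned visually); β = 0 (pure inverse filter) requires an
explicit flag. Output is unclipped by default so reconstruction noise
remains visible; clipping is opt-in.

**FISTA.** Solves min_x ‖Ax − b‖² + λ‖x‖₁ (no ½ factor, so the gradient
carries a factor 2 and L = 2σ_max(A)²). Because the periodic correlation
operator is diagonal per spatial frequency, L = 2·max_k Σ_z |F̂_z(k)|² in
closed form; the `auto` step uses 1/L and a power-iteration estimator is
provided as a cross-check. Iteration: Beck–Teboulle momentum from x₀ = 0,
soft threshold θ = step·λ, with a **monotone safeguard**: a step that
increases the objective is rejected and the momentum restarted. Since a
proximal step from a restarted state cannot increase the objective when
step ≤ 1/L, three consecutive significant increases are diagnosed as
divergence (step too large) and raised as an error. The safeguard changes
neither the fixed points nor the accelerated rate; it makes the
non-increasing-objective invariant hold over the full trace. Restarting
alone does not make the trace monotone, which is why the increasing step is
also rejected. Nonnegativity projection (max(v − θ, 0)) is available and
off by default — the objective has no such constraint, but fluorophore
density is physically nonnegative. A grid-search helper selects λ by RMSE
against ground truth for simulation studies only.

Convergence caveat: the Lipschitz constant is dominated by the DC component
of the nonnegative speckle response (|F̂_z(0)|² ∝ N⁴), so the per-spike
amplitude error decays at the accelerated O(L‖x*‖²/k²) rate against a much
smaller restricted curvature. Support is typically recovered within a few
hundred iterations; amplitude accuracy at the percent level needs a few
thousand (measured on 64×64×8: max amplitude error ≈ 0.78 at 500
iterations, ≈ 0.01 at 4000–8000). Plan iteration budgets accordingly.

### Metrology

FWHMs are measured by linear interpolation of the half-maximum crossings
around a unique global peak; truncated peaks raise errors rather than
extrapolate. Correlation curves are **mean-subtracted** before
normalization: saturation adds a large DC pedestal to F that would
otherwise mask the narrowing of the correlation peak. Spectral support is
the largest radius at which the azimuthally averaged power spectrum exceeds
a floor (default 10⁻³, reported with every value) times its DC-adjacent
bin. Reconstruction SNR compares the mean estimate at true source voxels
with the RMS over voxels ≥ 3 transverse grain lengths from every source; an
exactly clean background reports a capped sentinel (10¹²).

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| wavelength | — (532 nm in examples) | vacuum wavelength, nm |
| na / medium_index | — (0.77 / 1.515) | aperture and medium; NA < n required |
| pixel_size_xy | — (130 nm in tests) | must satisfy ≤ λ/(4NA) |
| s_mean | 0 | spot-averaged saturation parameter; 0 = linear |
| Wiener noise_psd | 10⁻³·max|F̂_z|² | flat spectral noise density |
| FISTA step | auto = 1/L | L from the closed-form spectral maximum |
| FISTA λ | 0 | l1 weight; ~10⁻²·‖Aᵀb‖∞ is a practical sparse-recovery scale |
| spectral floor | 10⁻³ | support threshold, reported with the value |

## What the generator does and does not emulate

Emulated: fully developed speckle (exponential PDF, unit contrast), the
axial decorrelation scale 2nλ/NA², pointwise saturation, K-sparse/bead/
layer/filament objects with exact ground truth, Poisson shot noise with
constant background. Not emulated: a finite illumination-spot envelope,
SLM pixelation, scan distortions, index-mismatch aberrations, background
fluorescence from optics or immersion oil, photobleaching, and the full
vector focal field. A green test therefore establishes correctness of the
computational pipeline under ideal homogeneous speckle statistics — not
agreement with any particular instrument, whose aberrations and local
saturation levels can shift the measured narrowing factors substantially
(the axial Wiener-profile narrowing at spot-averaged s = 1.4 is ≈ 1.15 in
this ideal model and only reaches ≈ 2 when the local saturation at the
source plane is ~10, as happens when the speckle is focused on the source).

## Numerical choices

* Frequency grids are fftshift-centred for pupils and human-readable
  spectra; internal transforms use FFT order.
* Stacks are (z, y, x), z in nm relative to the focal plane, 0-based.
* Unitary FFTs in the optics module (energy bookkeeping); plain FFTs in the
  operator module (all identities stated in that convention).
* Beads are density spheres rasterized by 5³ supersampling; by default each
  bead's integrated density equals its amplitude (amplitude-homogeneous
  sparse recovery), with a volume-proportional mode available.
* Filaments are persistent random walks (direction perturbed by a Gaussian
  of scale 0.02 per half-voxel step — smooth at voxel scale, as actin-like
  strands are) rasterized at unit Chebyshev spacing, so the voxel count
  tracks the Chebyshev arc length stored in the ground truth.
* Degenerate inputs (all-zero planes, constant planes, truncated peaks,
  zero response planes) raise errors rather than return silent NaNs.

## Known limitations

* The simplified vectorial mode is a qualitative stand-in; do not use it
  for quantitative vector-field predictions.
* Periodic boundaries mean a bright source near one edge wraps around;
  at the intended use (statistically homogeneous speckle, desk-scale
  grids) this is by design.
* FISTA amplitude convergence is slow on raw nonnegative responses (see
  above); for amplitude-quantitative work run ≥ a few thousand iterations
  or debias on the recovered support.
* The measurement-budget constant in M ≥ C·K·log(N_voxels) is
  instrument- and solver-dependent; the test suite reports the fitted C
  for the simulated regime rather than assuming one.
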