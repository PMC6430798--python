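# specklescope

Simulation and reconstruction toolkit for **compressive 3D super-resolution
microscopy with saturated speckle excitation**.

## The problem

Scanning a sample with a 3D speckle pattern turns a *single 2D raster scan*
into a 3D measurement: speckle patterns in transverse planes separated by
more than the axial grain length δz ≈ 2nλ/NA² are statistically orthogonal,
so each object plane is encoded by its own, nearly independent random
pattern. Saturating the fluorescence excitation (per-pulse response
F(s) = 1 − e^(−s), with s the saturation parameter) flattens the bright
grains while preserving the dark optical-vortex network, which broadens the
optical transfer function and sharpens resolution as

    δx = (λ / 2NA) / √(1 + s),

with the speckle-averaged signal following ⟨F⟩ = ⟨s⟩/(⟨s⟩ + 1).

The package is for microscopists and method developers who want to simulate
this imaging mode end to end, validate reconstruction pipelines against
exact ground truth, or process their own measured response stacks
(multi-page TIFF).

## What it does

* **Speckle optics** — random-pupil, angular-spectrum simulation of fully
  developed 3D speckle volumes with exact exponential intensity statistics
  (`build_pupil`, `propagate`, `intensity`, `check_rayleigh`, `grain_sizes`).
* **Saturation** — pointwise saturated response, the ⟨s⟩/(⟨s⟩+1) signal law,
  saturation-curve fitting, and the RESOLFT resolution bound.
* **Phantoms** — beads, K-sparse point clouds, dense layers and filaments,
  each carrying its exact ground truth.
* **Forward imaging** — the single-2D-scan image b(r₀) = Σ_z Σ_r O_z(r) F_z(r−r₀),
  a diffraction-limited point-scan reference, and Poisson noise.
* **Reconstruction** — plane-by-plane Wiener deconvolution (one tunable
  flat noise PSD) and FISTA for min_x ‖Ax − b‖² + λ‖x‖₁, sharing one
  forward-operator implementation, plus plain cross-correlation projection.
* **Metrology** — FWHM estimation, bead-size correction w = √(W² − d²),
  axial correlation curves, axial Wiener response profiles, spectral
  support, reconstruction SNR, compressed-sensing budget checks.

## Worked example

```python
import numpy as np
import specklescope as sp

cfg = sp.OpticalConfig(wavelength=532.0, na=0.77, medium_index=1.515,
                       pixel_size_xy=130.0, grid_shape=(128, 128),
                       z_planes=tuple(float(z) for z in (np.arange(9) - 4) * 1000.0))
sp.grain_sizes(cfg)
# {'transverse': 345.45, 'axial': 2718.77}   # nm

volume = sp.propagate(sp.build_pupil(cfg, seed=7))
stack = sp.intensity(volume)                  # linear speckle response
sp.check_rayleigh(stack[cfg.reference_plane])
# {'contrast': 0.993, 'pdf_distance': 0.0053} # fully developed speckle

resp = sp.fluorescence_response(stack, s_mean=1.4,
                                reference_plane=cfg.reference_plane)

obj = sp.beads(sp.GridSpec((9, 128, 128), (1000.0, 130.0, 130.0)),
               positions=[(2, 40, 40), (4, 64, 64), (6, 90, 90)])
img = sp.scan_image(obj, resp)                # ONE 2D image of a 3D object

est = sp.wiener_stack(img, resp)              # 3D estimate, plane by plane
# per-plane argmax: (40,40), (64,64), (90,90) — every bead at its true voxel
sp.reconstruction_snr(est, obj, sp.grain_sizes(cfg)["transverse"])["snr"]
# 38.6  (peak vs out-of-focus residue)

lam = 0.02 * np.abs(sp.adjoint_At(img.values, resp)).max()
res = sp.fista(img, resp, sp.FistaParams(lambda_reg=lam, n_iter=2000,
                                         nonnegativity=True))
# res.n_nonzero == 32 (vs 384000 voxels); same three argmax positions,
# out-of-focus background suppressed
```

The grain sizes are the speckle coherence extents (λ/2NA transversely,
2nλ/NA² axially); contrast ≈ 1 and a small CDF distance confirm exponential
(Rayleigh) intensity statistics; the Wiener stack demixes the three beads
from one 2D image because their planes are ~1 µm apart; FISTA returns a
sparse volume with the same support and a much cleaner background.

The same workflow is available from the shell:

```bash
specklescope demo --out demo_run --seed 7
specklescope spsf --config run.yaml --seed 3 --s-mean 1.4 --out resp.tif
specklescope wiener --image scan.tif --response resp.tif --out recon.tif
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the axial-resolution-narrowing observable: it
simulates ten independent 256×256×25-plane speckle responses (NA 0.77,
λ = 532 nm, n = 1.515, 250 nm plane spacing), forms the 2D scan image of an
in-focus point source, Wiener-deconvolves that image against every response
plane for the linear and the ⟨s⟩ = 1.4 saturated response on matched seeds,
and reports the median ratio of the axial FWHMs of the per-plane peak
profiles as JSON.
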