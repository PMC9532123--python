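# helicalct

Simulation and reconstruction toolkit for **multi-source helical
(spiral) CT** with cross-helix z-axis interpolation — the situation faced
when imaging thin, low-contrast structures such as occult knee fractures:
the scanner never measures a complete sinogram in any one transverse
plane, and the slice at bed position `Z_R` must be interpolated from
helical data acquired above and below it before it can be reconstructed.

The package is aimed at people studying CT sampling and interpolation
schemes: it provides every stage of the chain as a tested, seedable
library plus a thin CLI.

## What it implements

* **Geometry** — N X-ray sources on interleaved helices (uniform phases
  φᵢ = 2π(i−1)/N), fixed pitch `z = h·β/2π` or variable pitch
  `z = ∫ h(β) dβ / 2π` from a tabulated bed-speed profile, with exact
  piecewise-quadratic evaluation and inversion; Q-row equiangular fan
  detectors.
* **Analytic phantom** — knee-like ellipsoid arrangements with a
  sub-voxel-thin low-attenuation crack slab ("occult fracture"),
  ground-truth bone/fracture masks, and exact line integrals that double
  as the projector oracle.
* **Projector** — exact fan-beam line integrals G(β, γ, q) along the
  helices, optional Poisson/Beer–Lambert noise.
* **Z-interpolation** (the core) — for each target-plane ray (β, γ), the
  acquired parallel rays are the *direct* partners
  β′ = β + 2kπ − φᵢ (γ′ = γ) and *complementary* partners
  β′ = β + 2γ + (2k−1)π − φᵢ (γ′ = −γ); the nearest candidates above and
  below the plane (over all sources, turns, branches, and detector rows)
  are combined by node-exact linear interpolation,
  `G = w·G_A + (1−w)·G_B`, `w = (Z_R − z_B)/(z_A − z_B)`.
  Both the fixed-pitch global selection and the variable-pitch
  four-family selection are provided; at N = 1 the method reduces to the
  classical single-source half-turn interpolation (180MLI).
* **FBP** — equiangular fan-beam filtered back-projection (cos γ
  pre-weight, band-limited equiangular ramp or Hann kernel, 1/L²
  back-projection over 2π), plus an independent fan→parallel rebinning
  route reconstructed with scikit-image's `iradon` as a cross-check.
* **Volume & MPR** — slice stacking at 0.5–1.0 mm intervals, NIfTI
  output, axial/sagittal/coronal resampling.
* **Metrics** — Dice overlap 2|M∩N|/(|M|+|N|), threshold segmentation,
  and the diagnostic-performance report (sensitivity, specificity,
  PPV/NPV, detection/coincidence/missed/misdiagnosis rates) with a
  Pearson χ² group comparison.

## Worked example

```python
import numpy as np
from helicalct import (FanDetector, HelixGeometry, make_knee_phantom,
                       simulate_projections, build_planar_fan, fan_fbp)
from helicalct.geometry import uniform_phases, TWO_PI

phantom = make_knee_phantom({"jitter": 1.0}, seed=0)
detector = FanDetector.equiangular(65, 0.38, n_rows=2, row_pitch=3.0)
geom = HelixGeometry(rho=300.0, omega=TWO_PI, phases=uniform_phases(2),
                     pitch=12.0, detector=detector)

beta = np.linspace(0, TWO_PI * 5, 5 * 72, endpoint=False)   # 5 turns
sinograms = simulate_projections(phantom, geom, beta)

fan = build_planar_fan(17.3, sinograms, geom, mode="fixed")
print(fan.values.shape, round(fan.beta_R, 4))

w = fan.provenance["weight_above"]
print(round(w.min(), 3), round(w.max(), 3))

slice_img = fan_fbp(fan, (96, 96), (2.0, 2.0))
print(round(slice_img.values.max(), 4))
```

prints

```
(72, 65) 9.0583
0.044 0.989
0.0518
```

i.e. a complete 72-angle × 65-channel fan sinogram interpolated at
Z_R = 17.3 mm (the reference source reaches that plane at β_R ≈ 9.058 rad),
all interpolation weights inside [0, 1] as the method requires, and a
reconstructed slice whose peak attenuation 0.0518 /mm matches the
phantom's bone value (soft tissue 0.02 + bone 0.03 = 0.05 /mm) to within
the filter ringing. The per-bin `provenance` records which source, turn,
branch, and detector row supplied each neighbor.

The same pipeline from the shell:

```bash
helicalct run --config config.yaml --seed 0 --out out/
helicalct evaluate --labels labels.csv --out report.json
```

`run` executes phantom → simulate → reconstruct → evaluate with
content-hash caching and writes a manifest; `evaluate` turns per-case
truth/prediction labels into the diagnostic report and χ² test (for
example, a cohort with tp=48, fn=2, tn=40, fp=10 yields sensitivity 0.96
and specificity 0.80).

## Layout

```
src/helicalct/
  geometry.py   helices, detectors, bed-speed profiles
  phantom.py    analytic phantoms, masks, exact line integrals
  projector.py  helical fan-beam simulation (+ noise)
  zinterp.py    cross-helix z-interpolation (fixed & variable pitch)
  fbp.py        equiangular fan FBP + parallel rebinning route
  volume.py     slice stacking, MPR views
  metrics.py    Dice, segmentation, diagnostic report, chi-squared
  io.py         HDF5 sinograms, NIfTI volumes/masks, previews
  config.py     YAML config, cached pipeline, fixtures
  cli.py        `helicalct` command-line interface
docs/methods.md   model, assumptions, numerical choices, limitations
```
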