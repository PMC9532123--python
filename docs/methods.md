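# Methods

## Problem and scope

Multislice spiral (helical) CT never measures a complete fan-beam sinogram
in any single transverse plane: while the gantry rotates through the
projection angle β, the bed carries the patient along z. Reconstructing the
slice at a chosen bed position `Z_R` therefore requires estimating, for
every fan coordinate (β, γ), the projection value that *would* have been
measured in that plane. This package implements the cross-helix
z-interpolation family of estimators for scanners with N interleaved X-ray
sources, at fixed and variable pitch, followed by standard equiangular
fan-beam filtered back-projection (FBP), plus the simulation and evaluation
machinery needed to study the method end to end: an analytic knee-like
phantom with an "occult fracture" crack, an exact fan-beam forward
projector, slice stacking with multiplanar resampling, and the
segmentation/diagnostic metrics used to score results.

## Scanner model

N sources ride a ring of radius ρ (mm) about the bed axis z, rotating at
angular velocity ω; source *i* starts at phase φ_i (default φ_i =
2π(i−1)/N, the uniform interleave). Writing β = ωt for the shared rotation
angle, source *i* sits at lab angle β + φ_i and bed position

* fixed pitch: z(β) = h·β/2π, with h the bed advance per rotation (mm/rev);
* variable pitch: z(β) = (1/2π) ∫₀^β h(b) db, with h(·) a tabulated speed
  profile integrated by cumulative trapezoid. Because the profile is
  piecewise linear, z is piecewise quadratic and is evaluated and inverted
  exactly (per-segment quadratic solve; ties on zero-speed segments resolve
  to the smallest β). `beta_of_plane` is the right inverse of z to
  better than 1e-6 mm.

Each source carries an equiangular fan detector with Q rows spaced
`row_pitch` mm apart at isocenter, centered on the source plane
(offset_q = (q − (Q+1)/2)·row_pitch). The cone angle is ignored: every row
is an independent in-plane fan at z_source + offset_q. That approximation
is not incidental — it is exactly what makes row data interchangeable with
in-plane data and hence what the z-interpolation method itself assumes.

Ray convention: the ray (i, β, γ, q) starts at the source displaced to row
q's plane and points at in-plane angle θ + π + γ, θ = β + φ_i; positive γ
rotates toward increasing β. This gives the classical opposed-ray identity
(β + 2γ ± π, −γ).

## Cross-helix z-interpolation

For a query ray (β, γ) in the target plane, the acquired rays parallel to
it are, for every source i and integer k:

    direct:        β′ = β + 2kπ − φ_i,              γ′ =  γ
    complementary: β′ = β + 2γ + (2k−1)π − φ_i,     γ′ = −γ

Each candidate's z position is z(β′) + offset_q. Two pipelines select the
bracketing pair:

* **fixed pitch** — the global nearest candidate at-or-above (A) and
  at-or-below (B) the plane over all (i, k, branch, q), then
  `G = w·G_A + (1−w)·G_B` with the node-exact weight
  `w = (Z_R − z_B)/(z_A − z_B)`;
* **variable pitch** — the four (branch × side) families are searched
  separately; per side the closer of the direct and complementary family
  winners is kept, with the direct family preferred on exact ties; the
  naming flips (A is the below neighbor) and the weight
  `w = (z_above − Z_R)/(z_above − z_below)` multiplies A. Both conventions
  are node-exact: the interpolant returns the stored value whenever Z_R
  coincides with a data plane.

Repeating this for β over [β_R, β_R + 2π), β_R the angle at which the
reference source crosses Z_R, yields a complete single-plane fan sinogram.
At N = 1 the machinery reduces to the classic single-source half-turn
multi-slice linear interpolation (180MLI), which the test suite checks
bin-for-bin against an independently coded reference.

**Candidate lookup.** Partner angles are snapped to the nearest stored β
sample; both the value *and* the z position come from that stored ray, so
the selection is a search over physically acquired rays and is verified
against an exhaustive brute-force enumeration. The snap tolerance
`snap_frac` (fraction of a β bin) defaults to 0.5 — every in-range partner
is accepted; below 0.5, out-of-tolerance partners switch to linear
interpolation along β. γ′ = −γ lookups use the mirrored index of the
(symmetric by construction) fan grid; no γ interpolation occurs.

**Tie-breaking.** Exact distance ties resolve by (direct before
complementary, smaller source index, smaller |β′ − β|), identically in both
pipelines. The branch-first order is deliberate: with an even number of
uniformly phased sources, source i's complementary partner and source
i + N/2's direct partner snap to the same stored angle and tie in z at
every bin, and only a shared tie rule keeps the fixed- and variable-pitch
pipelines bin-for-bin identical at constant table speed (a property the
suite asserts).

**Error behaviour.** The estimator is linear interpolation in z, so its
error scales with the bracketing gap. For N = 1, Q = 1 the gap is bounded
by h/2·(1 + 2γ_max/π) plus the snap slack h·Δβ/2π — note the γ-dependent
term; the often-quoted h/2 holds only at γ = 0. The gap (hence the error)
shrinks with smaller pitch, more rows, and more interleaved sources; the
suite measures all three monotonicities against the true stationary-plane
fan computed by the projector.

## Forward projection

Projection values are **exact line integrals** through the analytic
phantom — ellipsoid chords via the quadratic of the unit-sphere transform,
crack-slab chords via interval intersection — not ray marching through a
voxel grid. This makes the projector its own oracle and keeps voxelization
error out of interpolation experiments (a Siddon-style dense-sampling voxel
projector exists separately for voxel-domain checks). The noise model is
monochromatic Beer–Lambert with Poisson counts: counts ~ Poisson(I₀·e^(−p))
clamped to ≥ 1, then p̂ = ln(I₀/counts); draws are ordered source-by-source,
row-by-row from one seeded generator. Tube settings (kV, mAs) have no
monochromatic meaning and are treated as configuration metadata only.

## Reconstruction

Equiangular fan-beam FBP (curved-detector weighting, matching the (β, γ)
parameterization used throughout):

1. pre-weight by D·cos γ (D = ρ);
2. convolve along γ with the discrete equiangular ramp kernel
   g(0) = 1/(8Δγ²), g(odd·Δγ) = −1/(2(π sin(nΔγ))²), g(even) = 0 — the
   band-limited ramp with the (γ/sin γ)² modification;
3. back-project over the full turn with 1/L² weighting (L the
   source-to-pixel distance) and linear interpolation in γ.

Short-scan weighting is not implemented — the interpolated fan spans a full
2π by construction. The Hann option multiplies the kernel's frequency
response by 0.5(1 + cos 2πf), applied exactly as the 3-tap [¼, ½, ¼]
spatial smoothing of the ramp kernel; on noisy data it never increases RMSE
relative to the pure ramp (asserted on the noisy disk phantom).

An independent reconstruction route rebins the fan to parallel coordinates
(θ = β + γ, s = ρ sin γ, bilinear resampling) and applies the standard
parallel-beam FBP (scikit-image's `iradon`). The two routes agree within a
few percent RMSE on the calibration disk and guard each other against
scaling and geometry errors; on the uniform disk (r = 40 mm, μ = 0.02/mm)
the fan route recovers the interior attenuation to well under 1%.

Volumes are stacks of independently reconstructed planes (default slice
interval 0.5 mm, within the 0.5–1.0 mm thin-reconstruction regime this
models); independence makes the stack order-invariant and bit-reproducible.
"Slice thickness" beyond the interval is realized as z-averaging of
round(thickness/interval) sub-planes; the default is no averaging.
Multiplanar views are trilinear resamplings of the stacked volume.

## Phantom

The test object is a knee-like arrangement of ellipsoids: a soft-tissue
envelope (μ = 0.02/mm), femoral/tibial condyle and patella "bone"
ellipsoids (+0.03/mm), loosely matching soft tissue and cortical bone at
diagnostic energies, inside a 110 mm bounding radius. The occult fracture
is a slab of thickness 0.3 mm (below the 0.75–1.5 mm slice-thickness
regime, hence "occult" at coarse sampling) and attenuation deficit
−0.03/mm, clipped to the union of the bone ellipsoids so the total
attenuation stays non-negative; crack chords through overlapping bones are
counted once via inclusion–exclusion. Ground-truth bone and fracture masks
are derived analytically on any voxel grid. A single integer seed drives
optional center jitter (three N(0, jitter²) draws per ellipsoid, in listed
order). World frame: z is the bed axis, x–y the gantry plane, right-handed;
the voxel `origin` is the world coordinate of the *center* of voxel
(0, 0, 0), axis order (x, y, z).

What the phantom does **not** model: anatomical shape realism, trabecular
texture, beam hardening, scatter, detector blur, patient motion. Passing
tests therefore demonstrate the correctness and convergence of the
geometry, interpolation, and reconstruction chain — not clinical
performance on real knees.

## Evaluation metrics

Dice(M, N) = 2|M∩N|/(|M|+|N|); 0 for disjoint, 1 for identical masks. The
0/0 empty-vs-empty case is defined as 1 (two empty segmentations agree).
Threshold segmentation (values ≥ t) produces candidate masks.

The diagnostic report computes detection rate, sensitivity, specificity,
PPV, NPV, coincidence rate, and missed/misdiagnosis rates from a 2×2
confusion table. The missed and misdiagnosis rates follow the clinical
formula sheet this package targets, with *both* divided by
(true negatives + false positives); this is unconventional — the missed
rate is then not a true proportion and can exceed 1 when fn > tn + fp — but
it is reproduced exactly as defined, with the textbook rates (fn/(fn+tp),
fp/(fp+tn)) available behind `conventional=True`. Zero denominators yield
flagged `None` entries, never NaNs. Group comparison uses the hand-computed
Pearson χ² (1 df, optional Yates correction), with the p-value from the χ²
distribution; it is cross-checked against `scipy.stats.chi2_contingency`.

Wall-clock "efficiency" is logged per pipeline stage at INFO level for
information only; it is hardware-dependent and never a test criterion.

## Numerical and design choices

* Selection tolerance for side membership: 1e-9 mm; a candidate exactly on
  the plane is the winner on both sides and the interpolant returns it
  (degenerate z_A = z_B = Z_R).
* Default k-window: ±2 turns around the query angle.
* Weight of the above neighbor is clipped to [0, 1] after the division as a
  float-round-off guard; the tests assert the pre-clip invariant holds.
* The commensurate-grid configurations used by the exactness tests set
  Δγ = Δβ/2 so that complementary partner angles land exactly on stored
  samples; generic configurations exercise the snapped path.
* Problem sizes in tests and the acceptance script (36–360 angles/turn,
  17–181 fan channels, Q ≤ 4, N ≤ 3, 48²–256² grids) were chosen as the
  smallest sizes at which each property is cleanly measurable.
* Stage caching in the pipeline keys each stage by the SHA-256 of its own
  config plus upstream hashes; the global seed fans out to per-stage child
  seeds by a fixed hash derivation, so re-running a config reuses every
  cache and changing the seed invalidates exactly the seed-dependent
  stages.

## Known limitations

* No exact cone-beam (Katsevich-type) reconstruction; the row-as-fan
  approximation breaks down at large cone angles.
* No polychromatic spectra, scatter, or detector response; the Poisson
  model is the only physical noise source.
* The variable-pitch path requires a non-negative speed profile (no bed
  reversal) and data coverage on both sides of every reconstruction plane;
  one-sided coverage raises a descriptive error rather than extrapolating.
* Comparative claims about other segmentation algorithms are out of scope;
  the built-in threshold segmenter exists to exercise the Dice/diagnostic
  layer, not as a competitive method.
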