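# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `fetalatlas`, at the level of detail a maintainer
or reviewer needs to judge what the tests do and do not establish.

## Phantom cohort model

The generator emulates the *structure* of a multi-site fetal neurosonography
study — not acoustic physics.  Each phantom is built on a `grid_size`³ grid
(default 64, isotropic 0.6 mm) from:

- **Brain envelope.** An ellipsoid with semi-axes `(0.42, 0.36, 0.32)·G/2`
  at 31 weeks, scaled by the cube root of a quadratic volume trajectory
  `TBV(ga) ∝ (ga − 7.54)²`.  The 7.54-week offset is the unique quadratic
  root placement giving a 13.19-fold volume increase from 14 to 31 weeks
  (317.60/24.08); absolute units are deliberately uncalibrated because the
  printed volume means are consistent with cm³ rather than their nominal
  mm³, so only the ratio is trustworthy.
- **Cortical folding.** The surface is perturbed by
  `A·sin(6θ)cos(4φ)` in normalised radius; the amplitude is 0 through 16
  weeks and grows linearly to 1.5 voxels (at 64³ scale) by week 31,
  mimicking second-trimester folding onset.  A 2-voxel outer band of the
  folded surface is labelled cortical plate (CoP).
- **Choroid plexus.** A same-shaped ellipsoid scaled by `f(ga)^{1/3}` so its
  analytic volume share of the brain is exactly
  `f(ga) = 0.083·(0.004/0.083)^{(ga−14)/16}` — an exponential regression
  anchored at 8.3% of TBV at 14 weeks and 0.4% at 30 weeks, monotonically
  non-increasing.
- **Cerebellum.** A sphere of radius 0.22·(mean semi-axis) in the
  inferior-posterior quadrant.
- **Laminar parenchyma.** Brain-label intensities are modulated by
  `1 + 0.18·cos(7πρ)` in normalised radius.  Real parenchyma is organised in
  concentric transient zones (ventricular, intermediate, subplate); the
  modulation gives registration interior structure to track, without which
  an interior deformation is invisible in principle (a uniform region warped
  onto itself produces no intensity residual).
- **Speckle.** Multiplicative unit-mean noise
  `1 + noise_level·(S − 1)` where `S` is the normalised squared magnitude of
  a σ = 1.2-voxel-smoothed complex Gaussian field; `noise_level = 0.3` by
  default (1.0 would be fully developed speckle).  Ultrasound speckle is
  multiplicative; the exact law is an emulation choice.
- **Cohort structure.** Per week, `n` left-visible and `n` right-visible
  scans; eight sites assigned round-robin then shuffled; per-subject
  lognormal size jitter (s.d. 4%) and a smooth random diffeomorphic warp
  (max 1.5 voxels, σ = 4 smoothing, cosine-apodised to vanish at the
  boundary).  Site effects are linear size shifts.  Every parameter is
  written to a JSON sidecar so recovery tests read, never re-derive, the
  truth.

**Injected asymmetry.**  `inject_asymmetry` applies a radial map that is an
exact uniform scaling by `(1 + d)` inside a core ball, decays to identity
across a cosine taper (width `max(3, 0.8·r_core)` voxels), and is refused if
its support reaches the volume boundary.  Monotonicity of the radial profile
(hence diffeomorphism) holds for `d > −0.3`, which is enforced.  The default
region is a ball of radius 0.4·(mean semi-axis) abutting the cortical shell
from inside — placed against high-contrast boundaries deliberately, since a
deep textureless region would make the detection task ill-posed rather than
hard.

What the phantoms do **not** emulate: shadows, reverberation, attenuation,
probe-dependent resolution anisotropy, true gyral geometry, or
inter-subject topology differences.  Tests passing on phantoms therefore
establish the correctness of the *pipeline machinery* (registration,
morphometry, inference) under known ground truth, not clinical performance.

## Preprocessing

- Resampling: trilinear to 0.6 mm isotropic; field of view preserved to one
  voxel.  Cropping: 160³ about the brain centre, zero-padded.
- Rigid alignment: closed-form Umeyama/Procrustes similarity fit (3
  translations, 3 rotations, 1 scale) on ≥3 labelled midsagittal landmarks;
  collinear configurations are rejected by a rank test.  The generator emits
  synthetic corpus-callosum/CSP landmarks; a TSV format is supported for
  manually placed ones.
- Histogram matching: quantile mapping at 256 levels, estimated and applied
  within brain masks; a constant reference degenerates to the identity.
- Edge maps: 3D monogenic signal per scale — isotropic log-Gabor bandpass
  (centre wavelength λ·grid-extent voxels, σ/f₀ = 0.55, a standard
  two-octave bandwidth) and its Riesz transform.  Feature asymmetry is the
  rectified `(|odd| − |even| − T)/(energy + ε·mean(energy))` averaged over
  the three scales, with noise floor `T = 2·median(|odd|)`.  The `ε` term is
  scaled by mean energy so the map is exactly invariant to positive affine
  intensity changes.  Computation is fully 3D (slice-wise 2D was the main
  alternative; 3D is chosen because fissure surfaces are 3D structures).
- Hemisphere handling: after alignment the midsagittal plane is the central
  axis-0 plane (axis 0 = left→right); selection keeps the visible hemisphere
  plus a 10-voxel margin past the midline; mirroring reverses axis 0.

## Registration

Symmetric-forces demons in the log domain.  Per iteration: per-channel
update `δ = diff·J/(|J|² + diff²/max_step²)` with `J` the mean of fixed and
warped-moving gradients, weighted-summed over channels (intensity and edge
map, equal weights by default), fluid-smoothed (σ = 2.0 voxels), composed
into the stationary velocity at first BCH order (`v ← v + δ`), then
diffusion-smoothed (σ = 1.0).  Three-level pyramid, (100, 50, 25)
iterations fine→coarse by default; phantom-scale experiments use the
lighter `(10, 20, 40) × 3-level` schedule exposed in
`experiments.fast_demons_params` — phantoms are smooth and converge in far
fewer iterations.  Divergence (>10% rise of the channel MSE at the finest
level) aborts with diagnostics.

Exponentiation is scaling-and-squaring with the scaled step capped at 0.125
voxels (inside the demons loop a 0.5-voxel cap is used for speed; the
returned field is re-exponentiated at full accuracy).  The tighter default
keeps the one-step Euler error below interpolation error: at the 0.5-voxel
cap the `exp(v)∘exp(−v)` residual for a 2-voxel smooth field is ~0.18
voxels; at 0.125 it is under 0.1.  Field composition interpolates trilinearly
with edge clamping; inversion is fixed-point iteration to a 0.05-voxel
residual with failure reported, not silenced.

Groupwise atlasing starts from the voxel-wise mean, registers every scan to
the current template, subtracts the mean velocity from each scan's velocity
(debiasing — this is what makes the procedure template-free: the average
deformation is pinned to zero rather than to any reference anatomy), warps,
re-averages, and stops when the RMS template change falls below 1e−3 of the
intensity range (max 10 outer iterations; recovery experiments use 3).
Velocities warm-start from the previous outer iteration.

Affine size normalisation is moments-based: `A = C_t^{1/2} C_s^{-1/2}` with
symmetric square roots matches mask centroids and second moments in closed
form without introducing spurious rotation for near-aligned brains; the
isotropic scale `det(A)^{1/3}` is recorded separately so size can be
excluded from shape analyses.  An intensity-based refinement stage was
considered and dropped: on masked phantoms the moment fit recovers known
scalings within 2%, which is the accuracy the downstream analyses need.

## Morphometry and inference

Jacobians use central differences of `x + u(x)` (one-sided at boundary
faces; masks should be eroded by one voxel before statistics).  Determinants
are clamped at 1e−6 before the log.  All fields map template→scan, so a
structure larger in the scan than the template has determinant > 1; the JD
convention (`mean(J^a) − mean(J^b)`) therefore makes week-b expansion
*negative*, which the JDMap metadata records.

Before the GLM, log-Jacobian maps are Gaussian-smoothed at σ = 1.5 voxels —
standard tensor-based-morphometry practice that matches the statistic's
spatial scale to the registration's effective resolution.

TFCE integrates `e(h)^E h^H dh` (E = 0.5, H = 2.0, 26-connectivity,
dh = max/100 — the method's canonical defaults) over thresholds.  The
implementation processes thresholds descending with an incremental
union-find whose per-node offsets keep late-joining voxels from inheriting
earlier contributions; it is exact (equal to brute-force threshold
summation to machine precision) and runs in ~4 ms at 24³.  Two-tailed maps
enhance the positive and negative parts separately and re-sign.

Permutation inference is Freedman–Lane: fit the reduced model (intercept +
residualised covariate), permute residuals by group-label exchange, refit,
TFCE the |t| map, record the maximum.  When the number of distinct group
assignments is ≤ `n_perm` the enumeration is exhaustive and p-values are
exact fractions; otherwise `p = (1 + #{max* ≥ obs})/(1 + n_perm)`.  The
observed maps are routed through the same fitted-plus-residual
reconstruction as the surrogates so the identity rearrangement is bitwise
identical and `p ≥ 1/n_perm` holds exactly.  Group-label exchange (rather
than sign-flipping of paired differences) is used; the left/right groups
are independent samples here, not pairs.

PCA shape models are plain mean-centred SVD over flattened fields, with
components below 1e−12 relative variance dropped.  `size_corrected` is
metadata recording that affine scale was removed upstream.

## Cohort statistics

- SSD uses the sample s.d. of all values pooled across sites and ages; a
  quadratic-GA residualisation variant covers the "adjusted for gestational
  age" reading.  Note a construction subtlety used by the tests: shifting
  one of eight equal sites by δ pooled-s.d. yields an *expected* SSD of
  `δ·(7/8)/√(1 + 7δ²/64)`, not δ, because the site contributes to the
  pooled mean and s.d. itself.
- Variance components use the one-way ANOVA moment estimator with the
  unbalanced-design `n₀`; negative between-site estimates are clamped to
  zero and flagged.  REML was the alternative; the moment estimator is
  closed-form, unbiased before clamping, and sufficient for a variance
  *fraction*.  With eight sites the estimate has 7 degrees of freedom and is
  intrinsically noisy (null 95th percentile ≈ 0.025 at n = 50/site), so
  recovery is validated on means over replicates, not per replicate.
- White's LM test regresses squared residuals on {x, x²} (n·R², χ²₂),
  delegated to statsmodels; a perfect first-stage fit returns statistic 0.
- Growth fits: OLS linear/quadratic with a nested F comparison, and a
  least-squares cubic B-spline (interior knots at GA quartiles) standing in
  for a Gaussian additive model; with exact polynomial data the F
  comparison degenerates to ∞/0 and is handled explicitly.

## Volumetry

Volumes are voxel counts × spacing³.  Surface areas mesh the binary mask
with marching cubes after 2-voxel padding and a σ = 0.5-voxel Gaussian:
raw binary marching cubes overestimates curved-surface areas by ~8%
(staircase bias) while heavier smoothing erodes genuine edges; σ = 0.5
keeps both a digitised sphere and an axis-aligned cube within 5% of closed
form.  TBV counts all foreground labels; CoPA is the mesh area of the CoP
shell.

## Pipeline and determinism

`PipelineConfig` defaults encode the study design (0.6 mm, 160³, 10-voxel
margin, ≥10 scans/week/hemisphere, 5000 permutations, α = 0.05, weeks
14–31) and round-trip losslessly through YAML.  All randomness flows from
explicit seeds; re-running a configuration reproduces every output volume
and table to 1e−10.  Per-week failures are isolated and logged, and weeks
below the scan minimum are skipped with a warning.

The package is operated from Python: the library functions plus the
`examples/` scripts are the interface, and a thin shell wrapper would add a
second surface to maintain without adding capability.

## Problem sizes used in validation

Chosen so the full suite runs on one CPU comfortably within half an hour:
Jacobian oracle at 64³; TFCE oracle on 20 random 16³ maps; exact
enumeration at 4-vs-4 (70 rearrangements); FWER calibration with 100
replicates of 10+10 maps at 24³ and 500 permutations; template recovery
from 8 warps at 48³; asymmetry recovery at the study's 10+10 per-week size
(48³, 300 permutations) with nulls at 32³/6+6 over 10 seeds; variance
recovery over 200 replicates of 8×50; the determinism demo at 2 weeks ×
2+2 scans × 32³ with a light demons schedule.

## Known limitations

- First-order BCH composition in the demons loop slightly biases long
  velocity updates; acceptable at the ≤2-voxel updates used here.
- Registration recovers deformation only where image structure exists; the
  recovered log-Jacobian amplitude of the injected 15% dilation is ~45% of
  truth at 48³, which is why inference, not raw amplitude, is the tested
  contract.
- The moments-based affine has no intensity refinement; badly mis-masked
  real data would need one.
- Histogram matching assumes monotone intensity relations; it cannot fix
  shadowing artefacts (excluded from scope).
- The phantom parcellation used for cluster tables is synthetic; regional
  percentages on real anatomy require a real parcellation.
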