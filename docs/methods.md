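# Methods

## Signal model and phantom

The synthetic generator emulates a clinical single-shell acquisition: voxel
size 2×2×2 mm, one unweighted (b=0) volume and 32 diffusion directions at
b = 1000 s/mm², with directions placed on a golden-spiral hemisphere (an
even-order spherical-harmonic design matrix built from them has condition
number ≈ 2.6 at L_max = 6). Each fiber population is an axially symmetric
tensor, so a voxel with populations (dᵢ, fᵢ) has

S(g) = S0 · Σᵢ fᵢ · exp(−b·(λ⊥ + (λ∥−λ⊥)(g·dᵢ)²)),

with white-matter-like defaults λ∥ = 1.7·10⁻³ mm²/s, λ⊥ = 0.2·10⁻³ mm²/s.
Fiber-free voxels are isotropic with d = 2.0·10⁻³ mm²/s (CSF/edema-like).
Noise, when enabled, is Rician: |S + n₁ + i·n₂| with n₁, n₂ ~ N(0, σ),
σ = S0/SNR; the noise-free default keeps the structural acceptance properties
exact while SNR 30 is used for the noisy model-recovery checks.

### Geometry

Two mirror-image trunk-plus-branch systems, one per hemisphere, share one
transverse seed slice (as when seeding the corticospinal tract once in the
brain stem). Each trunk is a set of parallel voxel columns rising along +z.
The centre column continues straight to the trunk apex; every side column
ends at the branch level, where a straight branch leaves it at a prescribed
angle in the coronal plane (defaults: 70° lateral and 40° medial per
hemisphere, mirrored). Branch lengths are solved so all endpoints — and the
apex — lie exactly on a circular arc about the trunk centre at the branch
level; the "motor" mask is a one-voxel-thick shell on that arc (spanning the
fan plus a 10° margin), and doubles as the tracking target and ROI, as the
motor-cortex mask does clinically. Branches are rasterized at quarter-voxel
steps with an in-plane half-width of 0.6 voxels: a one-voxel-thick 70° chain
would lose any pathway running parallel to, but slightly off, its axis, which
is a rasterization artefact rather than tractography behaviour. Voxels
crossed by two populations carry both directions with occupancy-proportional
volume fractions.

This construction deliberately produces both behaviours the method
comparison needs: pathways seeded under the centre column reach the target
straight through (so single-direction trackers return a non-empty bundle),
while pathways under the side columns stall at the branch level — their
points are exactly where unused branch peaks wait to be harvested. What the
phantom does **not** emulate: curvature, kissing/fanning-within-voxel
configurations, partial voluming against grey matter, susceptibility or
motion artefacts, or tumor mass effect. Passing tests demonstrate
algorithmic correctness, not clinical performance.

## Tensor model

Ordinary least squares on the log signal, ln(S/S0) = −b·gᵀDg, with S0 the
mean of the b0 volumes and signals floored at a small positive value before
the log. OLS (rather than WLS/robust variants) is the deterministic baseline
choice. FA uses the standard eigenvalue formula, clamped to [0,1]; negative
eigenvalues from noise are admitted. The principal direction is the
eigenvector of the algebraically largest eigenvalue; all consumers treat ±e
as equivalent.

## FOD estimation

Real, symmetric, even-order spherical harmonics with descoteaux-style
ordering (l = 0,2,…,L_max; m = −l…l), L_max = 6 → 28 coefficients.
Spherical convolution with an axially symmetric kernel multiplies each
degree-l coefficient by √(4π/(2l+1))·r_l, where r_l are the kernel's zonal
coefficients.

**Recursive response calibration.** Start from a nearly isotropic tensor
response (FA ≈ 0.1; λ = 0.78/0.66·10⁻³ mm²/s). Iterate: deconvolve all
candidate voxels, keep those whose second/first peak amplitude ratio is
< 0.1, refit the zonal profile of each survivor's signal aligned to its
principal peak, and average. Stop when the selected set repeats (cycle
detection over all previous sets) or after 10 iterations. On phantom data
the calibrated response matches the true single-fiber profile to < 0.2%
relative RMS.

**Constrained deconvolution.** Per voxel, the S0-normalized DWI signal is
deconvolved by least squares with iterative soft non-negativity: amplitudes
on a fixed 300-direction constraint sphere below τ = 0.1 × the initial FOD's
mean amplitude are penalized with weight λ = 1, re-identifying the active
set until it stabilizes (cap 50 iterations; voxels that fail to stabilize
are zeroed and excluded from tracking). The initial estimate truncates the
basis at l ≤ 4. Soft penalization necessarily leaves small negative lobes:
with ~150 active constraints against 28 coefficients, forcing amplitudes to
zero annihilates the FOD, so the enforced invariant is min amplitude
≥ −5% of the peak (measured ≈ −3% on a 90° crossing).

**Peak extraction.** Initial search over a 724-direction hemisphere lattice
(the basis is antipodally symmetric, so one representative per axis),
greedy selection with ≥ 25° separation, then 10 iterations of projected
finite-difference ascent on the SH expansion with per-candidate step halving.
At most 3 peaks, amplitude threshold 0.08 (absolute, matching the emulated
protocol). Against an exhaustive 10242-direction search the refined top peak
agrees to well under 1°.

## Tracking

Fixed-step Euler, step = half the smallest voxel dimension; bidirectional
from plain seeds (±largest peak, halves joined), unidirectional from branch
seeds. Tensor components / SH coefficients are interpolated trilinearly
(zero outside the volume, so fields fade at the mask edge) and the model
quantity is recomputed at the interpolated point. Termination: mask exit
(points outside the tracking mask are never appended), FA < 0.1 (tensor),
no peak ≥ 0.08 (FOD), angular deviation > 45°, or a 250 mm length guard.
Seeds: 5 per voxel, uniform in-plane within each voxel of the single-slice
seed mask with the through-plane coordinate fixed to the voxel-centre plane;
the through-plane axis is the constant-index axis most aligned with the
world superior direction. ROI filtering for the baseline trackers keeps
streamlines with ≥ 1 point in the ROI (any-point semantics, also used as the
target-reaching predicate in MLFT). Everything is deterministic given the
RNG seed.

## Multi-level tracking

Level 1 partitions the baseline pathways into target-reaching (kept) and
failed. For each further level, every point of every failed pathway is
revisited: peaks at that point are oriented into the forward hemisphere of
the incoming direction, the peak within 1° of the recorded step direction is
discarded as "used", peaks within 10° of the travel axis are discarded as
retracing, and each survivor becomes a unidirectional branch seed (a point
with m unused peaks is duplicated m times). Branch seeds landing in one
voxel within 5° of an already-harvested direction are merged, bounding the
seed explosion from half-voxel step sampling. Successful branches are
concatenated with the parent segment up to the branch point (junction point
deduplicated); the junction angle may exceed the per-step threshold — that
is the method's purpose. Failed branch tails feed the next level's harvest;
their concatenated prefixes are carried so deeper levels concatenate the
full ancestry. Default 2 levels. Structural consequences, both asserted in
tests: max_levels = 1 reproduces the baseline bit-for-bit, and the merged
bundle's visitation mask is always a superset of the baseline's (coverage
of the baseline by the multi-level bundle = 100% on every input).

The interhemispheric filter removes streamlines that visit both hemisphere
masks strictly above the shared seed plane; visits at or below the plane are
allowed because the seed region is shared by construction.

## Metrics

Visitation masks mark voxels containing ≥ 1 streamline point (voxel-centre
convention). With steps at or below half a voxel a straight segment cannot
skip a voxel; for strongly curved steps point sampling could, which is a
documented limitation of point (vs segment) rasterization.

Coverage = 100 · |reference ∧ candidate| / |reference| on visitation masks.

Radial extent: the anterior–posterior world axis (from the affine) is
collapsed; projected motor-mask pixels get polar angles about the midpoint
of the inferior edge of the projection's bounding box (a configurable,
approximately hemispheric centre); the motor projection's angular span is
rescaled to [0°, 90°] and cut into 1° bins. The extent is 90° × (covered
occupied bins)/(occupied bins): normalizing by occupied bins makes full
overlap exactly 90° regardless of how sparsely a small mask populates the
90 bins, while remaining monotone in the bundle mask. Outliers in extent
differences use the strict 2σ rule with the sample standard deviation.

## Problem sizes and determinism

The default phantom is 30³ voxels at 2 mm with ~100 fiber voxels, 6 seed
voxels × 5 seeds, and 33 acquisition volumes; a full three-way comparison
runs in well under a minute on one core, and all pipelines are
byte-deterministic given the configuration and seed (summary JSON is
sorted-key, timing information goes to a separate log). Numbers quoted in
the README come from `mlftrack compare --seed 1` on this default phantom.

## Known limitations

- Single-shell, single-tissue deconvolution only; no multi-tissue variants.
- The phantom geometry builder supports a superior (+z) trunk axis on an
  axis-aligned grid; arbitrary obliques are accepted everywhere else.
- No resampling or registration anywhere: all inputs must share one grid.
- The arc parameterization of radial extent (centre, handedness) is one
  consistent reading of the metric's definition, isolated behind function
  parameters.
- Euler integration; no RK4 or adaptive stepping. Probabilistic tracking is
  out of scope.
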