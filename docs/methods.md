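# Methods

## Model overview and assumptions

The estimator predicts normalized muscle forces from kinematics alone.
Its core assumption is that at slow walking speeds active force is
dominated by the force–length relation: activation dynamics, velocity
dependence (force–velocity), and segmental acceleration effects are all
omitted. This is a deliberate scope restriction — the model is intended
for slow gait (≈0.6–0.8 m/s) and is expected to degrade as speed rises.
All outputs are normalized (dimensionless): maximum isometric forces and
physiological cross-sectional areas are out of scope, so no newton-valued
forces are produced.

Three further simplifications define the geometry:

- **Straight-line muscle paths.** Each muscle runs point-to-point from
  origin to insertion; no wrapping surfaces or via points. Muscles that
  wrap strongly (e.g. around the femoral condyles) are therefore tracked
  only approximately.
- **Muscle-tendon length as the fiber-length variable.** The normalized
  length fed to the force model is the origin–insertion distance divided
  by an operating optimal length L₀. There is no tendon-slack subtraction
  or pennation projection: the force–length relations consume only L/L₀,
  so any affine error folds into the calibration of L₀.
- **Row-vector homogeneous convention.** Points are 1×4 rows multiplied
  on the right by 4×4 transforms (rotation upper-left, translation in the
  bottom row). `FrameTransform.to_column_convention()` converts at the
  boundary.

## Anthropometric scaling

Per-segment scale factors are subject/generic length ratios, applied
isotropically to that segment's attachment coordinates and optimal fiber
length (the insertion segment's factor scales L₀). The sternum–head
distance is regressed from height by default (r² = 0.97); weight (kg) and
sitting-height (mm) branches exist but fit worse (r² = 0.52 and 0.94).
Segment masses use the Dempster/Winter proportional coefficients packaged
as an editable CSV (`data/segment_mass_fractions.csv`); the per-segment
fractions are single-side values and sum to less than 1 over the packaged
set.

## Architecture index

Ia(x, y) = 0.1546 − 5.7662·10⁻⁵x + 6.6753·10⁻⁴xy − 2.0563·10⁻⁴x² −
1.3233·10⁻³y + 7.6327·10⁻⁴y², with x the pennation angle in degrees and y
the optimal fiber length **in centimetres** (the regression's source
anatomical tables are tabulated in cm; passing mm inflates the y² term a
hundredfold, so the pipeline converts internally). Muscles with pennation
below 5° are treated as parallel with Ia = 1 exactly; this creates a real
discontinuity at 5° that is documented rather than smoothed. Above 25°
the polynomial is evaluated outside its calibration range with a warning
(the inputs are not clamped). Raw values outside (0, 1] are clamped with a
warning because the force-length branches require Ia ∈ (0, 1].

## Force–length relations and numerical choices

- Active, parallel branch: f_l = exp(−2.727·ln(L/L₀)²) — exactly 1 at
  L = L₀, symmetric in ln(L/L₀).
- Active, pennate branch: f_l = exp(−{[(L/L₀)^0.9631 − 1]/[0.3531(1 −
  Ia)]}²). The bell narrows as Ia → 1; the branch is isolated behind one
  function so the expression can be revised without touching callers, and
  tests pin only the contract (values in (0, 1], unique maximum at
  L = L₀).
- Passive: f_p = 0.0195·exp[(2.933 + 4.911·Ia)(L/L₀ − 1)] — the offset
  sits inside the exponential, so f_p is strictly positive, equals 0.0195
  at the optimal length, and only becomes prominent under stretch. The
  alternative parse with the −1 outside the exponential goes negative for
  L < L₀ and was rejected for violating f_p ≥ 0.

Cycle-offset compensation circularly shifts the **active** series forward
by the tabulated per-muscle offset (packaged `data/cycle_offsets.csv`,
five conditions), quantized to the nearest 1 % grid step; sub-sample
interpolation is out of scope. Passive force is never shifted. Offset
estimation (not used by the forward pipeline) is the arg-max of circular
cross-correlation of mean-centered series, ties broken toward the
smallest lag.

The gait-cycle grid is fixed at 101 points (0–100 % inclusive); the first
and last samples are the same phase, so uniqueness checks on peaks use
the first 100 samples. Multiple recorded cycles are averaged pointwise
after linear interpolation between consecutive foot strikes.

## Transition-matrix estimation

Anatomical→kinematic transforms are fit from ≥3 paired non-collinear
points by closed-form rigid Procrustes (SVD-based, rotation +
translation, no scaling); the RMS residual is attached to the returned
transform. On noiseless rigidly-transformed point sets recovery is exact
to ~1e-12. A transcribed pelvic transition matrix from cadaveric
calibration data ships as a constant; its rotation block is orthonormal
only to ~1e-3 (transcription precision), so it carries a relaxed
validation tolerance.

## Synthetic data: what it emulates, and what it does not

The generator emulates marker-based captures of slow walking at the four
studied speed conditions (X-slow 0.61, slow 0.80, free 1.17, R-fast
1.64 m/s, each with a printed spread). Sagittal hip/knee/ankle angles are
3-harmonic Fourier series (coefficients versioned in the body-model
fixture), scaled mildly with speed; the left leg runs half a cycle out of
phase; segment poses follow by forward kinematics over the fixture
skeleton; cycle duration is stride/speed with default strides of
0.85/1.00/1.22/1.48 m, so cycle duration falls monotonically with speed.
Foot strikes sit at each side's cycle boundaries by construction. All
randomness (marker jitter only) flows through one seed, default 20260326;
identical inputs give bitwise-identical trials. Trials default to 2
cycles at 100 Hz — enough for cycle averaging while keeping the full test
suite and acceptance run in seconds.

The hemiplegic variant scales the affected side's joint-angle excursions
by a weakness factor and delays that side's foot strike by
0.06·(1 − weakness) of a cycle, lengthening the unaffected stance — a
kinematic caricature of compensatory post-stroke gait, not a
neuromuscular model.

Not emulated: ground contact and ground-reaction forces (feet may slide;
no forces are consumed by the model), pelvic tilt/obliquity and axial
rotations (motion is sagittal-dominant; pose recovery from markers
exploits this by augmenting 2-marker segments with an out-of-plane
virtual pair), soft-tissue artifact, and real marker dropout. Passing
tests therefore demonstrate internal consistency of the estimation
machinery under clean periodic kinematics, not clinical accuracy on real
mocap data.

### Fixture length calibration

The packaged body model carries two length fields per muscle. The
anatomical fiber length (cm, Delp-like magnitudes) feeds the architecture
regression. The operating optimal length `L0_generic_mm` normalizes the
straight-line muscle-tendon distance; a single value cannot serve both
roles because origin–insertion distances are hundreds of mm while fiber
lengths are a few cm. Operating optima were placed relative to each
muscle's simulated length range: hip muscles (Glut_Max1, TFL, Iliacus,
Pectineus) at 0.97× the cycle minimum so they operate on the descending
limb and stay mildly stretched (this also makes one-sided weakness
strictly lower the affected side's peak active force); Vas_Int at
mid-range; distal muscles at the cycle mean so they cross the optimum
twice per cycle. TFL, Iliacus and Vas_Int are designated stretch-prone —
they exceed L/L₀ = 1 during the cycle and develop passive force above the
0.0195 baseline. The fixture file is versioned and integrity-checked by
SHA-256 at load.

## Known limitations

- No activation: co-contraction, spasticity and any force not explained
  by fiber length are invisible; accuracy degrades with walking speed.
- Straight-line paths misestimate lengths for wrapping muscles; moment
  arms are not computed.
- The architecture regression is least reliable for parallel-fibered
  muscles (the 5° rule is a hard default) and extrapolates above 25°.
- Cycle offsets are fixed per condition; per-subject offset estimation
  from a reference dataset is available (`estimate_cycle_offset`) but not
  wired into the default pipeline.
- The cm-vs-mm unit of the architecture regression's length input is a
  documented interpretation (source tables are in cm) and can be
  overridden by passing a different unit upstream.
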