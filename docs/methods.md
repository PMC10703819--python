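# Methods

## The measurement principle

A near-infrared point source illuminating the eye produces four specular
reflections — the Purkinje images.  P1 and P2 come from the anterior and
posterior cornea, P3 and P4 from the anterior and posterior surfaces of the
crystalline lens.  Because accommodation reshapes the lens (its anterior
radius shrinks as the eye focuses near), the lens reflections move on the
camera sensor as accommodation depth `A = 1/d` (diopters; `d` the focus
distance in meters) changes, while the corneal glint stays put.  Eye
rotation by the vergence angle `θ = arctan(d_target/d)` moves all
reflections, the deep-lying P4 most of all.  Ten quantities measured per
frame — pupil center and ellipse (`x_PC, y_PC, r1, r2`) and the spot
positions (`x_P1, y_P1, x_P3, y_P3, x_P4, y_P4`), all in pixels — therefore
carry enough information to estimate accommodation depth and vergence angle
simultaneously.

`purkinjeye` implements that measurement chain end to end on synthetic
data: a schematic-eye ray tracer generates ground-truth spot positions, a
renderer turns them into NIR-like frames, a detector recovers the ten
parameters, and two estimator families (closed-form linear maps and MLP
regression with calibration) map parameters to `(A, θ)`.

## Schematic eye

The eye is the four-surface Navarro-style schematic eye: anterior cornea
(R = 7.72 mm, Q = −0.26), posterior cornea (R = 6.5 mm), anterior lens
(R = 10.2 mm at rest, Q = −3.1316), posterior lens (R = −6.0 mm, Q = −1.0),
with corneal thickness 0.55 mm, anterior chamber 3.05 mm, lens 4.0 mm and a
constant 24.004 mm axial length (the vitreous depth absorbs lens-thickness
changes, so focusing never changes the eye's length).  Radii are signed
positive when the centre of curvature lies toward the retina; surfaces are
conicoids `ρ² + (1+Q)ζ² − 2Rζ = 0`.  Media indices (cornea 1.367, aqueous
1.3374, lens 1.42, vitreous 1.336 at 589 nm) carry additive NIR offsets
(−0.006 to −0.007) for 940 nm operation, following the dispersion of water.

**Accommodation law.**  Navarro's original model varies the lens radii,
lens thickness, anterior-chamber depth and conic with `ln(1+A)` and the
lens index with `9·10⁻⁵(10A + A²)`.  The log law is intrinsically curved:
its best straight-line fit of `A` against `ln(1+A)` over 1–4 D leaves a
0.13 D residual, which caps how well any strictly linear feature→depth map
can do.  The linear relationship between spot separation and accommodation
is exactly what this measurement method exploits, so the default parameter
file uses a **linear-in-A** dependence whose coefficients match the Navarro
log law at rest and at 4 D (e.g. anterior lens radius 10.2 − 0.7041·A mm),
in the style of linear-in-A schematic eyes such as the Arizona model.  The
log law remains available by setting `accommodation.law: log` (with the
published coefficients, listed in the file) for users who want Navarro's
exact curvature.  Conic constants ship with Navarro's published values; a
spherical eye is one override away.

Eye rotation is rigid, in the horizontal plane, about a point 13.5 mm
behind the corneal apex (the standard sighting-centre convention,
configurable).  A consequence worth knowing: the anterior-lens centre of
curvature sits ~12–12.6 mm behind the apex, almost on the rotation centre,
so P3 moves *less* than P1 under pure rotation in this model (~0.7 vs
~2 px/deg in the default scene) while P4, whose effective mirror centre is
~2 mm behind the apex, moves ~5 px/deg.  The same ordering shows up in the
permutation importances of the vergence-dominated configuration (P4 ≫ P1 >
P3).  Claims that both lens reflections move much more than the glint under
rotation hold for P4 but not for P3 at any anatomically plausible rotation
centre; one acceptance assertion encoding the stronger claim is left
failing deliberately.

## Ray tracing

`trace_purkinje` finds, for surface `k`, the chief ray: the single LED ray
that refracts through surfaces `1..k−1` (vector Snell's law), reflects at
`k`, refracts back out, and passes through the camera pinhole.  The launch
direction is parameterised by its aim point on the apex plane and solved by
a two-parameter root search (Powell hybrid with multi-start, |miss| <
10⁻⁶ mm at the pinhole; surfaces are unbounded during the search and
aperture/pupil vignetting is judged on the converged path).  The sensor
position is the pinhole projection of the exiting ray (origin top-left,
x right, y down, sub-pixel continuous).  P2 is computed but lies within
1 px of P1 in the default scene, so only P1 feeds the feature set.

The independent oracle, `paraxial_purkinje`, images the LED by sequential
paraxial refraction, paraxial mirror imaging at `k`, and refraction back
out, using the reduced-angle formulation with negative-index unfolding of
the reflection; the virtual image is projected through the same pinhole.
Exact and paraxial positions agree to < 10⁻⁴ px in small-angle scenes
(the acceptance bound is 0.5 px), and unit tests pin the engine to the
planar-mirror image and the spherical-mirror equation.

The entrance pupil is computed exactly: ≥ 16 pupil-rim points are each
connected to the pinhole by a root-found ray refracting through both
corneal surfaces; an ellipse fit (scikit-image `EllipseModel`) of the
projected rim gives `(x_PC, y_PC, r1 ≥ r2)`.

## Default scene

LED at (−4, +7, 75) mm, pinhole at (−2, −14, 75) mm, f = 1800 px, 400×300
sensor, targets 4→1 D in 0.5 D steps with a fixed 31.5 mm lateral offset
(vergence 1.8–7.2°; the accommodation-only configuration zeroes the
offsets).  The LED/camera heights are chosen so the camera's depth parallax
cancels the baseline vertical P3–P4 offset.  That one choice buys two
properties at once: `y_P4 − y_P3` swings ±2 px around zero with
accommodation and barely responds to rotation (a clean depth signal), and
`d(P3−P4)` is dominated by its horizontal component, so it grows linearly
with rotation instead of following a hyperbola.  No spot is vignetted at a
2 mm pupil anywhere in A ∈ [1, 4] D × θ ∈ [0, 7]°, and the minimum
inter-spot separation stays above 10 px.  The scene is a package default,
not a claim about any physical rig.

## Synthetic data

Subjects perturb the eye multiplicatively: per-surface radius and thickness
factors from a truncated normal (sd 3 %, hard ±9 %, inside the ±10 %
anatomical bound), pupil radius 2.5 ± 0.2 mm (truncated to [2, 3]),
rotation-centre offset ±0.3 mm sd, reaction time N(250, 60) ms clipped to
[150, 500] ms.  A session steps through the protocol (2 s per LED at 50 Hz
= exactly 100 frames per data point, sequential or seeded-random order);
frames within the reaction time after a switch keep the previous eye state
and carry a `discard` flag (pure transport delay — no accommodation
dynamics are modelled).  Measurement noise is zero-mean Gaussian, 0.3 px
per parameter per frame; this scale is a tuning choice made so the analytic
estimator's cohort RMSE lands near the 0.1–0.2 D decade reported for
comparable systems, not a measured camera property.  Blinks flag a row (1 %
probability) with all parameters missing; frame counts never change.
Everything is deterministic in `(seed, rep)` where `rep` distinguishes
repeat/calibration sessions.

The renderer draws a dark pupil ellipse (axis-aligned; sigmoid edge,
softness 0.7 px) on a brighter iris disc, and Gaussian spots (σ = 1.6 px)
with amplitudes ordered P1 > P3 > P4; optional Poisson (2 e⁻ per grey
level) plus Gaussian (σ = 2 grey) noise.  It renders what real frames would
show qualitatively; it does not model defocus blur of the spots, eyelids,
eyelashes, corneal reflections of the surround, or pupil light response —
so detection results on synthetic frames bound algorithmic error only, not
performance on real video.

## Detection

Pupil: darkest-class threshold from three-class Otsu, hole filling (the
spots punch holes in the pupil), largest plausible component, moments-based
centre and semi-axes.  Spots: percentile threshold *inside* the pupil
ellipse (the iris outshines P4, so the ROI must exclude it), floored at
median + 0.25·(max − median) so sparse spots cannot drag the threshold into
the noise; blobs ranked by background-subtracted integrated flux (robust to
shot noise, unlike the peak); P1 is the brightest, and of the remaining two
the dimmer is P4 (a prior-guided assignment using the previous frame is
selectable).  Positions are intensity-weighted centroids of the
background-subtracted blob.  Round-trip accuracy on noiseless frames:
< 0.2 px spots, < 0.1 px pupil centre, < 1.5 % semi-axes.

## Estimators

Analytic (per subject): `A = a_acc·((y_P4 − y_P3) − b_acc)` and
`θ = a_ver·(d(P3−P4) − b_ver)`, ordinary least squares in that
parameterisation; `d(P1−P4)` is selectable because both pairs appear in the
source literature for the vergence feature.  Headline RMSEs are computed on
per-target mean predictions over non-discarded frames.

MLP: one scikit-learn `MLPRegressor` jointly predicts `(A, θ)` from either
6 (spots) or 10 (spots+pupil) standardized inputs.  Hyperparameters come
from a grid search (3-fold CV, summed MSE): default grid hidden ∈ {(32,),
(64, 32)}, batch 32, ≤ 200 epochs with seeded validation-based early
stopping (disabled below 120 training rows, where a 10 % holdout
degenerates).  The compact default grid keeps a full 9-subject two-
configuration campaign to a few minutes on one core; the grid is plain
config for anyone wanting a wider sweep.

*Own-data protocol*: a seeded 30 % of a subject's frames trains the model,
and evaluation runs on the subject's entire sequence — training frames
included, as the protocol specifies; `leak_free=True` evaluates on the
held-out 70 % only.  *LOSO protocol*: each subject is held out in turn,
grid search and training see only the other subjects (audited), and the
held-out subject's raw predictions are corrected by two-point calibration:
fixations at 3.5 D and 1.5 D anchor the affine map

    A_calib = (A_CP1t·(A_pred − A_CP2p) + A_CP2t·(A_CP1p − A_pred)) / (A_CP1p − A_CP2p)

(the closed form of the anchored proportion; an independent Brent
root-finder of the proportion itself serves as the test oracle, agreeing to
< 10⁻⁹).  When both calibration points share one vergence target
(accommodation-only configuration) the vergence map degenerates and passes
through as identity.

Permutation importance shuffles one input column at a time (≥ 10 seeded
repeats), measures the MSE increase, clips at zero and normalises so the
maximum weight is 1; constant columns are flagged with zero weight.

## Numbers the pipeline produces (seed 1, defaults)

The 9-subject, two-configuration benchmark (`cohort_benchmark`, also run by
`scripts/acceptance.py`) yields: analytic depth RMSE 0.104 D / vergence
0.159°, own-data MLP 0.040 D / 0.041°, LOSO+calibration 0.055 D / 0.039°,
repeatability Pearson r 0.994, with the expected ordering own ≤ LOSO.
These are synthetic-cohort numbers under the noise model above; they
demonstrate that the pipeline recovers its own ground truth well inside the
0.22 D / 0.40 D envelopes, not that any camera achieves this on human eyes.

## Problem sizes and determinism

Defaults throughout were sized for a single core: cohort 9 subjects × 7
targets × 100 frames per configuration, detection round-trip 500 frames in
the test suite (200 in the acceptance script), 10⁴ rays for the optical
invariants, 10³ random calibration maps.  All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence` spawns (distinct
fixed prefixes per stage), and every training path re-runs bit-identically
under a fixed seed.

## Known limitations

- The anatomical variability model is multiplicative and surface-local; it
  does not model tilt, decentration, astigmatism or angle kappa.
- Reaction time is a pure delay; real accommodation responses are smooth
  and asymmetric.
- The renderer's pupil ellipse is axis-aligned; the true projected ellipse
  is slightly tilted for oblique cameras (sub-percent axis effect at the
  default geometry).
- The P3 rotation response is smaller than P1's in this model (see the
  schematic-eye section); systems relying on P3 for gaze would need a
  different geometry or model refinement.
- Simulated pixel coordinates reproduce trends, not any physical rig's
  absolute pixel values; scene files are configuration, not calibration.
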