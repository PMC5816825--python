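# Methods

This note records the scientific and numerical choices behind the package:
what is computed, under which assumptions, and where the genuinely open
design decisions were settled.

## The score

Each trial yields an m × n matrix of per-step symmetry indices (SI, signed
percent, left-minus-right over the bilateral mean).  The trial score is the
mean over steps of

d_i = sqrt( x_i Σ⁻¹ x_iᵀ / S ),  S = Σ_jk (Σ⁻¹)_jk,

with Σ the ordinary sample covariance (about column means, denominator m−1)
of the SI columns and x_i measured **from the origin**, i.e. from ideal
symmetry, not from the column mean.  Two deliberate consequences:

* A consistently asymmetric gait (large mean SI, small variance) scores
  high.  Centering the distance would hide exactly the signal of interest.
* Dividing the quadratic form by S converts it into a weighted mean across
  parameters, so adding a very noisy parameter does not inflate the score;
  its weight (normalized column sum of Σ⁻¹) shrinks instead.

Aggregation choices that the literature leaves open are exposed rather than
hidden: `CGAMResults.aggregate` offers mean (default), median, RMS and a
pooled form; per-step squared forms, distances, S and the ridge are all
carried on the results object, so any alternative is a one-liner.  The SI
numerator side is configurable and recorded on the matrix.

Signed SIs are kept (never absolute values) because the covariance must see
co-variation between parameters; taking magnitudes first would distort it.
Rows with an undefined SI (sides canceling to a near-zero bilateral mean)
are deleted listwise and counted, since the covariance needs complete rows.

**Effective weights.** w_j = (column sum of Σ⁻¹)_j / S; they always sum
to 1.  For diagonal Σ they reduce to inverse-variance shares and are
positive and strictly decreasing in the parameter's variance.  With strong
inter-parameter correlation (e.g. the three joint moments, which share
dynamics) individual weights can be negative; they are then signed
contributions of marginal directions, not probabilities, and are reported
together with the marginal variances for that reason.

**Covariance scope** is per trial by default — the score weighs each
condition by its own step-to-step variability.  A pooled covariance can be
supplied to `CGAM(cov=...)` for cross-condition comparability.

**Regularization.** The sample covariance is inverted by Cholesky.  If its
condition number exceeds 1e10 or m < n + 2, a deterministic diagonal ridge
ε = 1e-8·trace(Σ)/n is added, escalating tenfold until the factorization
succeeds (floor 1e-12 when the trace itself is zero, e.g. a perfectly
symmetric noise-free trial).  The ridge used is logged and reported, so
scores are reproducible bit for bit.  Negative quadratic forms beyond −1e-9
raise; smaller ones are clipped to zero.

## Pipeline

**Conditioning.**  Zero-phase 4th-order Butterworth low-pass: 6 Hz for
markers, 15 Hz for forces (standard gait-lab practice; overridable).  Force
baselines are the per-channel median over the lowest 5 % of vertical-force
samples — no swing phase is assumed to exist.  Two exceptions are
deliberate: *event detection* runs on the baseline-corrected, unfiltered
vertical force, because zero-phase smoothing blurs the contact edge
symmetrically and biases threshold crossings by several milliseconds; and
*step length* is read from raw markers, because smoothing biases the heel
trajectory most at the instant of contact, exactly where it is sampled.

**Events.**  Heel strike = first sample where vertical force rises above
20 N and stays above for ≥ 50 ms; toe off symmetric on the way down; shorter
excursions are debounced into the surrounding state.  Partial phases at the
trial edges are discarded.  A *step* runs from one side's heel strike to the
next contralateral heel strike and is labeled by its terminal side;
consecutive left/right steps form the stride pairs that become matrix rows.
Only complete pairs enter the matrix.  Whether rows should count steps or
strides is not settled usage; steps were chosen because each step carries
its own parameter vector, and the aggregation is a mean so the score scale
is unaffected.

**Parameters.**  Step time = contralateral-to-own heel-strike interval;
step length = anterior inter-heel distance at heel strike (belt integration
deliberately avoided — the inter-heel distance is well defined from markers
alone; belt speed stays in the metadata).  GRF features are stance extrema
(peak vertical; most negative / most positive anterior force), divided by
body weight.  Angles are sagittal segment angles (knee 0 at full extension,
flexion positive; ankle 0 in neutral, dorsiflexion positive; hip = thigh
from vertical).  The per-step scalar for angles and moments is the **range
of motion over the stride** — no published convention exists for which
scalar represents them per step, and the range is sign-convention-free and
identical for both sides by construction; peak summaries are available via
`summary="peak"`.

**Inverse dynamics** is sagittal-plane (2-D) link-segment Newton–Euler,
distal to proximal over foot, shank, thigh, with Winter's anthropometric
fractions (masses 0.0145/0.0465/0.100 of body mass; CoM at 0.50/0.433/0.433
of segment length from proximal; radii of gyration 0.475/0.302/0.323).  The
hip joint is approximated by the ASI marker and the foot's inertial axis by
heel→toe (the standard foot length); its proximal joint is the ankle
marker.  CoM and angular accelerations are second-order central differences
of the conditioned trajectories; during stance the measured GRF acts at the
CoP, during swing the external force is zero.  Full 3-D inverse dynamics is
out of scope; the 2-D form is verifiable against closed forms (static
equilibrium and a rigid-pendulum oracle in the test suite, both matching to
1e-6 and 2 % respectively).  Moments are normalized by body mass (N·m/kg),
forces by body weight — the SI is scale-free so normalization does not
change the score, but it makes fixtures portable across subjects.

## Synthetic gait generator

Two levels:

* **Matrix level** — SI rows drawn from a multivariate normal with chosen
  mean offsets and covariance; exact statistical control for testing the
  metric (expectations, monotonicity, estimator consistency).
* **Waveform level** — a full treadmill trial.  Vertical GRF per stance is a
  double-hump template (two Gaussians at 30 %/70 % of stance, rescaled so
  the sampled peak equals the drawn value); AP force is a braking-then-
  propulsive sine with independently drawn lobe amplitudes.  Heel
  trajectories move backward at the treadmill-consistent speed during stance
  and swing forward by quintic (minimum-jerk) interpolation, landing exactly
  where the programmed step length dictates.  Hip/knee/ankle markers follow
  a kinematic chain driven by prescribed joint-angle waveforms that vanish
  at stride boundaries, so per-stride amplitude jitter never creates
  discontinuities and each stride's extracted range equals its drawn ROM
  exactly.  Step-to-step variability is injected at the template-parameter
  level (defaults: ST 10 ms, SL 12 mm, GRF peak 0.03 BW, AP lobes 0.01 BW,
  angle ROM 1.5°); defaults otherwise are stride 1.2 s, stance fraction
  0.62, vGRF 1.1 BW, AP 0.2 BW, knee/hip/ankle ROM 60/40/25°, step length
  0.55 m, subject 70 kg / 0.94 m leg length, markers 100 Hz, forces
  1000 Hz, 20 strides per trial — ordinary values for adult treadmill
  walking at ~0.9 m/s.  The generator emits its ground truth (event times
  and per-step parameter values) alongside the recording.

Two honest simplifications.  First, the heel/toe markers (foot model) and
the knee/ankle markers (angle chain) are not rigidly coupled; each extracted
quantity has an exact programmed truth value, but the marker set as a whole
is not one consistent rigid-body skeleton.  Second, joint moments are not
independently programmable: they emerge from inverse dynamics of the
generated kinematics and forces, so scenario offsets for AM/KM/HM are
honored in matrix-level generation and recorded in provenance, while
waveform-level moment asymmetry is whatever the dynamics produce.  Moment
correctness is instead established by the closed-form oracles above.

**Scenarios** mirror a split-belt protocol: leg-length increments of
27/52 mm and distal masses of 2.3/4.6 kg on the left leg (alone and in all
combinations), a damping/stiffness knee orthosis ("stroke simulator",
rotary damper 8 898 g·cm·s/°, torsional spring 0.457 kg/mm) on the right,
and its after-effect condition.  Effect maps are *phenomenological* mean-SI
offsets per parameter — there is no validated transfer function from a
physical perturbation to each gait parameter, so the maps encode only the
qualitative signatures: leg length loads step-length asymmetry more than
step-time (and mass the reverse, with opposite signs on shared parameters so
combined conditions partially cancel); the orthosis adds large offsets with
1.8× step-to-step variability, dominated by step length and hip moment.
Offset s (percent) on a parameter multiplies the left template by
(1 + s/200) and the right by (1 − s/200), preserving the bilateral mean and
the stride period.  Magnitudes are free parameters chosen once (catalog in
`cgam/data/scenarios.yaml`).

**What passing tests show — and don't.**  The generator produces clean
template-plus-jitter waveforms: no marker dropout or soft-tissue artifact,
no crossover steps on the split belt, no force-plate noise (robustness to
additive noise and spikes is exercised by dedicated fixtures instead).
Recovery and ranking results on synthetic trials therefore validate the
*pipeline's correctness*, not its robustness to every artifact of real
laboratory data.

## Numerical conventions

* Sample-grid indexing of event times uses an 1e-9 epsilon guard so that
  events falling exactly on a sample are not shifted by floating-point
  representation.
* Degenerate inputs: zero-length segments raise; isolated marker NaNs flag
  the affected stride pair as incomplete rather than aborting; all-zero
  matrices score 0 through the ridge floor.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical configs give byte-identical outputs (bootstrap CIs
  included).

## Problem sizes

Simulation-based checks in the test suite use 20-stride trials (the
package's default trial length), 100 seed-paired trials per perturbation
class for ranking, 50 random recipes for recovery, and m = 10,000 draws for
the Gaussian expectation; `scripts/acceptance.py` uses the same designs at
10–50 replicates.  These sizes put Monte-Carlo error well below every margin
tested while keeping a full run in tens of seconds.

## Known limitations

* 2-D sagittal analysis only: no frontal/transverse angles or moments, no
  joint powers, zero mediolateral force in the generator.
* The hip-joint-at-ASI approximation offsets absolute hip angles and
  moments; symmetry indices are insensitive to a bilateral offset, but
  absolute moment magnitudes should not be read as clinical values.
* Treadmill step length is the inter-heel distance at contact; overground
  definitions that integrate belt motion will differ for asymmetric timing.
* C3D reading requires the optional `ezc3d` dependency; the tested paths
  are the CSV dialects.
* Scenario effect magnitudes are plausibility choices, not fitted to any
  dataset; only their qualitative signatures are meaningful.
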