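# Methods

`cervkin` implements a complete analysis chain for the fast cervical
axial-rotation test: seated subjects rotate the head "as fast as possible"
to one side and back, six trials in alternating directions, recorded by two
6-DOF electromagnetic-tracker receivers (forehead and upper-thoracic
spinous process) at 60 Hz. This note documents the models, the numerical
choices, and what the synthetic data do and do not establish.

## Kinematic model

**Orientation algebra.** Each receiver's ZYX cardan angles (azimuth,
elevation, roll, degrees) are converted to rotation matrices
R = Rz(az)·Ry(el)·Rx(roll); head-on-thorax motion is the relative rotation
M = M_thoraxᵀ·M_head. All twelve raw channels are first low-pass filtered
with a 2nd-order Butterworth at 20 Hz, applied forward–backward
(zero-phase) so that the timing of the speed peak is not shifted; the
effective magnitude response is |H(f)|². Filtering acts on the Euler
channels directly; this is safe here because the task keeps elevation far
from the ±90° cardan singularity, and a guard rejects trials with
|elevation| > 80°.

**Helical angle.** The rotation from the trial-start orientation to the
current one is summarized by its helical (screw) angle
θ = arccos((tr(R₀ᵀR_t) − 1)/2) — a single non-negative scalar capturing the
full 3-D rotation.

**Angular speed.** Because finite rotations do not commute, attitude
angles are not differentiated directly. Instead the kinematic relation
Ṁ = [ω]×·M gives the angular-velocity vector from the skew-symmetric part
of Ṁ·Mᵀ (anti-symmetrized to suppress numerical asymmetry); the pipeline
uses |ω| in °/s. Ṁ is built with centred differences: a 4th-order
five-point stencil in the interior, 2nd-order at the two frames adjacent to
the ends, one-sided at the ends. The 2nd-order stencil was measured to
attenuate the speed peak of the fastest rotations (movement times near
0.2 s at 60 Hz) by up to ~3%, biasing Peak Speed; the 5-point stencil
removes this at no smoothing cost.

**Finite helical axis (FHA).** For each frame the rotation axis is
computed relative to the nearest *earlier* frame at least 4° of helical
rotation away (the unit vector of the skew part of M_jᵀM_i). The 4° window
keeps the axis estimate away from the small-rotation regime where its
direction is ill-conditioned; frames with less accumulated rotation are
undefined. Directions keep their natural sign (which encodes the sense of
rotation); sign alignment against the first defined direction is applied
only where a sign-free cloud is needed (the CM statistic).

**Resampling.** Helical angle and speed are resampled from 60 Hz to a
uniform 100 Hz grid with natural cubic splines, to refine peak and
threshold localisation; FHA directions stay at the native rate.

## Per-trial variables

The movement is segmented on the 100 Hz grid at a threshold of 10% of Peak
Speed: start = last sample at/below threshold before the speed maximum,
stop = first at/below after it. For an ideal minimum-jerk profile these
crossings sit at phases τ ≈ 0.0865 and 0.9135, capturing ≈98.9% of the
amplitude.

Because segmentation leaves the profile at non-zero speed, both sides are
extended to zero before timing variables are computed. On each side a
quintic polynomial matches the profile's value, slope and curvature at the
boundary and lands with zero value, slope and curvature at a new endpoint.
The endpoint offset comes from the profile history over a 30 ms window just
inside the boundary: a least-squares quadratic in v and a least-squares
line in √v are each extended to their zero crossing. For bell-shaped tails
(v ≈ c·δ² near rest) the quadratic estimate stops short of the true rest
point and the √v estimate overshoots it, so a 0.4/0.6-weighted mean is
used; the weights were calibrated against the closed-form minimum-jerk tail
across the 100–500 °/s range (Move-Time error within ±1%). Offsets are
capped at 0.25 s, and a boundary slope of the wrong sign falls back to a
linear ramp with a warning.

The six variables:

| variable | definition | units / notes |
|---|---|---|
| Peak Speed | max |ω| on the 100 Hz grid | °/s |
| ROM | θ(stop) − θ(start), pre-extrapolation boundaries | ° (biased ~1% low by the threshold; by design) |
| NPA | Peak Speed / mean extrapolated speed | 1.875 for an ideal minimum-jerk profile |
| A/D-ratio | TTP / (Move Time − TTP) | 1 for a symmetric profile |
| SID | 100 · time-weighted RMSE between the extrapolated profile and a minimum-jerk profile with T = Move Time and displacement A = ∫v dt, divided by mean speed | % ; the fit is parameter-free (duration- and displacement-matched, no optimizer); denominator configurable (mean or peak) |
| CM | condition number σ_max/σ_min of the sign-aligned FHA direction set within the segment | a.u.; *smaller* CM = more axis wandering = more conjunct movement; ≥3 defined directions required, degenerate collinear clouds capped at 10⁶ |

Mean speed and displacement integrals use trapezoidal quadrature on the
actual (slightly non-uniform at the seams) extrapolated time base.

Trials are flagged invalid — an automated stand-in for the original manual
curation of "atypical movements" — when peak speed < 30 °/s, ROM < 10°,
the net rotation opposes the instructed direction (judged from the sign of
the raw FHA z-components in the segment), or the profile is clearly
multi-peaked (two peaks within 20% of the maximum separated by a drop below
half maximum). Valid trials are averaged per subject and session, left and
right rotations pooled; CM is averaged over the trials where it is defined.

## Reliability statistics

For each variable and group, test–retest pairs (n = 16 per group in the
emulated design) yield:

- **ICC**, two-way random single-measure, *consistency* form:
  (MS_subjects − MS_error)/(MS_subjects + MS_error) for k = 2, with the
  F-based 95% CI; an absolute-agreement ICC(2,1) variant is available by
  option. Consistency was chosen because the source convention explicitly
  says "consistency" even while citing the 2,1 numeral; both forms are
  cross-checked against pingouin in the tests.
- **SEM** = SD(test1 − test2)/√2, with a χ²-based CI for a standard
  deviation (the CI method is this package's choice; none is inherited).
- **CV** = 100·(eˢ − 1) with s the SEM formula on log-transformed values.
- **MD** = SEM × 1.96 × √2 (= 2.77186·SEM), the minimal individual change
  exceeding measurement error at 95% confidence.
- **Heteroscedasticity**: Pearson correlation (Spearman by option) between
  subject means and |differences|; **bias**: two-sided paired t.

ICC and the bias test are computed on log values when heteroscedasticity is
significant (p < 0.05) or pooled skewness exceeds |1| (the skewness cutoff
is this package's explicit rule); SEM/MD stay on the original scale.

## Group analysis

Variables correlated with age in the pooled sample (Peak Speed, ROM, NPA by
default) are replaced by OLS residuals of value ~ age fitted on both groups
together before comparisons. Group differences use independent-samples
t-tests. Classification is Fisher LDA: pooled within-group covariance,
equal priors (threshold midway between projected class means — chosen
because near-symmetric sensitivity/specificity is the expected regime),
leave-one-out cross-validated sensitivity (patients) and specificity
(controls), standardized coefficients (weights × pooled within-group SD,
unit-normalized). Stepwise selection is forward by Wilks'-lambda partial F
with enter/remove thresholds 3.84/2.71 (the conventional defaults of the
statistics package this workflow emulates), with a removal pass after each
entry; collinear candidates are skipped, and the final model is refit and
evaluated with leave-one-out.

## O-PLS association model

The association between a kinematic response (Peak Speed by default) and
the 44-item self-rating block uses orthogonal projections to latent
structures: variation in X orthogonal to y is removed by orthogonal
component(s), then a single predictive PLS component is fitted, all on
mean-centred unit-variance columns. Missing predictor cells are handled by
the NIPALS convention (inner products over present cells only). Columns
with |skewness| > 1 and strictly positive values are log-transformed first
(an explicit rule standing in for the original software's automatic
recommendation).

- **R²Y** is explained variation on the training data; **Q² = 1 −
  PRESS/SS** from 7-fold cross-validation with a seeded shuffled fold
  assignment, each fold refitting the scaling and the model. A model is
  significant when Q² > 0.05.
- **Orthogonal components** are added one at a time and kept only while
  they improve Q² by more than 0.01 (up to 2). A forced fixed count
  measurably overfits weak-signal p ≫ n data (Q² dropped from +0.08 to
  −0.12 on the synthetic questionnaire block, against a plain-PLS oracle);
  the CV rule mirrors the autofit behaviour of standard chemometrics
  software. A fixed integer count remains available.
- **VIP** for a single predictive component is √p·|w_j|/‖w‖ (so mean
  VIP² = 1), with confidence intervals by jack-knifing the fold-deleted
  models (t-interval over fold VIPs). A predictor is reported significant
  when the model is significant, VIP > 1, and the CI lower bound stays
  above 0.5; output is ordered by descending VIP.

## Synthetic data: what it emulates

No recordings or questionnaires from the original cohorts were ever
deposited, so a generator defines the study conditions end to end.

**Trial model.** The primary rotation angle follows a *two-piece*
minimum-jerk trajectory: each side of the speed peak is half a
minimum-jerk bell, compressed or stretched in time so the
acceleration/deceleration ratio equals the configured value exactly while
the peak/mean ratio stays exactly 1.875. (A power-law time warp was
rejected: at the published A/D levels it deviates 25–30% RMS from the
fitted minimum-jerk profile, far above the published smoothness indices.)
Jerkiness is a band-limited (5–9 Hz) sinusoidal speed ripple whose window
vanishes at the movement ends *and* at the peak phase, so the configured
peak speed is the trial's true peak. Conjunct movement is a smooth random
arc of the rotation axis inside a cone about the vertical, parameterized by
movement *progress* (one- and two-cycle sinusoids with random phases) so
the axis is stationary whenever the head is; a wall-time random walk would
leak spurious speed into the profile tails and break segmentation. The
thorax is held at identity; both receivers' cardan channels receive
additive white noise, and 0.5 s stationary padding flanks the movement.

**Sensor noise.** The white orientation jitter default is 0.03° SD.
Electromagnetic trackers' headline accuracy figures (~0.15°) are dominated
by quasi-static field distortion, which differentiation suppresses and
which is therefore not modelled; white jitter at the accuracy figure would
produce an unphysical ~6 °/s speed-noise floor that no published speed
profile of this test shows.

**Cohort model.** Subject latents are drawn per group (truncated
normals): Peak Speed 348 ± 92 (controls) vs 226 ± 88 °/s (patients), ROM
61.5 ± 8.3 vs 52.7 ± 9.2°, A/D 0.81 ± 0.24 vs 0.74 ± 0.22, with a negative
age trend on speed (−3 °/s·yr) and range (−0.45 °/yr) carried inside the
configured between-subject SD, group ages 46 ± 10 vs 50.5 ± 9, and a
low-back-pain flag for 62/118 of patients. Ripple and wobble levels were
calibrated empirically (a utility, `calibrate_wobble_to_cm`, maps wobble to
measured CM, which has no closed form) so the cohort-level smoothness and
axis-dispersion variables land in the published ranges: SID ≈ 14–17%
(published 13.7/18.1) and CM ≈ 15–18 a.u. (published 14.5/17.6). Exact
group separation of SID is not reproduced: the two-piece profile's
asymmetry alone contributes a ~10–14% SID floor at the published A/D
levels, compressing the room between groups. Six trials per session
alternate direction (half the cohort starting rightward) with 8%
trial-to-trial jitter; retest cohorts share subject latents with a 10%
between-session component, which places Peak Speed SEM near the published
~41 °/s and ICC in the published 0.75–0.84 band.

**What passing tests show — and don't.** The synthetic data share the
published group means, variances, effect sizes and noise structure, so
they validate the *machinery*: signal processing, segmentation, variable
definitions, statistics, and their calibration (type-I error, null Q²,
recovery rates). They do not establish clinical validity on real
recordings: real profiles' ripple spectra, real questionnaire response
distributions, and the measured NPA level (published ≈2.33 vs the
generator's minimum-jerk-bound ≈1.87) are known differences.

## Problem sizes and determinism

Default analysis sizes mirror the emulated design (118 + 49 cross-
sectional; 16 + 16 × 2 sessions for reliability). The test suite and the
acceptance script use these sizes directly except where a check is
intrinsically replicated (calibration loops use 25–1000 replicates at
reduced per-replicate cost). All randomness flows through explicit integer
seeds (`numpy.random.default_rng`); the same seed reproduces a cohort
bit-for-bit, including through the CSV round trip (files are written at
full decimal precision and parsed with round-trip float parsing).

## Known limitations

- The tracker dialect assumes the ZYX (azimuth–elevation–roll) cardan
  convention; other sign conventions must be declared in the dialect
  configuration (per-axis sign flips), as the convention cannot be inferred
  from data.
- The FHA window rule is "nearest earlier frame ≥ 4°"; symmetric-window
  variants found in the wider literature are not implemented.
- The quintic endpoint placement and the SID denominator are underdetermined
  by the source description; both are explicit, configurable choices here.
- CM depends on the number of native-rate frames in the segment and hence
  mildly on movement speed; published values are matched at the published
  speeds.
- Translation of the helical axis (its position in space) is out of scope;
  only the rotation angle and axis direction are used.
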