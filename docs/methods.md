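# Methods

This note documents the models, parameter choices and numerical decisions
behind `gaitmep`, and what the synthetic-data validation does and does not
establish about real recordings.

## Gait events and spatiotemporal metrics

Heel strike is the per-cycle minimum of the heel marker's vertical
trajectory; toe-off is the per-cycle maximum of its upward acceleration.
Both detectors first estimate the dominant stride period from the
autocorrelation of the demeaned trajectory and then suppress candidate
events closer than half that period, with an additional prominence
threshold (10 % of the signal/acceleration range) to reject shallow
stance-phase wobbles. The acceleration is obtained by central differences
after a zero-phase 10 Hz low-pass, which stabilises the peak location
without biasing it (the low-pass is symmetric). Event times are reported
at sample resolution; no sub-sample interpolation is attempted.

Step width is the absolute mediolateral heel separation at each heel
strike. Both feet stand on the treadmill surface, so a lateral belt
displacement moves both markers equally at contact and cancels in the
difference. "Variance" is the sample variance (n − 1 denominator).
Summaries are taken over a trailing window of strides (default 150; the
last `window` stride durations and `2·window` step widths).

## Local divergence exponent (λ_s)

State space: the thorax mediolateral velocity (mean of C7 and both
acromion markers), resampled so every stride spans 100 samples, embedded
with five delayed copies. The embedding delay is 10 samples (10 % of a
stride) and the temporal exclusion (Theiler) window for the
nearest-neighbour search is half a stride — both conventional values in
the gait literature; neither is prescribed by the estimator itself, and
sensitivity to them should be checked when comparing absolute λ_s values
across studies. For each point the nearest Euclidean neighbour outside
the exclusion window is tracked forward, and λ_s is the least-squares
slope of the mean log distance over 0–0.5 strides (curve horizon 10
strides). Ties in the neighbour search resolve to the earliest index.

Validation uses three oracles: a noiseless quasi-periodically sampled
limit cycle (flat curve, |λ_s| < 0.05 — the test period is irrational
relative to the sample grid, because an exactly commensurate period makes
all cycles sample-identical and nearest-neighbour distances collapse to
zero); the logistic map x ← 4x(1 − x), whose divergence rate ln 2 per
iterate is recovered within 10 %; and strict growth of λ_s with added
white-noise amplitude. On generated gait, λ_s is systematically higher in
the destabilised condition, driven by the belt coupling and the larger
aperiodic thorax motion.

## Foot-placement control model

For each step, the single-stance window runs from the swing leg's toe-off
to its heel strike. The pelvis (mean of left/right PSIS markers) is
expressed relative to the previous stance heel's position at its own
contact instant — a per-step constant origin that removes slow drift over
the belt. The velocity predictor is the within-step time derivative
(second-order `np.gradient`, one-sided at the window edges: the placement
instant is the last sample of the window, and a first-order edge
difference would bias the velocity there in proportion to the local
acceleration, which measurably attenuates the recovered coefficients).
When a belt-displacement signal is provided, its velocity is added,
recovering the belt-relative CoM velocity on the oscillating surface.

Predictors are resampled to 51 phase points (0–100 % of single stance)
and demeaned per phase point; the outcome (ML heel position at contact in
the same frame) is demeaned across steps, so the two-coefficient OLS
needs no intercept. Left and right steps are analysed separately — each
side's matrix is oriented "away from the stance foot", so the
coefficients share signs — and the headline curves are the per-side
averages. R²(t) is the explained-variance fraction; phase points with
collinear or zero-variance predictors are flagged NaN. The Fisher
transform is applied as `atanh(√R²)` (the transform needs an argument
inside (−1, 1), so it acts on the correlation scale; values are clipped
at 1 − 10⁻¹² to keep perfect fits finite). The foot-placement error is
the sample SD of the residual at the final phase point.

## EMG and MEP extraction

EMG is band-pass filtered 20–500 Hz with a 2nd-order Butterworth design
applied forward and backward (zero phase, effective 4th order). Ongoing
EMG is the rectified mean from 20 ms before to 10 ms after the pulse,
window endpoints inclusive (61 samples at 2000 Hz), with the single
sample at the stimulation instant removed; the measure is therefore
exactly invariant to the artifact sample's value in the filtered trace.
The absolute MEP is the peak-to-peak amplitude 10–60 ms post pulse.
MEP gain divides the absolute MEP by the ongoing EMG; at zero background
the gain is flagged missing (NaN) rather than infinite, and missing gains
are simply omitted from smoothing. Millisecond windows convert to samples
by rounding.

Coil displacement: least-squares rigid-body transforms (Kabsch/SVD) map
the static calibration of the helmet marker set and of the head marker
set to each stimulation instant; each transform predicts the position of
the calibrated virtual marker at the coil centre, and the head-predicted
minus helmet-predicted difference is reported as |vertical| and the
Euclidean norm of the two horizontal components. A pulse is excluded iff
vertical > 5 mm **or** horizontal > 10 mm (strict inequalities; values
exactly at a threshold survive), and a participant is flagged for
exclusion below 100 surviving pulses in either condition.

## Cyclic smoothing

Sparse per-pulse outcomes y_i at cycle percentages p_i are smoothed onto
a 0.5 % cyclic grid by Nadaraya–Watson regression with the Von Mises
kernel w(θ_t, θ_i) = exp(κ cos(θ_t − θ_i)) / (2π I₀(κ)): the kernel is
convolved with the outcomes and divided by the summed kernel density, so
constant inputs give constant outputs. κ follows from the Gaussian
equivalence κ = 1/σ_rad² (large-κ limit); σ = 2 % of the cycle gives
κ ≈ 63.3, rounded to 60 in the conventional rounded mode, which is the
default used by the pipeline. The kernel is evaluated directly at the
grid points — mathematically identical to convolving a binned signal at
this resolution — and log-I₀ scaling avoids overflow at large κ.

A grid point's estimate is flagged valid when at least 6 samples lie
within a circular distance of 2σ ("within two standard deviations" read
as an arc of ±2σ; at the typical density of ~2 samples per 1 % of the
cycle this expects ≈ 16 samples, so healthy recordings are valid almost
everywhere). Group curves are formed either unweighted (plain mean per
grid point) or density-weighted, where each participant's contribution is
proportional to their local kernel density (ŵ_p(t) sums to 1 over
participants at every t).

## Cluster-based permutation testing

Scalar outcomes use classical two-sided paired t tests. Cyclic curves use
pointwise paired t statistics — classical, or weighted with
d̄_w = Σ ŵ_p d_p and s²_w = Σ ŵ_p (d_p − d̄_w)² / (1 − Σ ŵ_p²),
SE = √(s²_w Σ ŵ_p²), which reduces exactly to the classical paired t at
equal weights (tested to 10⁻¹²). Points with |t| above the two-sided
Student quantile (α = 0.05, df = n − 1) form clusters of consecutive
same-signed points; runs touching both ends of the grid merge into one
wrapped cluster. Ties exactly at the threshold are not significant.

The null distribution records, for each of 1000 permutations, the maximal
absolute cluster mass after exchanging the two condition labels within
each participant with probability ½ (the sign-flip scheme for paired
designs; the identity permutation can be drawn). Because smoothing acts
per participant-condition block, exchanging a participant's condition
labels at the stimulation level and re-smoothing yields the same two
curves swapped — so the curve-level sign flip implements the raw-data
permutation exactly, at a fraction of the cost. Cluster p-values are the
fraction of null values ≥ the observed |mass|, floored at
1/n_permutations (0.001 at 1000 permutations); significance requires
exceeding the 95th percentile of the null. Degenerate zero-variance
differences produce a capped |t| = 10⁶ rather than an infinity.

Calibration on null synthetic data (15 participants, ~200 pulses each,
identical outcome distributions in both conditions) gives a family-wise
false-positive rate of ≈ 0.05 (asserted within [0.02, 0.09] over 200
datasets of 500 permutations), and power increases monotonically with a
multiplicative effect injected over a 20 % window of the cycle (effect
factors 1.03 / 1.08 / 1.15 were chosen to span the rising part of the
power curve; larger effects saturate at power 1).

## Synthetic-data generator

The generator produces the study conditions the analysis assumes, with
stored ground truth for every recoverable quantity.

**Perturbation.** The destabilised belt signal is a sum of 12 sinusoids
with random incommensurate frequencies in 0.1–1.0 Hz, rescaled exactly to
the 100 mm peak-to-peak default and centred. Any band-limited
pseudorandom law would do; the multi-sine is smooth and exactly
rescalable.

**Kinematics.** Right heel strikes accumulate Gaussian stride durations
(steady: 1.10 ± 0.02 s; destabilised: 1.05 ± 0.045 s — destabilisation
shortens strides and raises their variance), quantised to the 100 Hz
marker grid so stored event times coincide with what sampled data can
express; left events sit mid-cycle. Heel heights follow a smooth periodic
template (small 1−cos stance lift, a broad swing-clearance bump and a
sharper heel-off rise) whose per-cycle minimum defines heel strike and
whose acceleration maximum (at ≈ 67 % of the cycle) defines toe-off; the
template shape is a free design choice and the heels carry no added
marker noise, so event recovery is exact by construction. The pelvis is
generated directly as the CoM proxy (no full-body CoM is synthesised).

**Foot placement.** A smooth multi-sine CoM-deviation process dev(t)
(0.1–1.2 Hz; steady SD 8 mm, destabilised 14 mm) drives placement: each
step's true state is the belt-relative pelvis deviation at contact
(position: dev − 0.3·pert, the body following 70 % of the belt motion;
velocity: dev′ + 0.7·pert′, which the analysis' belt-velocity correction
recovers), oriented away from the stance foot and demeaned per side. Each
contact sits one step width (steady 100 mm, destabilised 120 mm) plus
β_pos·Δpos + β_vel·Δvel + ε + η beyond the previous contact
(β_pos = 1.2 mm/mm, β_vel = 0.15 mm·s/mm, ε = 5 mm, and η an independent
width noise of 5/9 mm per condition). The pelvis rides between contacts
with zero relative lateral velocity at contact, so the extracted
predictors at the placement instant equal the stored states exactly; the
deviation process is a multi-sine rather than filtered noise because the
stored finite-difference velocity truth and the analysis' re-derivative
only agree when the sample path is smooth. Realised step-width variance
is the sum of the control-law and noise contributions, which is what
makes the destabilised condition more variable.

**EMG and MEPs.** Each muscle's trace is a phasic envelope (Von
Mises-shaped bumps over the cycle at textbook activation phases, baseline
8 µV; destabilised activity scaled ×1.2) multiplied by 20–450 Hz noise
normalised to unit rectified mean, so ongoing-EMG extraction recovers the
envelope. Pulses are scheduled 3–5 strides apart at a uniform random
delay after a right heel strike (≈ 270 pulses per 20-min trial). Each
pulse injects a damped sinusoid (8 ms period, 15 ms decay — an arbitrary
smooth waveform; only the 10–60 ms window matters downstream) at 12 ms
latency with peak-to-peak amplitude gain(cycle %) × envelope(cycle %)
(gain 6.0, 10 % relative jitter), plus a one-sample artifact spike at the
stimulation instant. A condition effect for power studies is injected as
a multiplicative gain factor over a configurable cyclic window.

**Coil displacement** is generated per pulse: sub-threshold baselines,
with a configured fraction of pulses pushed over a randomly chosen
threshold. **The motor-threshold staircase** follows the standard hunt:
start at 35 % stimulator output, +5 % until ≥ 5/10 pulses evoke an MEP
(terminating at a ceiling), −2 % until the criterion fails, then +1 % to
the lowest consistently effective intensity; if the criterion already
holds at the start, the start is the threshold; the test intensity is
110 % of threshold.

All randomness flows from one root seed through named child streams (per
condition, per muscle, per purpose), so identical configurations are
bit-identical.

### What the generator does not emulate

No musculoskeletal dynamics, ground-reaction forces, soft-tissue or
marker noise, realistic EMG spectra beyond band-limited noise, gap-filled
or missing markers, or electrode artifacts other than the stimulation
spike. Passing the closed-loop tests therefore shows that the estimators
are correct for data satisfying the stated models — not that real
recordings satisfy them. In particular the exact β recovery relies on the
constructed pelvis–foot geometry; on real data the CoM proxy, marker
noise and soft tissue add bias the synthetic loop cannot expose.

## Problem sizes

The test suite and the acceptance script run scaled-down versions of the
study: 60–180 s trials instead of 20 minutes, 2–15 participants,
40–150-stride windows, 300–1000 permutations, and 10–20 seed replicates
per claim. These sizes were chosen so each statistical check retains
enough replicates to be meaningful while the whole validation completes
in minutes on one CPU; the full-size defaults (20-min trials, 15
participants, 150-stride windows, 1000 permutations) remain the package
defaults used when nothing smaller is requested.

## Known limitations

- Absolute λ_s values depend on the unreported embedding delay and
  Theiler window conventions; only within-study comparisons are safe.
- Whether the Fisher transform should act on R or R² is ambiguous in the
  field's usage; both are monotone in R², so cluster inference on the
  transformed curves is ordinally unaffected by the choice made here.
- Low-density grid points are flagged rather than dropped; downstream
  group statistics currently use all grid points, so sparse phases are
  noisier rather than absent.
- The weighted t's degrees of freedom are approximated as n − 1
  regardless of weight dispersion (exact at equal weights; slightly
  liberal at extreme weight concentration).
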