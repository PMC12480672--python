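# Methods

This note records the models, estimators and design choices behind
`copdmon`, in the spirit of a statistical software methods appendix: what
each stage assumes, which knobs matter, and what the synthetic-data tests
do and do not demonstrate about real wearable data.

## Speech segmentation cascade

Recordings are processed in five fixed stages. Silence removal slides a
50-ms frame and keeps frames whose RMS intensity is at or above
−20 dB *relative to full scale* (amplitude 1.0); the reference is a
package choice — it makes the gate deterministic and device-independent,
at the cost of assuming sensibly normalized input levels. Non-silent
intervals are tiled with 2-s windows at a 1-s step (trailing remainders
dropped; all frame/window intervals are half-open `[start, end)`). A
frame scorer maps each 20-ms frame to a speech probability; probabilities
are binarized at 0.7, consecutive speech frames merge into utterances,
utterances shorter than 250 ms are discarded, and a window counts as
speech when its summed utterance time strictly exceeds 75% of the window
(1.5 s). Because consecutive windows overlap 50%, utterance spans from
retained windows are unioned on the recording timeline before any
duration bookkeeping, so no second of speech is counted twice. How
overlapping retained windows should be de-duplicated is genuinely
underdetermined in field practice; union semantics is our choice and is
recorded here.

The voice-activity detector is pluggable (any callable mapping a 20-ms
frame to a probability in [0, 1]). The bundled `EnergyPeriodicityVAD`
multiplies a logistic intensity term (centred at −30 dBFS, 5-dB scale) by
an autocorrelation-periodicity term; it is deterministic, adequate for
synthetic and clean speech, and deliberately *not* a substitute model of
conversational speech — running the pipeline on real-world audio calls
for a pretrained neural detector plugged into the same interface.

## Voice features

**Cycle tracking.** A frame-wise normalized autocorrelation F0 track
(40-ms frames, 10-ms hop, search range 60–400 Hz, voicing threshold
r ≥ 0.45) guides waveform peak picking. Normalization divides each lag's
correlation by the energies of the two overlapping chunks, so perfect
periodicity scores 1 regardless of frame length. Two octave safeguards
matter in practice: among autocorrelation local maxima within 0.04 of the
global maximum the smallest lag wins, and frame estimates that sit at
1/2×, 1/3×, 2× or 3× of the track median are folded back onto it. Peak
positions get parabolic sub-sample refinement; cycle amplitude is the RMS
over one period starting just before each peak, with fractional-sample
window edges via cumulative-energy interpolation — a measure invariant to
where the cycle falls on the sample grid, which a raw peak-height reading
is not.

**Perturbation suites.** The printed feature list names the standard
voice-analysis measures without formulas, so the definitions are frozen
here: local jitter = mean |T_i − T_{i−1}| / mean(T); absolute jitter in
ms; rap/ppq5 the 3-/5-point quotients (mean absolute deviation from the
centred moving average over the overall mean); ddp = 3·rap identically,
and the shimmer family the amplitude analogues with dda = 3·apq3.
Minimum track lengths: 3 cycles (5 for ppq5, 11 for apq11); shorter
tracks yield missing values.

**HNR.** Per voiced frame, 10·log10(r/(1−r)) at the detected period,
averaged, with a 60-dB ceiling. When 1−r falls below 1e−5 the frame is at
the estimator's numerical resolution and reports the ceiling — a pure
sine therefore reports exactly 60 dB.

**Formants.** The segment is resampled to 9 kHz and fitted with one
Burg-method LPC model of order 14; complex roots with bandwidth < 600 Hz
and frequency in (90, fs/2−100) Hz are resonance candidates and the four
lowest are F1–F4. Burg on the whole segment (no window) proved less
biased than framewise autocorrelation LPC against the generator's known
resonators; analysis rate and order were selected on generator output for
minimum worst-case error. Derived quantities use the quarter-wave
resonator model with speed of sound c = 35,000 cm/s (configurable):
Δf is the least-squares spacing (regression of F_i on (2i−1)/2 through
the origin), fdisp = (F4−F1)/3, fitch_vtl the mean of (2i−1)c/(4F_i),
vtl_delta_f = c/(2Δf), mff the geometric mean, and pF the mean
standardized deviation from reference formant means/SDs — by default the
processed cohort's own distribution, configurable to external norms.

**Syllable nuclei.** Intensity peaks (prominence ≥ 2 dB) above the
segment's median intensity on voiced frames count as nuclei; a voiced
region with no internal dip counts once. Pauses are unvoiced or
low-intensity runs ≥ 0.3 s. Speech rate and pause rate divide by the
segment duration; phonation time is the fraction of the segment covered
by syllabic regions.

**Daily aggregation** is the unweighted mean over segments with pairwise
deletion of missing values; mean/std F0 instead pool all voiced-frame F0
estimates of the day, so cross-utterance pitch variation is retained in
std F0. Features are computed per merged utterance (not per 2-s window)
before averaging; this choice is recorded in output metadata.

## HRV and activity

Streams split at any inter-sample gap exceeding 1.5 × the nominal 1-s
period; runs shorter than 45 s are dropped to keep the low-frequency HRV
band (0.04–0.15 Hz) observable. Each sample's RR = 60000/HR (each 1-Hz
sample is treated as one NN interval — beat-level intervals are not
reconstructable from 1-Hz vendor output). The range filter keeps
[350, 1200] ms inclusive; successive-difference pairs never bridge a
removed sample or a segment boundary (configurable), which avoids
fabricating large spurious differences. SDNN uses the sample (n−1)
denominator; pNN20 counts |ΔNN| > 20 ms strictly. Daily values are
unweighted means over segments. Step counts pass through as daily
totals; multiple records per day sum, negative counts are rejected.

## Outcomes

Majors (sputum-colour change, increased breathlessness, increased sputum
amount) score 5; minors (cold, fever, increased wheezing, sore throat,
worsening cough) score 1. Exacerbation-day labelling uses score ≥ 6 on
≥ 2 consecutive calendar days (an inclusive threshold; a strict ">"
variant is exposed as a flag because the two phrasings circulate in the
literature). Missing diary days break consecutiveness — no
carry-forward, deliberately conservative. The day-level binary
exacerbation-state flag, not episode onset, is the outcome modelled
downstream; episodes are also reported with identifiers.

## Statistical models

Linear mixed models (symptom score) are fitted by REML via statsmodels
`MixedLM` with a random intercept per participant — the simplest
structure consistent with per-term reporting; no random slopes.
Inference is Wald: z-based p-values and 95% CIs. statsmodels does not
implement Satterthwaite degrees of freedom; at the day-level sample sizes
this package targets (thousands of rows, tens of participants) the
difference is negligible, and the choice is documented here rather than
hidden. Optimization retries lbfgs/cg/powell when the random-intercept
variance sits on the boundary, and the model frame is canonically sorted
so estimates are exactly invariant to input row order.

The exacerbation outcome uses a mixed-effects logistic model fitted by
variational Bayes (`BinomialBayesMixedGLM`); estimates are posterior
means exponentiated to odds ratios, with CIs and p-values from the
Gaussian posterior approximation. This is the one place a Bayesian
approximation stands behind a frequentist-style report; the linear-model
route is cross-checked against R lme4 in the test suite, and the
logistic route's planted-effect behaviour (protective OR for a planted
negative effect, null coverage) is exercised on synthetic cohorts.

z-scoring is cohort-pooled (not per-participant), configurable. All
models adjust for age, sex and smoking history; when a small subset
cannot support all three (participant-level collinearity), aliased
confounders are dropped automatically and recorded, while an aliased
term of interest raises. The univariate screen reports raw p-values with
star tiers (*, **, *** at .05/.01/.001) and no multiple-testing
correction by default, matching the reporting convention it emulates; a
Benjamini–Hochberg option exists. VIF pruning computes 1/(1−R²) for each
term regressed on the others (interaction columns included as plain
products of z-scored components), removes the worst term while the
maximum is ≥ 20 — an unusually permissive cutoff, kept as the default
deliberately — with ties broken by removing the lexicographically last
term. The multivariate design contains covariate mains, HRV×steps
two-ways, feature×covariate two-ways and feature×HRV×steps three-ways,
named with the `a:b:c` colon convention. Moderation strata are exactly
`< m−s, [m−s, m), [m, m+s), > m+s` from the cohort mean and SD; a value
exactly equal to m+s falls in no stratum (measure-zero for continuous
moderators), and strata with fewer than 20 rows or 2 participants are
reported as empty rather than fitted.

## Synthetic data: what it emulates and what it does not

**Voice.** An impulse-train source through four cascaded second-order
resonators (default 500/1500/2500/3500 Hz, bandwidths 150–240 Hz).
Glottal periods are T0(1 + j/100·z_k) and cycle amplitudes
A0(1 + s/100·w_k) with z, w standard normal clipped at ±3 (guaranteeing
positive periods); impulses are placed with windowed-sinc sub-sample
precision so realized cycle energies do not depend on grid alignment.
Additive white noise at a configurable SNR (default 25 dB) controls the
achievable HNR; pauses carry noise 60 dB below voiced RMS. The generator
records its realized period/amplitude lists, which are the oracle for
the extractor: note that for i.i.d. Gaussian perturbations the expected
local jitter is (2/√π) ≈ 1.128 times the planted percentage, so recovery
is judged against the realized sequences (and by correlation against the
planted dial). The generator does not attempt conversational content,
coarticulation, or ambient acoustic scenes — extractor accuracy shown
here bounds what clean speech permits, not what noisy free-living audio
delivers.

**Heart rate.** The RR process is AR(1) (φ = 0.9) with stationary mean
and SD equal to the planted mean RR and SDNN; a configurable fraction of
steps is forced beyond ±20 ms to control pNN20. Samples arrive in 120-s
bursts mirroring the 2-min-on/8-min-off duty cycle, with dropout removed
in contiguous gaps. Heart rate is emitted as exact floats, so
HR→RR→metrics is an exact round trip against the recorded truth; vendor
integer rounding is not modelled.

**Cohort.** Each participant-day draws z-scored feature values; latent
severity sums planted fixed effects, product-term interaction effects,
confounder terms (age uniform 55–93 standardized, one-third female,
smoking 22/11/67% current/never/ex), a N(0, σ_b) random intercept
(default 0.5) and unit Gaussian noise (`residual_sd`). Severity maps to
the eight symptoms through per-symptom logistic links; majors get steeper
slopes (2.0) and higher thresholds (1.5/1.7/1.9) than minors (1.5;
1.0–1.8), calibrated so a null cohort's daily score averages ≈ 1 point
with a heavy zero mass — the regime typical of elderly COPD cohorts —
and score-≥6 days concentrate at high severity, exercising exacerbation
detection. Per-stream missingness is independent Bernoulli per day; real
missingness is patterned (device off-wrist, charge cycles), so the
generator supports power and calibration claims, not missing-data-
mechanism claims. Degenerate configurations (all scores zero or all
maximal) are rejected.

**Study conditions used by the validation suite.** Parameter-recovery
tests use 20 seeded voices (3 s, F0 100–195 Hz, jitter ∈ {0.5, 1, 2}%,
shimmer ∈ {2, 5, 10}%); mixed-model recovery uses 50 cohorts of 20
participants × 100 days with a planted β = −0.4; type-I calibration uses
200 null cohorts at the same size; moderation uses the planted
(−0.3, +0.5) configuration above. The full-fidelity synthetic study that
feeds the end-to-end run is 3 participants × 8 days with two 6-s
recordings per speech day — a smoke-scale cohort chosen so a complete
raw-streams-to-reports run stays in the tens of seconds while touching
every stage.

## Numerical conventions and degenerate inputs

Empty waveforms, empty segments and negative step counts raise; unvoiced
audio yields empty tracks and missing features rather than errors; days
with no qualifying data are absent from outputs, not imputed. Constant
columns cannot be z-scored and raise naming the column. All randomness
descends from a single top-level seed through `numpy.random.SeedSequence`
spawning, and every pipeline output is hash-stamped in the run manifest;
the variational logistic fit pins the legacy global RNG it consumes so
identical data give identical fits.

## Known limitations

The bundled VAD is an energy/periodicity heuristic, not a speech model.
Formant estimation is tuned on resonator-generated vowels; real
conversational audio has time-varying tracts the single-model-per-segment
approach blurs. The logistic mixed model's variational CIs are
approximate (they ignore posterior correlation between fixed and random
effects). The moderation analysis stratifies rather than fitting
simple-slope contrasts, mirroring the reporting style it reproduces; the
two approaches agree qualitatively but not numerically. None of the
printed clinical coefficients from the motivating study can be reproduced
here — they require the undeposited patient dataset — so validation rests
on planted-truth recovery, analytic constants, and calibration under the
null.
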