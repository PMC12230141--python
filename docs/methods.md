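# Methods

## The measurement problem

A tone appearing inside ongoing threshold-equalizing noise (TEN) evokes an
acoustic change complex (ACC): a negative deflection (N1) ~100 ms after the
change and a positive one (P2) ~200 ms after it. Detecting the ACC
objectively, SNR by SNR, yields an electrophysiological analogue of the
behavioural TEN test for cochlear dead regions: in a dead region the tone is
heard only by off-frequency listening, so the ACC threshold (in dB SNR re
the TEN level) is elevated. The package implements the whole chain — signal
generation or ingestion, preprocessing, three detectors, threshold
estimation, dead-region rules, and agreement statistics — as seeded,
replayable stages.

## Recording design

All timing lives in `StimulusDesign`: noise onset at 0 s, tone at 1.0 s for
0.5 s, stimulus offset at 1.5 s, epochs spanning [−0.1, 2.5) s at 2048 Hz,
inter-stimulus interval 1.5 s (a 3-s sweep), 120 sweeps per condition, SNR
grid 0–15 dB in 3-dB steps, tone frequencies 1 and 4 kHz, two repetitions.
Analysis windows (absolute seconds): N1 1.080–1.120, P2 1.170–1.230,
response RMS 1.080–1.230, noise floor 1.580–1.730 (80–230 ms after the
stimulus offset, a no-stimulus period). Epoch length in samples is
`round(2.6 × fs)` (5325 at 2048 Hz — 2.6 × 2048 = 5324.8 is non-integral);
all windows are half-open `[start, stop)` sample ranges with indices rounded
from absolute times. These conventions are deterministic and identical in
the generator and the analysis, so round-trip tests are exact.

## Synthetic EEG generator

The generator emulates the *statistical* structure of the recordings, not
their audio:

- **Morphology.** The ACC template is a biphasic Gaussian-windowed
  deflection: a negative lobe at 1.100 s (FWHM 30 ms) and a positive lobe at
  1.200 s (FWHM 50 ms), amplitudes split 60/40 of the nominal N1-P2
  peak-to-peak, hard-zeroed outside [1.0, 1.4] s. At 100-ms lobe separation
  the overlap error on the peak-to-peak is < 0.05 %. Real waveshape is not
  standardised across labs; this is a deliberate idealisation.
- **Amplitude model.** N1-P2 amplitude = `max(A_max − k·(15 − SNR), 0)`,
  with per-frequency `A_max` (defaults 6 µV at 1 kHz, 4 µV at 4 kHz) and
  slope `k = 0.35 µV/dB`; multiplied by a habituation factor (default 0.8)
  on the second repetition and a contralateral projection factor (default
  0.6) on the contra channel. A dead-region participant's amplitude is
  forced to zero below a configurable SNR. Defaults were chosen once so that
  detection transitions across the 0–15 dB grid under the default noise —
  they are free parameters of the simulation, not estimates of any
  particular dataset.
- **Background EEG.** Gaussian noise shaped to ~1/f power over 0.5–35 Hz
  plus an alpha bump at 10 Hz (fraction 0.2), scaled to an epoch RMS of
  8 µV by default — a plausible 1–30 Hz scalp level that leaves ~0.75 µV in
  a 120-sweep average. Per-epoch latency jitter (SD 5 ms) smears the
  average slightly, as arousal drift would.
- **Artifacts.** With probability 0.05 an epoch's background is scaled
  ×10, mimicking movement artifacts the 2-SD RMS screen should catch.
- **Cohorts.** `simulate_cohort` draws per-participant amplitudes and noise
  from lognormal spreads (σ = 0.25), assigns behavioural signal-to-TEN
  ratios uniformly in −6…2 dB, and records one seed per recording cell in a
  manifest; epochs are regenerated lazily from those seeds, so cohorts of
  any size are bookkeeping until data are requested. Attrition (missing
  recordings) is strictly opt-in.

What the generator does **not** emulate: real electrode noise spectra,
eye-blinks and their frontal topography, non-stationary arousal, onset and
offset responses to the TEN itself, or any audio-calibration effects.
Passing tests therefore certify the *analysis logic* (calibration,
monotonicity, rule equivalence) — not performance on any specific clinical
population.

## Preprocessing

Mastoid channels are referenced to Cz and band-passed 1–30 Hz. The
"3rd-order Chebyshev II band-pass with 30 dB ripple" is realised as a
high-pass (stopband edge 1 Hz) cascaded with a low-pass (stopband edge
30 Hz), each 3rd-order with 30 dB stopband attenuation, because a single
3rd-order band-pass is under-specified. The cascade is applied
forward-backward (zero phase) so the absolute N1/P2 windows stay valid;
effective stopband attenuation consequently doubles, and the passband
magnitude is the squared single-pass response (exposed by
`filter_response` for inspection). Pre-cut epochs are filtered per epoch
with 1 s of edge padding.

Artifact rejection is a single pass: epoch i is rejected iff
`RMS_i > mean(RMS) + 2·SD(RMS)` over all epochs of the recording (sample
SD). The looser literal reading "RMS larger than two standard deviations of
their mean value" admits `RMS > 2·mean`, which almost never rejects
anything for unimodal RMS distributions and was discarded as degenerate;
the rule in force is recorded in the rejection report. Rejection runs
per recording (the two repetitions are never pooled). Averages are
arithmetic means over accepted epochs; a recording with zero accepted
epochs carries no waveform and every detector maps it to "inconclusive".

The synthetic path generates epochs already inside the analysis band, so
the pipeline's synthetic route goes generator → rejection → averaging →
peaks; with noise, jitter and artifacts disabled this chain recovers an
injected amplitude to ≪ 1 % (the acceptance script measures it). Filtering
a template through the band-pass additionally costs a few percent of peak
amplitude (passband droop) — that droop belongs to the filter, not the
estimator, and is excluded from the recovery check.

## Detectors

- **RMS.** statistic = RMS(1.080–1.230 s) / RMS(1.580–1.730 s); present iff
  ≥ 1.5 (boundary inclusive). The numerator is the *waveform segment* RMS;
  a two-point "RMS of the N1-P2 amplitude", |N1P2|/√2, is available as
  `numerator="peaks"` since that reading is also defensible. A zero noise
  floor yields +∞ and a logged warning.
- **BSA.** statistic = 20·log₁₀(mean(a₁,a₂)/SD(a₁,a₂)) with the sample SD
  of two values (|a₁−a₂|/√2); present iff > 3 dB as printed. A
  `scale="linear"` switch implements the alternative linear-ratio ≥ 3
  reading. Equal amplitudes give +∞ (present, logged); a non-positive mean
  gives −∞ (absent).
- **Bootstrap.** Accepted epochs from both mastoids are pooled (or one
  mastoid, for per-ear decisions). Plain with-replacement resampling
  preserves the phase-locked response and cannot form a null, so the null
  is built by giving every drawn epoch an independent random ±1 polarity
  flip — the evoked component cancels in expectation while the noise
  spectrum is untouched. Each of 499 iterations draws 240 epochs, averages,
  and computes (N1-P2)/(noise-floor RMS); the empirical 2.5/97.5 %
  quantiles form the interval and the decision is one-sided
  (observed > upper bound), because only response-larger-than-noise is
  meaningful. By linearity of the mean the null averages are computed only
  over the analysis-window columns — an exact shortcut that makes one
  decision cost ~50 ms. A `mode="plain"` switch provides the
  estimate-uncertainty reading (present iff the observed statistic's lower
  quantile exceeds 1). Type-I calibration on pure-noise recordings sits at
  the nominal one-sided 2.5 % (the acceptance script re-measures it on 500
  recordings).

The bootstrap numerator (peak-to-peak over noise RMS) and the RMS
detector's peak mode differ by exactly √2 by construction; a test pins that
conversion so the two statistics share one convention.

## Threshold rule and dead-region screens

The ACC threshold is the lowest grid SNR L with outcome present at L,
absent at L−3 dB and present at L+3 dB. Grid-edge clauses are vacuous
(L = 0 needs no absence below; L = 15 no presence above). Inconclusive or
missing neighbours make the corresponding clause vacuous and are flagged in
the result, but the threshold level itself must be a determinate
"present". Non-monotone patterns are evaluated literally — lowest
qualifying L wins, no smoothing — and the implementation is proven equal to
a brute-force evaluation over all 2⁶ present/absent patterns.
"Undetermined" is a first-class outcome and propagates to the agreement
analyses as missing.

Dead-region rules: ACC rule positive iff the threshold is determined and
≥ 12 dB SNR (boundary inclusive); behavioural TEN rule positive iff the
masked threshold is ≥ TEN level + 10 dB *and* ≥ absolute threshold + 10 dB.
An undetermined ACC threshold yields an undetermined flag, never "false".
On normal synthetic cohorts with realistic noise some individual thresholds
do exceed 12 dB — the RMS and BSA statistics are scale-invariant, so their
false-present rates do not shrink with quieter EEG — which is precisely the
false-positive concern the 12-dB screening rule raises.

## Behavioural staircase

The masked-threshold simulator is a 2-down/1-up track, 4 dB down / 2 dB up,
start 70 dB HL, against a logistic psychometric function (infinite slope =
deterministic listener). The track stops at the later of 8 reversals and 60
trials; the threshold is the mean of the last 4 reversal levels; a hard cap
(400 trials) flags non-convergence, e.g. a listener pinned at a level
floor. The published procedure does not state a read-out; mean-of-last-
reversals is the field's default, and the asymmetric-step equilibrium is
verified against a brute-force Markov-chain stationary distribution in the
tests.

## Agreement statistics

Bland–Altman: bias = mean difference, LoA = bias ± 1.96·SD; CI of the bias
= bias ± t(n−1, 0.975)·SD/√n; CI of each limit = limit ±
t(n−1, 0.975)·√(3·SD²/n). For repeated measurements of a constant quantity
(here: ipsi/contra thresholds as replicates of a participant) the SD is
corrected with one-way ANOVA components on the differences —
`SD² = σ²_between + MS_within`, with σ²_between = (MSB − MSW)/m₀ floored at
zero — which requires subject labels; without labels the plain SD is used
with a warning. Coefficient of repeatability = 2·SD of test-retest
differences; the published coefficients follow from published limits via
SD = (upper − lower)/(2·1.96), which the acceptance script recomputes. The
published tables themselves obey the midpoint symmetry bias =
(LoA_lower + LoA_upper)/2 to printed precision, whichever variance variant
produced them.

CCC: Lin's estimator with n-denominator moments,
ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), CI via the z-transform variance
of Lin (1989, corrected 2000) — the convention of the standard
epidemiology tooling — with a percentile bootstrap available behind
`n_boot`. Degenerate inputs (|ρ_c| → 1, n < 4) collapse the CI to the
point estimate.

Method comparisons in the pipeline use the first repetition of the RMS and
bootstrap thresholds and the overall BSA threshold (one threshold per
channel from the repetition pair), mirroring how a single clinical
measurement would be validated; repeatability uses repetitions 1 vs 2.
Pairing is (participant, channel) within frequency.

## Pipeline, seeds, formats

`run_pipeline` drives cohort simulation, per-recording preprocessing, all
three detectors, threshold estimation, dead-region classification and the
agreement tables, writing CSVs (header row, empty cell = missing) plus a
YAML manifest holding the config snapshot, the per-stage seeds and the file
registry — enough to replay a run bit-identically. One master seed fans out
as `(seed × 2654435761) XOR crc32(stage_name) mod 2³¹`. Epoch containers
are NumPy `.npz` files; continuous EDF/BDF enters through `mne` with a
config-driven channel map and is converted to µV.

## Problem sizes and numerical tolerances

Monte-Carlo checks are sized for a single CPU: bootstrap type-I
calibration uses 500 recordings at full fidelity (120+120 epochs, 240×499
resampling, exact windowed averaging); detection-probability monotonicity
uses 60 runs per SNR level at 512 Hz with the full 120 sweeps and 199
bootstrap iterations, with a two-standard-error slack on step decreases;
limits-of-agreement coverage uses 10⁴ Gaussian differences (±0.01);
staircase convergence uses 400 seeded tracks against the Markov-chain
equilibrium (±2 dB). Peak-to-peak template recovery tolerates 1 %
(lobe-overlap and sample-centre quantisation); window RMS identities are
asserted to 1e−9.

## Known limitations

- The generator's amplitude/noise parameters are stand-ins, not estimates
  of any study's data; absolute detection rates on synthetic cohorts should
  not be read as clinical sensitivity/specificity.
- The replicate-variance correction assumes the underlying threshold is
  constant within participant across channels; if ipsi and contra
  thresholds differ systematically, the corrected SD is inflated.
- The CCC CI formula is first-order; for n < ~10 it is approximate, and the
  bootstrap option is preferable.
- The polarity-flip bootstrap loses power when a large response inflates
  the null spread (each flipped epoch carries ±template); this is inherent
  to response-destroying resampling and is visible as sub-unity detection
  probability at the top of the SNR grid in the Monte-Carlo.
- Latency statistics are deliberately out of scope; peak latencies are
  reported but not tested as detection parameters.
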