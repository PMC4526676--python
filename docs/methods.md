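# Methods

`ultracoll` analyzes auditory responses along the mouse ascending pathway —
auditory nerve (AN), dorsal cochlear nucleus (DCN), and the central nucleus
of the inferior colliculus (ICC) — to pure tones and ultrasonic
vocalizations (USVs), together with auditory brainstem responses (ABRs).
This note documents the models, statistics, defaults, and design choices,
and what the synthetic-data generator does and does not emulate.

Units are fixed package-wide: time in milliseconds on a single session
clock, frequency in kHz, sound level in dB SPL, extracellular voltage in
volts, ABR waveforms in microvolts.

## Signal chain

**Filtering.** All filters are 4th-order Butterworth applied
forward-backward (`sosfiltfilt`), i.e. zero-phase, so spike and ABR-wave
latencies are not biased by group delay. The spike band is 500–5000 Hz;
the analog multi-unit activity (aMUA) measure is band-pass 300–6000 Hz →
absolute value → low-pass below 300 Hz, with filter undershoot clipped at
zero. For an in-band sinusoid of amplitude A the aMUA settles at the
full-wave-rectified mean 2A/π; it is sign-flip invariant and homogeneous
of degree one in the input gain.

**Spike detection.** Putative spikes are absolute-value crossings of a
threshold expressed in robust noise SDs (median(|x|)/0.6745; default 4).
Each crossing is re-aligned to the |x| extremum within 0.6 ms after the
crossing: the raw crossing sample jitters with waveform phase and with the
pre-ringing that a zero-phase filter spreads backward in time, and
unaligned snippets fragment clusters downstream. A 0.7 ms dead time keeps
the earlier of two close triggers. Snippets span 0.4 ms before to 0.8 ms
after the trigger — wide enough for a full biphasic mouse action
potential.

**Sorting.** Snippets are projected onto the first three principal
components of the snippet covariance (eigenvector signs fixed so the
largest-magnitude coefficient is positive, making the projection
deterministic). Clustering is a full-covariance Gaussian-mixture EM fit
with the number of components chosen by BIC over 1..`max_clusters`;
snippets whose maximum responsibility falls below 0.5 are left unassigned
and count as cluster non-members. Cluster quality is gated by isolation
distance: the squared Mahalanobis distance, under the cluster's own mean
and covariance, of the n-th closest non-member (n = cluster size);
undefined when non-members are fewer than members. Units are accepted only
with isolation distance strictly greater than 20. A singular cluster
covariance is regularized by adding `1e-9·trace/3` to the diagonal.

## Per-unit statistics

**AN-fiber gate.** Units recorded on electrode tracks through the
cochlear nucleus are accepted as AN fibers when, for ~500 repetitions of
the CF tone at 30 dB above threshold: the CV of within-trial interspike
intervals is ≥ 0.5 (inclusive; intervals never span trial boundaries,
sample SD with n−1), the mode of the first-spike-latency histogram
(0.5 ms bins, ties to the earliest bin) is ≤ 5 ms (inclusive), and the
PSTH is primary-like.

**PSTH classification** is visual in practice; here it is a deterministic
rule set over a 1 ms-binned, ≥100-trial PSTH, applied in order: *onset* if
the sustained rate (mean of the last 25 ms) is below 20% of the peak;
*chopper* if the mean-removed autocorrelation of the first 25 ms has a
local maximum at a non-zero lag short enough for ≥3 regular peaks with
normalized height above 0.3; *pri-N* if primary-shaped but some bin within
2–6 ms after the peak falls below 50% of the peak and the rate then
recovers by ≥25% of the peak (a notch, distinguishing it from a plain
monotone decay); *primary* if the peak lies within the first 10 ms and the
sustained rate is ≥20% of the peak; otherwise *unclassified* (a valid
label). All thresholds are keyword parameters.

## Tuning

The frequency response area (FRA) maps baseline-subtracted mean rate over
the tone grid (2–90 kHz in 0.2-octave steps by default, 0.15 supported;
15–100 dB SPL in 5 dB steps), with the default count window (0, duration
+ 10] ms and the baseline estimated from the 50 ms preceding every tone
onset, pooled. Cells with no repetitions are flagged missing rather than
imputed.

**CF / threshold.** Per frequency, the threshold is the lowest level whose
cell is significant (one-sided z against the single-trial baseline SD at
α = 0.05 when ≥5 repetitions; mean excess > 2 baseline SDs otherwise) and
stays significant at the next two levels — the contiguity requirement
suppresses isolated false-positive cells. CF is the frequency of minimal
threshold; exact ties resolve to the grid frequency nearest the geometric
mean of the tied frequencies.

**F_max** is the highest frequency whose per-trial evoked counts, pooled
across all levels, exceed equal-duration pre-onset baseline counts by a
one-sided Wilcoxon rank-sum test. Because the grid spans ~30 frequencies,
the per-frequency level is Bonferroni-corrected by default
(α/n_frequencies): without the correction a unit with no tone response
would report the highest of its ~1.4 expected false positives instead of
an undefined F_max. The correction makes the estimate slightly
conservative near the response-area edge, where driven rates taper to
zero; F_max remains monotone in the generator's high-frequency extent.

## Vocalization responsiveness

For each of the 9 calls, per-trial spike counts in a driven window
(call duration, offset 5 ms after onset for response latency) are compared
with counts in an equal-duration window immediately before onset, by a
two-sided Wilcoxon rank-sum test — exact enumeration when both samples
have n ≤ 10 without ties, otherwise the normal approximation with tie and
continuity corrections. A unit is *responsive* when at least 3 of the 9
calls give p < 0.05 (with fewer calls the criterion scales as ⌈n/3⌉, with
a warning). Two-sidedness is the conservative choice; the latency offset
and the 2 ms SNR bin width are keyword parameters.

The response SNR is Var_bins(PSTH) / mean_trials(Var_bins(trial − PSTH)),
both variances population-style. It is invariant to adding a constant to
all trials and to common rescaling; under an additive signal+noise model
its expectation is σ²_signal/σ²_noise. A zero denominator with a non-zero
numerator is flagged infinite and excluded from the 9-call mean (with a
logged count) so population scatter against F_max stays finite.

## ABR analysis

Sweeps (25 kHz sampling, 0–10 ms) are band-pass filtered 100–3000 Hz;
sweeps whose peak |amplitude| exceeds 5× the median per-sweep SD are
rejected as artifacts (an error if more than half are rejected), and the
rest averaged. **Wave V** is the local maximum nearest 5.7 ms within
4.5–7.0 ms; amplitude is peak minus the nearest antecedent trough.
**Wave I** is the earliest local maximum in 0.8–2.8 ms that is (a)
*prominent* — amplitude above 5× the noise floor estimated from the
split-half difference waveform, in which the signal cancels exactly; the
largest noise excursion across the search band reaches 4–4.5 SD, so a
smaller multiplier would accept noise bumps — and (b) *repeatable* — the
nearest local maximum of each split-half average lies within 0.5 ms of
it. The same peak-minus-antecedent-trough rule is used for both waves.

**Threshold** replaces visual scoring with an objective criterion: the
lowest level whose wave-V amplitude exceeds 5× the noise floor (SD of the
averaged waveform at 8–10 ms), with every higher tested level also
supra-criterion. The multiplier is configurable; 5 sits above the
extreme-value ceiling of noise-only records, where a 2× criterion would
call thresholds at arbitrarily low levels.

## Population statistics

Responsive fractions carry a bootstrap percentile 95% CI (2.5th/97.5th
percentiles with linear interpolation; 10,000 resamples by default).
Two resampling units are implemented: *unit-level* (units with
replacement) and *animal-level* (animals with replacement, keeping each
drawn animal's units together). Animal-level resampling is the
appropriate default for multi-site array data, where units within an
animal are not independent and unit-level intervals are anti-conservative;
unit-level is the default for singly-recorded AN fibers. CF histograms use
log-spaced bins (1/3 octave) over 2–90 kHz, excluding undefined CFs with a
logged count. Across-animal comparisons use one-way fixed-effects ANOVA,
optionally on log2-transformed CFs.

## The synthetic-data generator

The generator supplies ground truth for every stage; it is
phenomenological, not biophysical.

* **Tuning**: a symmetric V in log frequency. Driven excess
  `r(f, L) = max_rate · max(0, 1 − |log2(f/CF)|/w(L))` with octave
  half-width `w(L) = q_sharpness · (L − threshold)/20`. Quantitative FRA
  bandwidths for mouse AN/ICC are not established; `q_sharpness` defaults
  to 0.3 (half-width 1 octave at 67 dB above threshold) and is exposed in
  every entry point.
* **Dynamics**: primary-like (exponential adaptation, τ default 5 ms, to a
  40% plateau), pri-N (primary with an 85% notch ~4 ms after response
  onset), chopper (4 ms-period modulation), onset (1.5 ms transient).
  The driven response begins one first-spike latency after stimulus onset
  and decays with a 2 ms constant after offset.
* **Spiking**: time-rescaled gamma-renewal process; gamma order k gives
  asymptotic ISI CV 1/√k, and an absolute refractory period (default
  0.8 ms) is imposed as integration dead time.
* **Calls**: single-component log-linear FM sweeps confined to 60–90 kHz,
  30–60 ms, at 80 or 90 dB SPL, with optional amplitude modulation. Real
  USVs are not resynthesized; the only property the analysis uses is
  energy confined to the call band. A unit's ground-truth
  `responds_to_calls` is the predicate "the call's frequency trajectory
  enters the response area at the call level", re-evaluable at any time.
* **Populations**: a `fraction_high_f` share of units get CFs uniform in
  log inside the call band; the rest are drawn from a station-profile
  log-normal (AN/DCN centered at 25 kHz, spread 0.6–0.7 octaves; ICC at
  48 kHz, 0.8 octaves, 60% in-band), redrawn until their response area at
  80 dB stays below 60 kHz so the ground-truth label cleanly tracks the
  high-frequency group. Default station fractions (AN 7.5%, DCN 9.5%,
  ICC 60%) correspond to the observed per-station responsive fractions.
* **Extracellular traces**: spike trains convolved with ~1 ms biphasic
  templates plus white Gaussian noise.
* **ABR**: each wave is a difference-of-Gaussians bump (trough 0.35 ms
  before peak, σ = 0.15 ms — comfortably inside the 100–3000 Hz analysis
  band, so filtering preserves amplitudes) normalized so that
  peak-minus-antecedent-trough equals the specified amplitude. Wave
  latencies default to 1.5/2.5/3.5/4.6/5.7 ms. The default amplitude maps
  make wave I fall and wave V rise with tone frequency, the signature of a
  central overrepresentation of high ultrasonic frequencies; per-sweep
  noise defaults to 2 µV SD.

**What passing tests show.** The generator reproduces the statistical
structure the analysis assumes — stationary renewal spiking, independent
trials, symmetric tuning, additive Gaussian noise, perfectly non-overlapping
stimulus windows. It does not emulate electrode drift, overlapping spikes,
non-stationary anesthesia states, inhibitory sidebands, spectral pinna
notches, or correlated noise across sweeps. Recovery results on synthetic
data therefore validate the implementation of the estimators, not their
robustness to those real-data complications.

## Problem sizes and numerical choices

Default simulated problem sizes are chosen to mirror the study design at
desk scale: 94 AN units, 200 DCN/ICC sites, 20 presentations per call,
2 repetitions per FRA grid cell, 500 ABR sweeps, 10,000 bootstrap
resamples (1,000–5,000 in the heavier simulation loops). Filters assert
band edges strictly inside (0, Nyquist). Spike-time grids use 0.25 ms
resolution for rate profiles. Degenerate inputs follow explicit contracts:
empty spike trains give zero counts everywhere, flat FRAs give undefined
tuning, monotone ABR waveforms give undefined waves, an all-significant or
all-null bootstrap degenerates to a point interval.

## Known limitations

* The GMM/BIC clusterer is a stand-in for density-based sorters; on
  heavily overlapping clusters it merges rather than splits, and the
  isolation-distance gate is the only protection against contamination.
* PSTH classification thresholds are calibrated on the generator's shape
  families; real units with intermediate shapes will land in
  `unclassified` more often.
* F_max's Bonferroni correction trades edge sensitivity for a controlled
  false-discovery behavior on unresponsive units.
* Animal-level bootstrap intervals are percentile intervals; with very few
  animals (< ~8) their coverage is approximate.
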