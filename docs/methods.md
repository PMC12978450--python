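# Methods

`callcode` re-implements, as a tested pipeline, an analysis of how caller
familiarity shapes zebra finch vocal responses and single-unit activity in
the premotor nucleus HVC. Because the original animal data are not
available, the package pairs every analysis stage with a seeded synthetic
generator whose effect sizes are known, so each statistical procedure can be
checked for calibration (no effect in, no detection out) and recovery
(known effect in, detection out).

## The synthetic experiment

**Playback schedule.** Each simulated bird hears one familiar (cage-mate)
and several unfamiliar stack-call playbacks in pseudo-random blocks: every
block repeats each stimulus 6 times in shuffled order, 20 blocks per daily
session, 4 sessions, 1 s of silence between playbacks (150 ms default clip)
and 60 s between blocks. Head-fixed recording sessions interleave the
stimuli for 48 trials per condition at the same 1 s gap.

**Vocal responses.** Each trial is answered independently with a
familiarity-dependent probability (defaults 0.117 familiar vs 0.090
unfamiliar). Answered trials draw a first-response latency from a normal
distribution truncated to the onset-to-onset span (defaults 306/354 ms mean,
246/264 ms SD). The truncated normal is the simplest two-parameter family
matching median/SD summaries. Responses that would collide with the next
playback are truncated at its onset, never dropped. A configuration whose
latency distribution puts less than 1% of its mass inside the inter-trial
span is rejected.

**Spiking.** Units are inhomogeneous Poisson processes with a 1.5 ms
absolute dead time. Two waveform classes are generated: narrow
(trough-to-peak 0.20 ± 0.03 ms, baseline 9.5 Hz; putative interneurons) and
broad (0.52 ± 0.06 ms, 1.9 Hz; putative projection neurons). Each playback
adds an evoked-rate profile: an alpha-function transient (rise 12 ms,
essentially over by 50 ms) plus a sustained component (relative amplitude
0.45) that rises over 30 ms and decays exponentially, outlasting stimulus
offset. Per unit, a log-normal gain jitter (SD 0.25 in log space) and an
exponential onset delay (mean 70 ms, capped at 300 ms) are drawn once and
shared across conditions; the delay spread reproduces the broad distribution
of peak-response times seen across real units, and matters statistically:
a homogeneous population makes every label permutation "decodable" and
grossly widens permutation nulls.

The familiarity effect lives in the narrow class: evoked gain 0.80
(familiar) vs 0.65 (unfamiliar) and sustained decay 170 vs 139 ms. These
four numbers were calibrated once so the generated per-unit condition means
match the study's reported response features (window-mean z ≈ 1.46 vs 1.14;
response-duration ratio ≈ 1.25) and then frozen. Broad units respond
equally to both conditions; with coupling enabled their evoked profile is
the narrow-class profile delayed by `coupling_lag_ms` (default 20 ms). An
optional per-stimulus log-normal "salience" multiplies both the behavioral
response probability and the narrow-class gain, installing ground-truth
behavior–neural coupling.

**Dead time and QC.** A purely Poisson train has a refractory-violation
index near 1 and would fail the conventional single-unit criterion
(violation index < 0.3); the default dead time equals the 1.5 ms refractory
window of the index so clean units pass deterministically, while the
separate contamination knob produces units that fail by injected doublets
(ISI mode), silenced session chunks (presence mode) or a drawn amplitude
cutoff (amplitude mode).

**Audio.** Call clips are harmonic stacks (8 harmonics, 1/h amplitudes,
attack–decay envelope) whose cluster structure comes from distinct
fundamentals (620/980/1450 Hz) and durations. Rendition jitter is 0.05% of
f0/duration: stack calls are highly stereotyped, and raw-waveform
similarity only reflects caller identity while renditions stay
phase-coherent across the clip.

**What the generator does not emulate.** Real spike trains have bursting,
slow non-stationarities and correlated noise across units; real calls have
frequency modulation and amplitude noise; real birds habituate across days.
Passing tests therefore demonstrate that the *procedures* are correct and
calibrated under the stated statistical structure, not that the biological
effect sizes are re-derived from real data.

## Analysis pipeline

**Behavior.** A "response" is the first contact-call onset after a playback
onset and before the next playback onset; later calls in the interval are
ignored for latency. The response-time distribution divides the
inter-playback interval into 50 ms bins (configurable; the bin width is a
package default, not a reported value) and counts the fraction of trials
whose first response falls in each bin, so the histogram sums to the
answered fraction. Per (bird, stimulus): peak response probability = max
histogram bin; response latency = median of first-response latencies;
latency variability = their SD (requiring ≥ 2 responses). Familiar vs
unfamiliar contrasts use the two-sided Wilcoxon signed-rank test on pairs of
one familiar row against the mean of that bird's unfamiliar rows (exact
null distribution at small n; all-zero differences are flagged and return
p = 1).

**Classification.** Features are min-max normalized per bird *before* any
subsampling or splitting. Each iteration randomly subsamples unfamiliar
rows to the familiar count, splits 50/50 with stratification, fits a random
forest (default 100 trees) and records test accuracy; the observed statistic
is the mean over iterations. The null permutes familiarity labels, reruns
the classifier several times per permutation (default 10) and stores one
accuracy — the mean over those reruns — per permutation. The p-value is the
proportion of null accuracies strictly exceeding the observed mean; chance
level is the null mean; the null's 95th percentile is the reported
confidence bound. Per-permutation means (not pooled single runs) are the
convention because only they reproduce the scale of reported chance bands
at realistic test-set sizes.

**Units.** QC keeps units with amplitude cutoff < 0.5, presence ratio
> 0.70 (fraction of 100 equal session chunks containing a spike) and ISI
violation index < 0.3 (violation rate relative to a chance-level
contaminating process, 1.5 ms refractory window). The published criterion
prints the opposite ISI direction ("> 0.3"), which contradicts the
conventional reading; the direction is configurable and defaults to
conventional. Waveform class = narrow if the trough-to-subsequent-peak
duration is < 0.35 ms, broad otherwise (boundary inclusive to broad);
waveforms without a post-trough peak are flagged unclassifiable.

**z-scored PSTHs.** Firing rates are binned at 10 ms, averaged over
response-free trials, smoothed by Gaussian convolution (kernel width 3
bins; a 51 ms window order-1 Savitzky–Golay filter is used for 1 ms display
series), and z-scored: z = (rate − baseline mean)/baseline SD, baseline
window −400 to 0 ms. Baseline statistics are estimated once per unit from
*all* of its response-free trials and shared by both conditions' z-scores,
with the SD rescaled by √(n_baseline/n_reference) to the noise scale of a
reference trial count common to every condition in the session (the
smallest condition's count), so z values stay comparable across conditions
even when their trial counts differ. The alternative — independent per-condition
baselines — puts a persistent multiplicative bias on every between-condition
comparison (the ratio of two noisy SD estimates multiplies the full evoked
response, which reaches several z), badly inflating the divergence and
decoding signals under the null. A unit is *responsive* if any bin in
0–400 ms deviates ≥ 2 SD from baseline (in either direction). Response
features over that window: mean z, max z, time of max (earliest bin on
ties) and response duration = total, not necessarily contiguous, time with
z ≥ 2.

**Population.** PCA is fit on the two conditions' (units × time) z-matrices
concatenated along time — units are features, time points observations — so
both trajectories live in one space; trajectories are smoothed only for
display. The familiar–unfamiliar Euclidean distance per 10 ms bin is taken
over the smallest set of leading PCs explaining ≥ 90% variance
(configurable). Its null shuffles the pooled per-PC baseline score values
(100 ms pre-onset, both conditions) 1000 times, recomputing distances from
the shuffled values; bins outside the null mean ± 2 SD are significant.
Note the rule is calibrated only when response-epoch variance matches
baseline variance; with evoked responses present the Poisson variance of
the response epoch exceeds the baseline's and the rule over-flags (see
limitations).

**Decoding.** Each responsive neuron contributes one familiar and one
unfamiliar trial-averaged z-vector over 0–400 ms (sub-windows selectable);
vectors are min-max normalized per neuron across the pair, and a linear SVM
(C = 1) is scored over stratified 90/10 splits with the same
permutation-null machinery. Feature-based decoding replaces the time series
with (mean z, max z, response duration). Mixed-model contrasts fit
`feature ~ familiarity` with a random intercept per bird and a variance
component for unit nested in bird (REML); singular or non-converged fits are
flagged, falling back to OLS only when the mixed fit fails outright.

**Coupling.** Behavioral features (normalized per bird) and interneuron
features (normalized per neuron, averaged across a bird's interneurons per
stimulus) are scaled 0–100, joined on (bird, stimulus) and correlated
(Pearson) per cell of the 3 × 3 grid with Bonferroni correction; cells
failing a Kolmogorov–Smirnov normality screen fall back to Spearman and are
flagged. Cross-correlations between narrow and broad units use raw
(unsmoothed) 1 ms binned trial-averaged rates over −100 to 400 ms, both
conditions mean-centered and concatenated:
c(ℓ) = Σₜ x(t+ℓ)·y(t) / (N·sd(x)·sd(y)), bounded in [−1, 1]. Negative best
lag means the narrow (interneuron) series leads. Smoothing is deliberately
off here: a symmetric smoothing kernel convolved onto the asymmetric
cross-correlation function shifts its peak even in the noiseless limit.

**Acoustics.** Clips are peak-normalized, band-passed 300 Hz–14 kHz
(zero-phase Butterworth, order 6), onset-aligned at the first 5%-of-peak
crossing and zero-padded to a common length. PCA on the waveform samples
retains PCs to 90% cumulative variance; k-means (10 restarts) is scored by
silhouette over k = 2…5 and the argmax wins. All-identical clips are
flagged degenerate.

## Numerical and design notes

- All randomness flows from explicit integer seeds; a run configuration
  (YAML-serializable) reproduces every output byte-for-byte.
- Degenerate cases are flagged, not silently dropped: zero baseline
  variance (z undefined), zero-variance cross-correlation inputs, all-zero
  signed-rank differences, single-class test folds (resampled), sparse
  correlation cells (< 3 points).
- Test and analysis problem sizes are scaled-down choices of this package
  (tens of units, 200-replicate calibrations, tens of permutations with
  several reruns each); each test states its sizes.

## Known limitations

- The Euclidean-divergence ±2 SD rule inherits a baseline-only null; when
  stimuli evoke strong responses the response-epoch sampling variance
  exceeds the baseline's, and the rule flags far more than the nominal 5%
  of post-onset bins even with no familiarity effect (the calibration test
  quantifies this). It should be read as a descriptive band,
  not a calibrated test; the calibrated alternatives in this package are
  the label-permutation decoders and the mixed-model contrasts.
- At the study's reported behavioral and neural effect sizes, the
  permutation-test margins are modest (observed accuracy a few points above
  the null's 95th percentile); single replicate experiments at those sizes
  are expected to cross the significance threshold often but not always.
- Per-pair best-lag extraction has ±1 ms precision only for
  transient-dominated responses; hump-shaped profiles make the
  cross-correlation peak flat and the argmax correspondingly imprecise.
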