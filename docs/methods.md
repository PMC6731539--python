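# Methods

This note documents the models, parameters and numerical choices behind
`eaload`, and what the synthetic data used in the tests does and does
not establish about real recordings.

## Coordinate conventions

All times are seconds from session start; intervals are half-open
`[start, end)`. Phases of a session, together with excluded regions,
tile the analyzed timeline exactly — this tiling is enforced by the
phase reader and asserted over randomized simulated sessions in the
tests.

## Spike detection

The detector targets epileptiform spikes: brief high-amplitude LFP
transients, often followed by a slower wave of opposite polarity.

* **Downsampling.** Input traces are polyphase-resampled to 500 Hz
  (anti-aliased). Rates below 500 Hz are rejected.
* **Band power.** Spectrogram with 256 ms Hann windows and 75 %
  overlap. Each frequency bin is z-scored across usable time, which
  whitens the 1/f background so that the 4–40 Hz mean responds to
  transients rather than to slow power drifts. The overlap is denser
  than the conventional 50 % because a ~20 ms spike falling midway
  between 50 %-overlapped window centers loses up to three quarters of
  its measured power to the taper and can slip under the threshold.
* **Peak threshold.** No absolute criterion is assumed; peaks are strict
  local maxima above mean + 3 SD of the band-power trace (configurable
  `k_sd`). A dead time of 0.0833 s suppresses secondary detections.
* **Amplitude rescue.** The baseline is every usable sample at least
  0.5 s from any detection; deflections beyond ±4.5 × the baseline SD
  are added as spikes unless they fall within 300 ms of an existing
  detection — the trailing wave of an already-detected spike belongs to
  that event and must not be re-counted.
* **Waveform filter.** 300 ms cutouts around candidates are projected
  onto their first three principal components and fitted with a
  five-component Gaussian mixture, separately per polarity (sign of the
  extremal deflection). The lowest-amplitude cluster is discarded only
  when its mean peak-to-peak amplitude is below 0.6 × that of the other
  clusters: an unconditional discard removes a fifth of genuine events
  whenever no noise population is present. Candidates with overlapping
  cutouts (dense bursts) bypass the filter.
* **Validation.** Greedy earliest-first one-to-one matching within a
  150 ms tolerance yields TP/FP/FN, sensitivity TP/(TP+FN) and
  precision TP/(TP+FP).

## Burst delimitation

Single-linkage grouping at 2.5 s (strict "closer than"), joining of
multi-spike bursts at 3.5 s. A solitary spike can never sit between two
joinable bursts: it would have to be ≥ 2.5 s from each, putting the
bursts ≥ 5 s apart. The joining rule therefore never chains through
solitary spikes. Burst extent runs from first to last spike. In the
robustness sweep the joining threshold scales proportionally with the
grouping threshold (a fixed `group + 1 s` offset is available).

The smoothed rate profile convolves spike times with a unit-mass
Gaussian kernel (total width 5 s, SD 1.66 s, truncated at the width and
renormalized so spike mass is conserved). A burst's AUC integrates the
profile over the burst extent padded by half the kernel width per side,
so the kernel mass of edge spikes is captured and an isolated burst's
AUC approximates its spike count.

## Spike-load classification

Features per burst (≥ 5 spikes): `log n_spikes`, `log median ISI`,
sample SD of ISIs (ddof = 1). Features are z-scored across the pooled
training set *first* and weighted (2, 2, 1) *second* — the reverse
order would cancel the weights. Natural logarithms (any base is
equivalent after z-scoring).

The batch SOM uses a hexagonal grid (default 12 × 8 for datasets of
~10⁴ bursts; smaller grids for smaller data), Gaussian neighborhood
with radius annealed linearly from half the grid diagonal to 0.5 over
30 epochs, and deterministic PCA linear initialization. With linear
initialization the quantization error decreases monotonically from the
second epoch on; the first, coarsest update may trade quantization for
topological order. H\* is the node maximizing (weighted-z log spike
count − weighted-z log median ISI); the load index of a node is
`1 − d/d_max` of its prototype distance to H\*.

Ward clustering of the node prototypes defines categories. The
Thorndike elbow is read as the smallest number of categories from which
the last-merge-distance curve stays flat (every further drop below 20 %
of the largest drop); a manual `k` override exists and is recommended
for very small maps. Categories are named by mean node load index.
Bursts inherit category and index from their best-matching node (ties
break to the lowest node index); bursts with < 5 spikes are too variable
for the map and join the low-load category without an index.

## Phase segmentation

* High-load clusters: high-load bursts with offset-to-onset gaps < 3 min
  (single-burst clusters allowed), spanning first onset to last offset.
* Transition phases: within each inter-cluster gap the inter-burst
  intervals are z-scored per gap (so change points are comparable
  across gaps; per-session normalization is configurable) and scanned
  with two one-sided CUSUM detectors (threshold 1.5, drift 0.1). An
  alarm is localized at the sample after the last zero of its
  cumulative sum and each excursion raises one alarm. The last
  downward change point before a cluster starts the pre-phase; the
  first upward one after it ends the post-phase. Candidates are kept
  only if their burst occupancy exceeds that of the unassigned
  remainder of the session; overlapping post/pre candidates inside one
  gap are resolved in favor of the earlier phase.
* Depression: burst-free gaps after a cluster longer than the 95th
  percentile (linear interpolation) of unassigned inter-burst intervals
  pooled across sessions become post-phases; a per-session fallback
  serves single-session use. The threshold is data-derived and logged.
* Background assembly: the first 3 min are excluded unless a high-load
  cluster ends inside them; the last 5 min are always excluded; epochs
  overlapping an artifact interval are excluded in full (radius 0
  beyond the mask). Remaining epochs become `pre_post` (> 15 %
  medium-load occupancy), `short` (< 90 s) or `background`. Epochs cut
  by session borders or exclusions are flagged incomplete and are left
  out of duration statistics.

Session-level rates follow fixed definitions: the background rate of an
event type counts events starting within background phases divided by
total background time (undefined for sessions without background
phases, which are excluded); the high-load burst rate divides the
session's high-load burst count by session duration minus border and
artifact time. Per-animal averages weight by background time or phase
duration.

## Statistics and surrogates

Burstiness uses the sample SD. A phase's burstiness is only meaningful
with at least five inter-spike intervals; callers enforce this.
Kendall's τ is the tie-corrected τ-b (rates contain ties); Theil–Sen
uses the median pairwise slope with intercept `median(y − slope·x)`.
Kaplan–Meier survival is computed with lifelines. Group differences use
Kruskal–Wallis, pairwise Mann–Whitney U with Bonferroni correction
across the stated family, Wilcoxon signed-rank for paired samples, and
a one-sample t test for regression-slope ensembles.

Surrogate event series concatenate exponential waits at
`rate_adj = rate_obs / (1 − rate_obs (T_dead + T_event))` with the dead
time (and, for burst surrogates, a duration drawn from the pooled burst
durations) inserted after each event, so the realized event rate equals
the observed one (verified to 1 %). Spike surrogates use
`T_dead = 0.0833 s, T_event = 0`; burst surrogates `T_dead = 3.5 s`
with `T_event` the mean pooled duration. `rate_obs` for pooled episodes
is the duration-weighted average rate. `p_surrogate` is the fraction of
surrogate values at or beyond the observed one (ties count as beyond —
conservative); an exact zero is reported as `< 1/N`. The permutation
test across animals reallocates episodes so each surrogate animal keeps
its original episode count.

## The nested modulated-Poisson simulator

The simulator embodies a null model in which all temporal structure of
EA comes from slow modulations of a spike rate, with no interaction
between burst categories. Stages (defaults in parentheses are the study
conditions of the surrogate dataset, SDS):

| parameter | default | meaning |
|---|---|---|
| `baseline_rate` | 0.17 /s | homogeneous baseline spikes (PP₀) |
| `burst_pool_rate` | 0.28 /s | pool copied under Modulation₁ (PP₁) |
| `cluster_pool_rate` | 0.39 /s | pool copied under Modulation₂ (PP₂) |
| `burst_peak_rate` | 0.92 /min | Poisson-timed Modulation₁ peaks |
| `cluster_rate` | 2.3 /h | Poisson-timed Modulation₂ step onsets |
| `gain_range` | 0.1–1.125 | Modulation₂ gain swept across sessions |
| `mod1_kernel_halfwidth` | 15 s | triangular kernel half-width |
| `mod2_step_duration` | 300 s | step length (a typical cluster duration) |
| `session_duration` | 9000 s | 2.5 h per session |
| `n_sessions` | 105 | one session per gain value |
| `auc_percentile` | 76 | calibration percentile for high load |

Copying is Bernoulli thinning: each pool event survives independently
with probability equal to the modulation value at its time. Triangular
kernels (peak 1) sum and are clipped to 1; step heights are
`min(gain, 1)` (the stated sweep extends to 1.125, saturating).

The kernel half-width is not a published number. It is set so that a
Modulation₁ event copies ~4 spikes on average (0.28 /s × 15 s), which
together with baseline spikes yields bursts at the ≥ 5-spike scale the
load classifier operates on; a half-width of a few seconds would copy
about one spike per peak and could not produce bursts at the stated
0.92 /min. The step duration is likewise unpublished; 300 s sits inside
the printed range of cluster durations (20 s to ~50 min).

SDS bursts are delimited by the 2.5 s grouping rule alone (the joining
pass belongs to the recorded-data pipeline). Since the within-burst
structure is not simulated, spike load is approximated by the
rate-profile AUC. Mirroring the SOM classifier it stands in for, the
AUC classifier operates on bursts with ≥ 5 spikes: the threshold is the
76th percentile of classifiable-burst AUCs of a gain = 1 calibration
session (the percentile that reproduced the recorded 3:1 low-to-high
rate ratio at full gain), held fixed across the sweep, and the SDS
low/high rates count classified bursts. Smaller bursts remain
unclassified in the SDS; medium-load bursts are deliberately not
simulated. Phase segmentation for the SDS uses the 3-min cluster rule
only, with everything else treated as background (transitions ignored).

Under these conditions the SDS reproduces the null model's signature:
across ten replicate seeds, τ(high-load rate, background low-load rate)
= +0.28 ± 0.13 (every replicate positive) and τ(background duration,
within-phase low-load rate) = −0.15 ± 0.07 (every replicate
non-positive). Both values fluctuate considerably from run to run —
the calibration percentile of a single 2.5 h session is itself a noisy
order statistic — so any single run should be read with that spread in
mind.

## LFP fixtures

`make_lfp_fixture` embeds a spike-and-wave template (sharp ~10 ms
deflection of −350 µV followed by a slower +120 µV wave 90 ms later) at
known times in Gaussian noise with a 1/f spectrum above a 1 Hz knee
(the knee mimics the recording chain's high-pass; unchecked 1/f drift
would dominate the trace and has no counterpart in filtered
recordings). Fixtures give the detector a ground truth: at noise SDs of
8–40 µV the detector scores sensitivity ≥ 0.95 and precision ≥ 0.9.

What fixtures do **not** establish: real LFP noise is non-Gaussian and
non-stationary, real spikes vary in shape within a session, and real
artifact structure (movement, chewing) is absent. Passing fixture tests
shows the machinery is correct, not that the published real-data scores
(sensitivity 0.87, precision 0.90) would be reproduced on new
recordings.

## Degenerate inputs and tie-breaks

Zero-variance features, empty surrogate pools, sessions without
background phases, all-censored survival input and constant correlation
samples raise informative errors rather than returning silent NaNs.
Best-matching-unit ties break to the lowest node index; `p_surrogate`
ties count as exceeding; percentiles interpolate linearly.

## Known limitations

* The SOM hyperparameters (grid size, epochs, radius schedule) are not
  published; defaults are documented above and configurable. The number
  of categories is data-dependent — three is the canonical outcome, not
  a guarantee.
* The pre-phase search spans the entire inter-cluster gap; a bounded
  lookback is not implemented.
* Cross-region analyses (contralateral/entorhinal participation) and
  behavioral seizure identification are out of scope; category labels
  can be stored but nothing more.
* Statistical power computations are not provided.
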