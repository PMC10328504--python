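# Methods

This package analyzes multi-scale electrophysiological responses to
single-pulse intracortical electrical stimulation in head-fixed mice:
skull-surface EEG (30 channels), laminar Neuropixels LFP, and sorted
single-unit spike trains, recorded across behavioral states (quiet
wakefulness, running, isoflurane anesthesia, recovery). It implements
the full analysis chain — preprocessing, ERP quantification, current
source density, spike-train analytics, perturbational complexity — plus
a synthetic-session generator that reproduces the statistical structure
those analyses assume, so the chain is testable end-to-end without any
recorded data.

## Preprocessing

**Artifact masking.** The electrical pulse leaves a transient of up to
2 ms in every data stream. The 0..+2 ms window after each onset is
replaced by the time-reversed copy of the −2..0 ms window, identically
for EEG, LFP and spike-band data; spikes timestamped in (0, +2] ms are
deleted. Masking is idempotent because the source region is never
modified.

**EEG.** Common-average reference over good channels, then a zero-phase
third-order Butterworth band-pass 0.1–100 Hz, epoched −2..+2 s around
each onset. Filters are applied forward-backward so ERP peak latencies
are not shifted. Because filtering acts on finite epochs (the original
recordings were filtered continuously), the low cutoff would otherwise
ring at the epoch edges; we use odd-reflection padding of 0.5 s, which
empirically removes the edge transient (zero-signal false-positive rate
of the GFP threshold drops from ~14% to 0).

**LFP.** Anti-alias low-pass (8th-order Butterworth at 0.4 × the output
rate, i.e. 500 Hz) followed by decimation 2.5 kHz → 1.25 kHz, a
first-order high-pass (default cutoff 0.1 Hz — the recording system's
cutoff is not public; configurable), and subtraction of the
per-time-point median over the channels in ACSF above the brain surface
(removes signal common to the tip reference).

**Trial states.** A trial is *anesthetized* if its onset falls in an
anesthesia interval (precedence over speed), *recovery* analogously;
otherwise *quiet* if mean wheel speed in (−0.5, +0.5) s is 0 cm/s
(tolerance 1e-6 cm/s, configurable) and *running* if positive.

## ERP metrics

The ERP is the per-channel trial average. Global field power (GFP) is
the SD across channels per time point — we use the population convention
(divisor N) for both the GFP and its baseline z-scoring (a `ddof`
switch is provided; the choice only rescales z). The z-score is taken
against the −2..0 s baseline, excluding the ±2 ms artifact window.

* **Duration** — total time with z > 3 in the 0..+2 s response window.
  A `last_crossing` mode returns the time of the final suprathreshold
  sample instead; the two agree when the suprathreshold set is one
  contiguous interval starting at 0.
* **Magnitude** — ∫ max(z − 3, 0) dt over the response window, in SD·s.
  A `baseline_area` mode additionally divides by ∫|z| dt over the
  baseline; it is provided because the two readings of the published
  definition differ dimensionally, and the raw SD·s integral is the one
  whose units match the reported values. The default is the raw
  integral.

## Current source density

Pipeline order is fixed: channel rejection → smoothing → derivative.

* **Rejection**: iteratively, any channel deviating instantaneously by
  more than ±7 across-channel SDs (Chebyshev-motivated bound) is
  replaced by linear interpolation over depth from surviving neighbors.
  Note the across-channel z of a single outlier is bounded by
  √(N−1), so the rule needs ≳50 channels to fire at all — appropriate
  for 384-channel probes.
* **Smoothing**: uniform moving averages — 8 ms in time, then 26 and 4
  channels over the depth-sorted channel axis, truncated at the edges.
  Kernel shape is not specified in the source protocol; uniform is the
  minimal choice.
* **Derivative**: CSD_i = −σ (V_{i−1} − 2V_i + V_{i+1})/h², σ = 0.3 S/m,
  with Vaknin edge duplication for the zero-external-current boundary.
  Sinks are negative. The stencil is exact for quadratic depth profiles
  and accurate to <1% for spatial wavenumbers with kh < 0.1.
* **Layer space**: each cortical layer maps affinely onto 10 equal bins
  (linear interpolation at bin centers), so maps from different probes
  are comparable bin-by-bin. Across subjects, a per-bin two-sided
  Wilcoxon signed-rank test (p < 0.05) marks consistent activations;
  marked bins with no marked 4-neighbor (depth/time) are cleared.

## Spike-train analytics

* **RS/FS**: waveform duration > 0.4 ms → regular-spiking, ≤ 0.4 ms →
  fast-spiking. Population analyses in cortex use RS units only.
* **Spike density**: 1 ms peri-stimulus bins averaged over trials,
  Gaussian-smoothed (σ = 3 ms), z-scored per unit against the −2..0 s
  baseline; the population series is the mean over units with non-zero
  baseline SD.
* **Evoked magnitude (onset-shuffle null)**: the statistic is the area
  under the rectified baseline-z-scored trial average over 0..+0.5 s.
  Its null is the same statistic recomputed for 1000 random per-trial
  onsets drawn uniformly over the valid recording span; the result is
  (AUC − mean_null)/SD_null. One shuffle set can be shared across units
  of a session (a computational choice; the null is session-level).
  Calibration at 200 homogeneous-Poisson units: |z| ≥ 1.96 in 4.5% of
  units; evoked units (5× rate for 100 ms) give z > 15.
* **Modulation calls**: per unit and window (2–25, 25–150, 150–300 ms),
  a paired two-sided Wilcoxon signed-rank test on trial-wise post counts
  vs an immediately pre-onset window of matched duration, BH-corrected
  across all unit × window tests of the call at FDR 0.05.
* **First-spike latency**: per unit the median over trials of the first
  spike in the window (no-spike trials excluded); the population value
  is the median over responsive units (a two-level median — whether the
  published population value is such a two-level median is not fully
  specified; ours is documented here). The late window defaults to
  75–300 ms, with 100–300 ms available.
* **Bursts**: maximal runs of ≥2 spikes with all ISIs < 4 ms, preceded
  by ≥100 ms of silence. The silence of a run at the start of a train
  must be *observed*: it qualifies only when a recording start time is
  supplied and precedes the run by the minimum silence. A burst belongs
  to a trial window by its start time. `burst_probability` is the
  fraction of trials in which any unit of the region bursts (75–300 ms
  window); `fraction_bursting` is the per-trial fraction of units that
  burst.
* **Off period**: the published values have no published estimator, so
  ours is a package construction: the longest contiguous interval inside
  10–300 ms post-stimulus where the un-normalized population rate stays
  below 0.25 × its baseline mean. The 3 ms PSTH smoothing biases the
  estimate low by ~8–10 ms at the configured conditions (edges of the
  silent window are smeared); this is within the generator-recovery
  tolerance and is reported as-is rather than corrected.

## PCI-ST

Complexity of the trial-averaged ERP: baseline window (−0.8, −0.002) s,
response (0.002, 0.8) s, SVD of the response matrix, components kept to
99% cumulative response variance and SNR (RMS_response/RMS_baseline)
> 1.6; per component, the number of state transitions (NST) of the
thresholded temporal distance matrix is compared between response and
baseline over a fixed threshold grid, ΔNST* = max over thresholds of
(NST_resp − 1.2·NST_base); the index is the sum over components.

Two sub-choices are frozen in this implementation (the published
protocol delegates them to its reference code, which is pinned by the
contract above): NST(ε) is the count of adjacent-time transitions of
T = (D > ε) divided by the segment length (average transitions per
reference column), and the threshold grid is 100 values linear from 0 to
the largest pairwise distance in either segment. The grid's top point
forces ΔNST* ≥ 0, and tying the grid to the data's own distance scale
makes the index exactly invariant to global rescaling of the input.
Variance selection uses response-window variance only. The NST
computation uses a sorted-band trick (each adjacent pair transitions for
ε in [min, max) of its two distances), giving the whole grid in
O(N² log N).

Trial counts are matched across the states being compared (random
subsample of larger states, seeded).

## Group statistics

Every comparison is gated on Shapiro-Wilk normality at α = 0.05 per
sample (on paired differences for paired designs): t-tests / one-way
repeated-measures ANOVA when the gate passes, Mann-Whitney U / Wilcoxon
signed-rank / Friedman otherwise; all two-sided. Post-hoc families are
BH-corrected. The trial-wise coupling analysis correlates (Pearson) the
per-trial fraction of bursting thalamic units with the late-ERP peak,
defined as the maximum single-trial GFP z in 100–300 ms (window
configurable; the published definition names no window).

## Synthetic sessions

The generator emulates the study conditions; its defaults are the
reported values, not tuning knobs:

| quantity | default | origin |
| --- | --- | --- |
| trials per state | 100 | experiment delivered up to 120 pulses/state |
| inter-stimulus interval | U(3.5, 4.5) s | protocol |
| cortical baseline (quiet/run/anesth) | 3.5 / 5.2 / 1.1 Hz | reported |
| thalamic baseline | 9.0 / 16.4 / 0.8 Hz | reported |
| cortical excitation peak / window | 38.1 Hz in 2–25 ms | reported |
| cortical off period (deep / superficial) | 125 / 94.2 ms, gain 0 | reported |
| cortical rebound peak / window | 7.9 Hz in 150–300 ms | reported |
| thalamic excitation / silence / rebound | 22.3 Hz, 74.6 ms, 14.7 Hz | reported |
| thalamic windows | shifted +7 ms vs cortex | reported latency difference |
| burst probability per unit (quiet/run/anesth) | 0.4 / 0.15 / 0 | free; chosen so the rebound is burst-dominated in quiet wakefulness |
| burst timing | N(148, 15) ms, size 2–6, ISI U(1.5, 3.5) ms | rebound latency reported; size/ISI within the burst definition |
| ERP components | 25 ms (σ 8 ms) and 180 ms (σ 40 ms) | reported peak latencies |
| ERP amplitudes (early/late) | 30 / 25 µV, noise 5 µV pink | free parameters, not claims about the data |
| state ERP scaling (early, late) | quiet (1,1), running (1,0.3), anesth (0.6,0) | late component reduced when running, absent under anesthesia |

Spike trains are inhomogeneous Poisson with the piecewise-constant gain
profile (baseline 1, excitation gain = peak/baseline, off gain 0,
rebound gain as configured); thalamic bursts are injected explicitly
with an enforced ≥100 ms silent gap. Under anesthesia the off and
rebound gains are 1 (no bistability) and burst probability is 0. EEG
epochs are sums of weight-map × waveform outer products — the early map
decays with distance from the stimulation site and flips sign beyond
~2.4 mm; the late map is a dipole with a different center — plus
1/f-amplitude (pink) noise, normalized per trace, and a stimulus
artifact transient in 0..+2 ms. LFP uses laminar voltage profiles with
an early deep (~600 µm) sink and a late sink at the L2/3–L5 border
(~400 µm) plus a common-mode component that the surface-median
reference removes.

When coupling is enabled, a log-normal latent per-trial drive (σ = 0.3)
multiplies the thalamic burst probability, the cortical rebound gain and
the late-ERP amplitude jointly, which produces the trial-wise
correlations between thalamic bursting, cortical rebound firing and the
late EEG component; with coupling off the drive is 1 and those
quantities are independent.

**What the generator does not emulate** — and hence what passing tests
do not show about recorded data: biophysical waveforms and overlapping
spikes, spike sorting errors, non-Poisson spiking statistics (e.g.
refractoriness outside bursts), anatomically realistic volume
conduction, EEG line noise and movement artifacts, slow drifts of state
within a block, and probe-localization uncertainty. Tests on synthetic
sessions validate the *computations*, not the biology.

## Problem sizes and numerics

Statistical checks run at sizes chosen to make their expected error
bands tight while keeping the whole suite desk-scale: 100 trials per
state and 10 seeds for ordering checks, 200 units for permutation
calibration, 20 seeds for FDR calibration, 1000 random trains for the
burst-detector equivalence. The acceptance script regenerates its
numbers from scratch at these sizes. Degenerate inputs reject loudly
(zero baseline SD, empty trial sets, all-bad channels, unsorted spikes);
zero-variance statistical comparisons return p = 1 with a warning
rather than raising. The published group-level values (24–31 animals)
are statistics of the recorded dataset and are not reproduced here;
qualitative orderings and generator-recovery are the validation targets.

## Known limitations

* The NWB reader requires `pynwb` (not bundled) and maps only the
  DANDI:000458 layout; it is untested against live files in this
  repository.
* The PCI-ST sub-conventions (NST normalization, threshold-grid
  scaling) follow this package's frozen documentation above; other
  implementations may scale ΔNST differently, so cross-implementation
  comparisons should be made on contrasts (state orderings), not raw
  values — the invariants (non-negativity, scale and channel-permutation
  invariance, noise-null zero) hold regardless.
* The Chebyshev channel-rejection rule is insensitive on probes with
  ≲50 channels (see above).
* `burst_probability` is region-level (any unit); per-unit probabilities
  are obtainable by calling it on single-unit subsets.
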