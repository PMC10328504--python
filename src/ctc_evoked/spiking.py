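"""Spike-train analytics: cell-class split, peri-stimulus rates, evoked
magnitude against an onset-shuffle null, windowed modulation calls,
first-spike latencies, thalamic burst detection, and off-period length.

Conventions used throughout:

* RS / FS split at 0.4 ms spike-waveform duration (boundary to FS);
  population analyses in cortex use RS units only.
* A burst is >= 2 consecutive spikes with every inter-spike interval
  below 4 ms, preceded by at least 100 ms of observed silence. Runs are
  maximal; a burst belongs to a window by its start time.
* Modulation calls: per unit and per post-stimulus window (2-25, 25-150,
  150-300 ms), a paired two-sided Wilcoxon signed-rank test on trial-wise
  spike counts against an immediately pre-stimulus window of matched
  duration, Benjamini-Hochberg corrected across all tests at FDR 0.05.
* Evoked magnitude: the area under the rectified baseline-z-scored
  trial-averaged signal over 0..+0.5 s, standardized against a null of
  1000 onset-shuffled recomputations ((AUC - mean_null) / SD_null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.multitest import multipletests

from .session import SpikeTrainSet, Unit


def classify_rs_fs(waveform_duration_ms: float) -> str:
    """Regular-spiking (> 0.4 ms) vs fast-spiking (<= 0.4 ms)."""
    if waveform_duration_ms <= 0:
        raise ValueError("waveform duration must be positive")
    return "RS" if waveform_duration_ms > 0.4 else "FS"


# ---------------------------------------------------------------------------
# Peri-stimulus rates
# ---------------------------------------------------------------------------

@dataclass
class SpikeDensity:
    t: np.ndarray  # bin centers, s relative to onset
    unit_rate: np.ndarray  # units x time, Hz (or z if normalized)
    population: np.ndarray  # time, mean over valid units
    valid_unit: np.ndarray  # units excluded when baseline SD was zero
    normalized: bool


def spike_density(
    units: SpikeTrainSet,
    onsets: np.ndarray,
    window_s: tuple = (-2.0, 2.0),
    bin_ms: float = 1.0,
    kernel_sigma_ms: float = 3.0,
    normalize: str | None = "baseline_z",
    baseline_window_s: tuple = (-2.0, 0.0),
) -> SpikeDensity:
    """Trial-pooled peri-stimulus spike density per unit.

    Counts in ``bin_ms`` bins are averaged over trials, converted to Hz,
    and smoothed with a Gaussian kernel. ``normalize='baseline_z'``
    z-scores each unit against its pre-stimulus baseline; units with zero
    baseline SD are flagged invalid and excluded from the population
    mean.
    """
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("need at least one trial")
    dt = bin_ms * 1e-3
    edges = np.arange(window_s[0], window_s[1] + dt / 2, dt)
    t = edges[:-1] + dt / 2
    n_units = len(units)
    rates = np.zeros((n_units, t.size))
    for i, u in enumerate(units):
        rel = _relative_times(u.spike_times, onsets, window_s)
        counts, _ = np.histogram(rel, bins=edges)
        rates[i] = counts / (onsets.size * dt)
    if kernel_sigma_ms > 0:
        rates = gaussian_filter1d(rates, kernel_sigma_ms / bin_ms, axis=-1)
    valid = np.ones(n_units, bool)
    if normalize == "baseline_z":
        base = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
        mu = rates[:, base].mean(axis=1, keepdims=True)
        sd = rates[:, base].std(axis=1, keepdims=True)
        valid = sd[:, 0] > 0
        sd[sd == 0] = 1.0
        rates = (rates - mu) / sd
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    pop = rates[valid].mean(axis=0) if valid.any() else np.full(t.size, np.nan)
    return SpikeDensity(t=t, unit_rate=rates, population=pop, valid_unit=valid,
                        normalized=normalize is not None)


def _relative_times(spike_times: np.ndarray, onsets: np.ndarray, window_s: tuple) -> np.ndarray:
    """Spike times relative to each onset, pooled, restricted to window."""
    out = []
    i0 = np.searchsorted(spike_times, onsets + window_s[0])
    i1 = np.searchsorted(spike_times, onsets + window_s[1])
    for onset, a, b in zip(onsets, i0, i1):
        out.append(spike_times[a:b] - onset)
    return np.concatenate(out) if out else np.zeros(0)


def trial_counts(unit: Unit, onsets: np.ndarray, window_s: tuple) -> np.ndarray:
    """Spike count per trial inside ``window_s`` relative to onset."""
    onsets = np.asarray(onsets, float)
    i0 = np.searchsorted(unit.spike_times, onsets + window_s[0])
    i1 = np.searchsorted(unit.spike_times, onsets + window_s[1])
    return (i1 - i0).astype(int)


# ---------------------------------------------------------------------------
# Evoked magnitude with onset-shuffle permutation null
# ---------------------------------------------------------------------------

def binned_rate(unit: Unit, t_end: float, bin_s: float = 0.005,
                kernel_sigma_s: float = 0.003) -> np.ndarray:
    """Continuous session-long spike density for one unit (Hz)."""
    n = int(np.ceil(t_end / bin_s))
    counts = np.bincount(
        np.clip((unit.spike_times / bin_s).astype(int), 0, n - 1), minlength=n
    ).astype(float)
    rate = counts / bin_s
    if kernel_sigma_s > 0:
        rate = gaussian_filter1d(rate, kernel_sigma_s / bin_s)
    return rate


def evoked_magnitude_permutation(
    signal: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    window_s: tuple = (0.0, 0.5),
    baseline_s: tuple = (-2.0, 0.0),
    n_shuffles: int = 1000,
    seed: int | None = 0,
    shuffled_onsets: np.ndarray | None = None,
) -> float:
    """Standardized evoked magnitude of a continuous 1-D signal.

    Observed statistic: trial-average the signal around the true onsets,
    z-score against the averaged baseline, and integrate the rectified
    z over ``window_s``. Null: the same statistic for ``n_shuffles``
    draws of per-trial onsets placed uniformly over the valid recording
    span. Returns ``(AUC - mean_null) / SD_null``; deterministic for a
    fixed seed. Precomputed ``shuffled_onsets`` (n_shuffles x n_trials,
    seconds) may be passed to share one null across many units.
    """
    signal = np.asarray(signal, float)
    onsets_s = np.asarray(onsets_s, float)
    n = signal.size
    t_total = n / fs
    lo, hi = -baseline_s[0], t_total - window_s[1] - 1.0 / fs
    if hi <= lo:
        raise ValueError("recording too short for onset shuffling")
    if shuffled_onsets is None:
        rng = np.random.default_rng(seed)
        shuffled_onsets = rng.uniform(lo, hi, size=(n_shuffles, onsets_s.size))
    obs = _shuffle_auc(signal, fs, onsets_s[None, :], window_s, baseline_s)[0]
    null = _shuffle_auc(signal, fs, shuffled_onsets, window_s, baseline_s)
    sd = null.std()
    if sd == 0:
        raise ValueError("degenerate permutation null")
    return float((obs - null.mean()) / sd)


def _shuffle_auc(signal, fs, onset_sets, window_s, baseline_s):
    """AUC of rectified baseline-z-scored trial average, per onset set."""
    i_base0 = int(round(baseline_s[0] * fs))
    i_win1 = int(round(window_s[1] * fs))
    offs = np.arange(i_base0, i_win1)  # relative sample offsets
    t_rel = offs / fs
    base_m = (t_rel >= baseline_s[0]) & (t_rel < baseline_s[1])
    win_m = (t_rel >= window_s[0]) & (t_rel < window_s[1])
    idx = np.round(onset_sets * fs).astype(int)  # (n_sets, n_trials)
    gathered = signal[idx[:, :, None] + offs[None, None, :]]
    avg = gathered.mean(axis=1)  # (n_sets, len(offs))
    mu = avg[:, base_m].mean(axis=1, keepdims=True)
    sd = avg[:, base_m].std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    z = (avg - mu) / sd
    return np.abs(z[:, win_m]).sum(axis=1) / fs


# ---------------------------------------------------------------------------
# Windowed modulation calls
# ---------------------------------------------------------------------------

DEFAULT_WINDOWS = ((0.002, 0.025), (0.025, 0.150), (0.150, 0.300))


def modulated_units(
    units: SpikeTrainSet,
    onsets: np.ndarray,
    windows: tuple = DEFAULT_WINDOWS,
    fdr: float = 0.05,
    rs_only: bool = True,
) -> pd.DataFrame:
    """Per-unit, per-window modulation calls.

    For each unit and post-stimulus window (a, b), trial-wise spike
    counts are compared with a pre-stimulus window of matched duration
    ending at the onset, using a paired two-sided Wilcoxon signed-rank
    test. p-values are Benjamini-Hochberg corrected across every test in
    the call; labels: 'increased' / 'decreased' when q < fdr by the mean
    count change, else 'none'.
    """
    rows = []
    for u in units:
        if rs_only and u.cell_class != "RS":
            continue
        for (a, b) in windows:
            post = trial_counts(u, onsets, (a, b))
            pre = trial_counts(u, onsets, (-(b - a), 0.0))
            diff = post - pre
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(post, pre, zero_method="wilcox",
                                         alternative="two-sided")[1])
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "region": u.region,
                    "cell_class": u.cell_class,
                    "window": f"{a * 1000:g}-{b * 1000:g}ms",
                    "p": p,
                    "mean_change": float(diff.mean()),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(q=[], label=[])
    result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    result["q"] = np.maximum(result["q"], result["p"])  # q >= p within the family
    result["label"] = "none"
    sig = result["q"] < fdr
    result.loc[sig & (result["mean_change"] > 0), "label"] = "increased"
    result.loc[sig & (result["mean_change"] < 0), "label"] = "decreased"
    return result


# ---------------------------------------------------------------------------
# First-spike latency
# ---------------------------------------------------------------------------

def first_spike_latency(
    units: SpikeTrainSet, onsets: np.ndarray, window_s: tuple
) -> tuple[pd.Series, float]:
    """Two-level median first-spike latency inside ``window_s``.

    Per unit: the median over trials of the first spike time in the
    window (trials without a spike are excluded). Population value: the
    median over responsive units. Returns ``(per_unit, population)``;
    population is NaN when no unit responds.
    """
    onsets = np.asarray(onsets, float)
    per_unit = {}
    for u in units:
        i0 = np.searchsorted(u.spike_times, onsets + window_s[0])
        i1 = np.searchsorted(u.spike_times, onsets + window_s[1])
        has = i0 < i1
        if not np.any(has):
            continue
        firsts = u.spike_times[i0[has]] - onsets[has]
        per_unit[u.unit_id] = float(np.median(firsts))
    series = pd.Series(per_unit, dtype=float)
    pop = float(series.median()) if len(series) else float("nan")
    return series, pop


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

@dataclass
class BurstEvent:
    unit_id: int
    start_s: float
    n_spikes: int
    preceding_silence_s: float
    trial_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_spikes < 2:
            raise ValueError("a burst has at least 2 spikes")


def detect_bursts(
    spike_times: np.ndarray,
    max_isi_s: float = 0.004,
    min_silence_s: float = 0.100,
    t_start: float | None = None,
    unit_id: int = -1,
) -> list[BurstEvent]:
    """Maximal runs of >= 2 consecutive spikes with every ISI below
    ``max_isi_s``, preceded by at least ``min_silence_s`` of silence.

    The preceding silence of the first spike of the train is measured
    from ``t_start`` (default: the first spike does not qualify unless
    ``t_start`` is given and precedes it by at least the minimum
    silence). Events are non-overlapping by construction.
    """
    st = np.asarray(spike_times, float)
    if st.size > 1 and np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    if st.size < 2:
        return []
    isi = np.diff(st)
    bursts = []
    i = 0
    n = st.size
    while i < n - 1:
        if isi[i] < max_isi_s:
            j = i + 1
            while j < n - 1 and isi[j] < max_isi_s:
                j += 1
            # run spans spikes i..j
            if i == 0:
                silence = st[0] - t_start if t_start is not None else -np.inf
            else:
                silence = isi[i - 1]
            if silence >= min_silence_s:
                bursts.append(
                    BurstEvent(
                        unit_id=unit_id,
                        start_s=float(st[i]),
                        n_spikes=int(j - i + 1),
                        preceding_silence_s=float(silence),
                    )
                )
            i = j + 1
        else:
            i += 1
    return bursts


def bursts_in_window(
    unit: Unit,
    onsets: np.ndarray,
    window_s: tuple = (0.075, 0.300),
    **kwargs,
) -> list[BurstEvent]:
    """Bursts whose start time falls inside ``window_s`` of a trial.
    Detection runs on the full spike train so the preceding-silence rule
    sees spikes before the window; ``start_s`` and ``trial_index`` are
    reported relative to the matched onset."""
    onsets = np.asarray(onsets, float)
    all_bursts = detect_bursts(unit.spike_times, unit_id=unit.unit_id, **kwargs)
    out = []
    if not all_bursts:
        return out
    starts = np.array([b.start_s for b in all_bursts])
    trial_of = np.searchsorted(onsets, starts) - 1
    for b, ti in zip(all_bursts, trial_of):
        if ti < 0:
            continue
        rel = b.start_s - onsets[ti]
        if window_s[0] <= rel < window_s[1]:
            out.append(
                BurstEvent(b.unit_id, float(rel), b.n_spikes, b.preceding_silence_s,
                           trial_index=int(ti))
            )
    return out


def burst_probability(
    units: SpikeTrainSet, onsets: np.ndarray, window_s: tuple = (0.075, 0.300)
) -> float:
    """Fraction of trials in which the region produces at least one burst
    (any unit) with start inside ``window_s``."""
    if len(units) == 0:
        raise ValueError("no units in region")
    onsets = np.asarray(onsets, float)
    has_burst = np.zeros(onsets.size, bool)
    for u in units:
        for b in bursts_in_window(u, onsets, window_s):
            has_burst[b.trial_index] = True
    return float(has_burst.mean())


def fraction_bursting(
    units: SpikeTrainSet, onsets: np.ndarray, window_s: tuple = (0.075, 0.300)
) -> np.ndarray:
    """Per-trial fraction of units with at least one burst in the window."""
    if len(units) == 0:
        raise ValueError("no units in region")
    onsets = np.asarray(onsets, float)
    counts = np.zeros((len(units), onsets.size), bool)
    for i, u in enumerate(units):
        for b in bursts_in_window(u, onsets, window_s):
            counts[i, b.trial_index] = True
    return counts.mean(axis=0)


def burst_table(
    units: SpikeTrainSet, onsets: np.ndarray, window_s: tuple = (0.075, 0.300)
) -> pd.DataFrame:
    """Tidy table of burst events inside the window across units."""
    rows = []
    for u in units:
        for b in bursts_in_window(u, onsets, window_s):
            rows.append(
                {
                    "unit_id": b.unit_id,
                    "trial_index": b.trial_index,
                    "start_s": b.start_s,
                    "n_spikes": b.n_spikes,
                    "preceding_silence_s": b.preceding_silence_s,
                }
            )
    return pd.DataFrame(rows,
                        columns=["unit_id", "trial_index", "start_s", "n_spikes",
                                 "preceding_silence_s"])


# ---------------------------------------------------------------------------
# Off-period estimation
# ---------------------------------------------------------------------------

def off_period_duration(
    t: np.ndarray,
    population_rate: np.ndarray,
    baseline_window_s: tuple = (-2.0, 0.0),
    start_search_s: float = 0.010,
    end_search_s: float = 0.300,
    frac_threshold: float = 0.25,
) -> float:
    """Length (s) of the longest contiguous interval inside the search
    window where the population rate stays below ``frac_threshold`` times
    its baseline mean. The rate series must be un-normalized (Hz)."""
    t = np.asarray(t, float)
    rate = np.asarray(population_rate, float)
    base = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    b = rate[base].mean()
    if b <= 0:
        raise ValueError("baseline rate is zero: off period undefined")
    sel = (t >= start_search_s) & (t <= end_search_s)
    below = rate[sel] < frac_threshold * b
    dt = float(np.median(np.diff(t)))
    best = run = 0
    for flag in below:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best * dt
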