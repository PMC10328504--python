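"""Event-related potentials and global-field-power response metrics.

The ERP is the per-channel trial average of the epoched EEG. Response
strength is summarized reference-free by the global field power (GFP):
the standard deviation across channels at every time point, z-scored
against the pre-stimulus baseline (-2..0 s). Two scalar scores follow:

* ``erp_duration`` — the time the GFP z-score spends above threshold
  (default z = 3) in the response window 0..+2 s, or, in
  ``last_crossing`` mode, the time of the final suprathreshold sample;
* ``erp_magnitude`` — the integral of the GFP z-score above the
  threshold over the response window (SD*s), optionally divided by the
  rectified baseline area (``normalize="baseline_area"``).

The SD uses the population convention (divisor N) for both the GFP and
the baseline z-scoring; ``ddof=1`` is available as a switch. Samples in
the +/-2 ms artifact window around the stimulus are excluded from the
baseline and the response metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import EEGEpochs


@dataclass
class GFPSeries:
    t: np.ndarray
    gfp: np.ndarray
    z: np.ndarray
    baseline_window: tuple
    artifact_window: tuple

    def response_mask(self, window: tuple) -> np.ndarray:
        m = (self.t >= window[0]) & (self.t < window[1])
        a0, a1 = self.artifact_window
        m &= ~((self.t >= a0) & (self.t <= a1))
        return m


@dataclass
class ERPMetrics:
    duration_s: float
    magnitude: float
    normalized_magnitude: float | None
    threshold_z: float
    n_trials: int


def average_erp(
    eeg: EEGEpochs, trial_indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean over the selected trials, good channels only.
    Returns ``(erp, t)`` with erp of shape (n_good_channels, n_time)."""
    if trial_indices is None:
        trial_indices = np.arange(eeg.n_trials)
    trial_indices = np.asarray(trial_indices)
    if trial_indices.size == 0:
        raise ValueError("empty trial set")
    data = eeg.data[trial_indices][:, eeg.good_channel, :]
    return data.mean(axis=0).astype(np.float64), eeg.t


def global_field_power(
    erp: np.ndarray,
    t: np.ndarray,
    baseline_window: tuple = (-2.0, 0.0),
    artifact_window: tuple = (-0.002, 0.002),
    ddof: int = 0,
) -> GFPSeries:
    """GFP = SD across channels per time point; z-scored against the
    baseline window (artifact samples excluded from the baseline)."""
    erp = np.asarray(erp, float)
    if erp.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    gfp = erp.std(axis=0, ddof=ddof)
    base = (t >= baseline_window[0]) & (t < baseline_window[1])
    base &= ~((t >= artifact_window[0]) & (t <= artifact_window[1]))
    mu = gfp[base].mean()
    sd = gfp[base].std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate baseline: GFP SD is zero")
    z = (gfp - mu) / sd
    return GFPSeries(t=t, gfp=gfp, z=z, baseline_window=baseline_window,
                     artifact_window=artifact_window)


def erp_duration(
    gfp: GFPSeries,
    threshold_z: float = 3.0,
    response_window: tuple = (0.0, 2.0),
    mode: str = "total",
) -> float:
    """Suprathreshold time of the GFP z-score in the response window.

    ``total`` counts every sample above threshold (sample count x dt);
    ``last_crossing`` returns the time of the final suprathreshold
    sample (0 if none)."""
    m = gfp.response_mask(response_window)
    dt = float(np.median(np.diff(gfp.t)))
    above = m & (gfp.z > threshold_z)
    if mode == "total":
        return float(above.sum() * dt)
    if mode == "last_crossing":
        idx = np.nonzero(above)[0]
        return float(gfp.t[idx[-1]]) if idx.size else 0.0
    raise ValueError(f"unknown duration mode {mode!r}")


def erp_magnitude(
    gfp: GFPSeries,
    threshold_z: float = 3.0,
    response_window: tuple = (0.0, 2.0),
    normalize: str | None = None,
) -> float:
    """Threshold-exceedance integral of the GFP z-score (SD*s):
    integral of max(z - threshold, 0) over the response window. With
    ``normalize="baseline_area"`` the result is additionally divided by
    the rectified area under the baseline-window z-score."""
    m = gfp.response_mask(response_window)
    dt = float(np.median(np.diff(gfp.t)))
    mag = float(np.clip(gfp.z[m] - threshold_z, 0.0, None).sum() * dt)
    if normalize is None:
        return mag
    if normalize == "baseline_area":
        b0, b1 = gfp.baseline_window
        base = (gfp.t >= b0) & (gfp.t < b1)
        area = float(np.abs(gfp.z[base]).sum() * dt)
        if area == 0:
            raise ValueError("zero baseline area")
        return mag / area
    raise ValueError(f"unknown normalize mode {normalize!r}")


def erp_metrics(
    eeg: EEGEpochs,
    trial_indices: np.ndarray | None = None,
    threshold_z: float = 3.0,
    response_window: tuple = (0.0, 2.0),
) -> ERPMetrics:
    """Convenience wrapper: ERP -> GFP -> duration and magnitude."""
    erp, t = average_erp(eeg, trial_indices)
    gfp = global_field_power(erp, t)
    n = eeg.n_trials if trial_indices is None else len(np.asarray(trial_indices))
    return ERPMetrics(
        duration_s=erp_duration(gfp, threshold_z, response_window),
        magnitude=erp_magnitude(gfp, threshold_z, response_window),
        normalized_magnitude=erp_magnitude(
            gfp, threshold_z, response_window, normalize="baseline_area"
        ),
        threshold_z=threshold_z,
        n_trials=int(n),
    )


def late_component_peak_per_trial(
    eeg: EEGEpochs,
    trial_indices: np.ndarray | None = None,
    window: tuple = (0.100, 0.300),
) -> np.ndarray:
    """Per-trial peak amplitude of the late ERP component: the maximum
    single-trial GFP z-score inside ``window`` (default 100-300 ms), each
    trial z-scored against its own baseline."""
    if trial_indices is None:
        trial_indices = np.arange(eeg.n_trials)
    out = np.empty(len(trial_indices))
    for k, i in enumerate(np.asarray(trial_indices)):
        trial = eeg.data[i][eeg.good_channel, :].astype(np.float64)
        gfp = global_field_power(trial, eeg.t)
        m = gfp.response_mask(window)
        out[k] = gfp.z[m].max()
    return out
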