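"""Signal preprocessing: artifact masking, filtering, referencing,
down-sampling and trial-state classification.

The electrical stimulus leaves a short artifact transient in every
recorded data stream. It is masked by copying the 2 ms of signal
immediately preceding the stimulus, reversing it in time, and writing it
over the 0..+2 ms window — identically for EEG, LFP and spike-band data.
Spikes timestamped inside the artifact window are deleted.

EEG: common-average reference over good channels, zero-phase third-order
Butterworth band-pass 0.1-100 Hz. LFP: anti-alias filter and decimate
2.5 kHz -> 1.25 kHz, first-order high-pass, then subtraction of the
per-time-point median over the channels sitting in ACSF above the brain.
Filters are applied forward-backward (zero phase) so ERP peak latencies
are not shifted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .session import EEGEpochs, ProbeLFP, SpeedSeries, SpikeTrainSet, Unit


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------

def mask_artifact(
    trace: np.ndarray,
    onset_index: int,
    fs: float,
    pre_ms: float = 2.0,
    post_ms: float = 2.0,
) -> np.ndarray:
    """Replace ``[onset, onset+post_ms)`` with the time-reverse of
    ``[onset-pre_ms, onset)`` along the last axis. All other samples are
    unchanged; the input is not modified.

    The replacement window is the reversed copy of the window preceding
    the onset, so applying the mask twice equals applying it once.
    """
    trace = np.asarray(trace)
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    if onset_index - n_pre < 0 or onset_index + n_post > trace.shape[-1]:
        raise ValueError("mask window exceeds trace bounds")
    out = trace.copy()
    src = trace[..., onset_index - n_pre : onset_index]
    rev = src[..., ::-1]
    out[..., onset_index : onset_index + n_post] = rev[..., :n_post]
    return out


def remove_artifact_spikes(
    units: SpikeTrainSet, onsets: np.ndarray, window_s: tuple = (0.0, 0.002)
) -> SpikeTrainSet:
    """Delete spikes that fall inside the artifact window after any
    stimulus onset (times in ``(onset, onset+2 ms]`` by default)."""
    onsets = np.asarray(onsets, float)
    out = []
    for u in units:
        st = u.spike_times
        rel_idx = np.searchsorted(onsets, st) - 1
        rel_idx = np.clip(rel_idx, 0, len(onsets) - 1)
        rel = st - onsets[rel_idx]
        keep = ~((rel > window_s[0]) & (rel <= window_s[1]))
        out.append(Unit(u.unit_id, st[keep], u.waveform_duration_ms, u.region))
    return SpikeTrainSet(out)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_array(
    continuous: np.ndarray, fs: float, onsets_s: np.ndarray, window_s: tuple = (-2.0, 2.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a continuous (channels x time) array into trials x channels x
    time epochs; returns ``(epochs, t)`` with t relative to onset."""
    continuous = np.atleast_2d(continuous)
    i0 = int(round(window_s[0] * fs))
    n_t = int(round((window_s[1] - window_s[0]) * fs))
    t = (np.arange(n_t) + i0) / fs
    idx = np.round(np.asarray(onsets_s) * fs).astype(int)
    if np.any(idx + i0 < 0) or np.any(idx + i0 + n_t > continuous.shape[-1]):
        raise ValueError("epoch window exceeds recording span")
    epochs = np.stack([continuous[:, j + i0 : j + i0 + n_t] for j in idx])
    return epochs, t


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def preprocess_eeg(
    eeg: EEGEpochs,
    good_channel: np.ndarray | None = None,
    band_hz: tuple = (0.1, 100.0),
    mask: bool = True,
) -> EEGEpochs:
    """Mask the stimulus artifact, re-reference to the common average of
    good channels, and band-pass filter (zero-phase Butterworth, third
    order, 0.1-100 Hz)."""
    good = eeg.good_channel if good_channel is None else np.asarray(good_channel, bool)
    if good.sum() < 2:
        raise ValueError("need at least 2 good channels")
    data = eeg.data.astype(np.float64)
    if mask:
        data = mask_artifact(data, eeg.onset_index(), eeg.fs)
    car = data[:, good, :].mean(axis=1, keepdims=True)
    data = data - car
    sos = sps.butter(3, band_hz, btype="bandpass", fs=eeg.fs, output="sos")
    # odd-reflection padding suppresses the low-cutoff edge transient that
    # per-epoch filtering would otherwise leak into the response window
    padlen = min(data.shape[-1] - 1, int(0.5 * eeg.fs))
    data = sps.sosfiltfilt(sos, data, axis=-1, padtype="odd", padlen=padlen)
    return EEGEpochs(
        data=data.astype(np.float32),
        fs=eeg.fs,
        t=eeg.t,
        good_channel=good,
        pos_mm=eeg.pos_mm,
        stim_site_mm=eeg.stim_site_mm,
    )


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def preprocess_lfp(
    lfp: ProbeLFP,
    surface_channels: np.ndarray | None = None,
    highpass_hz: float = 0.1,
    mask: bool = True,
) -> ProbeLFP:
    """Mask the artifact, anti-alias filter and decimate by 2 (2.5 kHz ->
    1.25 kHz), first-order zero-phase high-pass, then subtract the
    per-time-point median of the surface (ACSF) channels.

    The anti-alias filter is an 8th-order Butterworth low-pass at
    0.4 x the output rate.
    """
    surf = lfp.surface_channels if surface_channels is None else np.asarray(surface_channels)
    data = lfp.data.astype(np.float64)
    if mask:
        data = mask_artifact(data, lfp.onset_index(), lfp.fs)
    fs_out = lfp.fs / 2.0
    sos_aa = sps.butter(8, 0.4 * fs_out, btype="low", fs=lfp.fs, output="sos")
    data = sps.sosfiltfilt(sos_aa, data, axis=-1)
    data = data[..., ::2]
    t = lfp.t[::2]
    sos_hp = sps.butter(1, highpass_hz, btype="high", fs=fs_out, output="sos")
    padlen = min(data.shape[-1] - 1, int(0.5 * fs_out))
    data = sps.sosfiltfilt(sos_hp, data, axis=-1, padtype="odd", padlen=padlen)
    if len(surf) >= 1:
        ref = np.median(data[:, surf, :], axis=1, keepdims=True)
        data = data - ref
    else:
        warnings.warn("no surface channels: skipping median referencing")
    return ProbeLFP(
        data=data.astype(np.float32),
        fs=fs_out,
        t=t,
        depth_um=lfp.depth_um,
        layer=lfp.layer,
        region=lfp.region,
        surface_channels=surf,
    )


# ---------------------------------------------------------------------------
# Trial state classification
# ---------------------------------------------------------------------------

def classify_trial_state(
    trials: pd.DataFrame,
    speed: SpeedSeries | None,
    anesthesia_intervals: list | None = None,
    recovery_intervals: list | None = None,
    speed_window_s: tuple = (-0.5, 0.5),
    speed_tol_cm_s: float = 1e-6,
) -> pd.DataFrame:
    """Label each trial quiet / running / anesthetized / recovery.

    Precedence: a trial whose onset falls inside an anesthesia interval is
    ``anesthetized`` (regardless of speed); inside a recovery interval,
    ``recovery``. Otherwise a trial is ``quiet`` when the mean running
    speed in (-0.5, +0.5) s around the onset is 0 cm/s (within
    ``speed_tol_cm_s``), else ``running``. Trials without speed coverage
    are flagged ``unclassifiable``.
    """
    anesthesia_intervals = anesthesia_intervals or []
    recovery_intervals = recovery_intervals or []
    labels = []
    for onset in trials["onset_s"]:
        if any(a <= onset <= b for a, b in anesthesia_intervals):
            labels.append("anesthetized")
            continue
        if any(a <= onset <= b for a, b in recovery_intervals):
            labels.append("recovery")
            continue
        if speed is None:
            labels.append("unclassifiable")
            continue
        m = speed.mean_in_window(onset + speed_window_s[0], onset + speed_window_s[1])
        if np.isnan(m):
            labels.append("unclassifiable")
        elif abs(m) <= speed_tol_cm_s:
            labels.append("quiet")
        else:
            labels.append("running")
    out = trials.copy()
    out["state"] = labels
    return out
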