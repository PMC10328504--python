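"""In-memory session model and the internal HDF5 session format.

A session bundles everything one recording contributes to the analysis:
a trial table (stimulus onsets with behavioral-state and stimulation
metadata), epoched 30-channel EEG, epoched laminar probe LFP, sorted
spike trains with waveform durations and region labels, and a running
speed trace. Synthetic sessions and (optionally) NWB-backed sessions are
both materialized into this model so every downstream stage sees one
schema.

On disk a session is a single HDF5 file with groups ``/trials``,
``/eeg``, ``/lfp/<probe>``, ``/units``, ``/speed`` and ``/meta``; see
:func:`save_session` for the exact datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

STATES = ("quiet", "running", "anesthetized", "recovery")

TRIAL_COLUMNS = ("onset_s", "state", "stim_depth", "stim_area", "current_ua")


def validate_trials(trials: pd.DataFrame, min_gap_s: float = 3.0) -> None:
    """Check trial-table invariants: required columns, strictly increasing
    onsets, known state labels. Onset gaps below ``min_gap_s`` only warn."""
    import warnings

    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    onsets = trials["onset_s"].to_numpy(float)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise ValueError("trial onsets must be strictly increasing")
    if onsets.size and np.any(np.diff(onsets) < min_gap_s):
        warnings.warn(f"consecutive trial onsets closer than {min_gap_s} s")
    bad = set(trials["state"].unique()) - set(STATES) - {"unclassifiable"}
    if bad:
        raise ValueError(f"unknown state labels: {sorted(bad)}")


@dataclass
class EEGEpochs:
    """Epoched EEG: ``data`` is trials x channels x time in microvolts,
    with the time axis spanning -2..+2 s around each stimulus onset."""

    data: np.ndarray
    fs: float
    t: np.ndarray
    good_channel: np.ndarray
    pos_mm: np.ndarray
    stim_site_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("EEG data must be trials x channels x time")
        if self.data.shape[1] != self.pos_mm.shape[0]:
            raise ValueError("channel count does not match layout")
        if self.data.shape[2] != self.t.size:
            raise ValueError("time axis does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.t)))


@dataclass
class ProbeLFP:
    """Epoched laminar probe LFP: trials x channels x time (microvolts).

    ``depth_um`` is depth below the brain surface per channel (negative
    above the brain); ``surface_channels`` index channels sitting in the
    ACSF above the surface, used for median referencing.
    """

    data: np.ndarray
    fs: float
    t: np.ndarray
    depth_um: np.ndarray
    layer: np.ndarray
    region: np.ndarray
    surface_channels: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("LFP data must be trials x channels x time")
        d = np.asarray(self.depth_um, float)
        if d.size > 1 and not (np.all(np.diff(d) > 0) or np.all(np.diff(d) < 0)):
            raise ValueError("probe channel depths must be strictly monotone")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.t)))


@dataclass
class Unit:
    """One sorted unit: absolute spike times (s) over the session."""

    unit_id: int
    spike_times: np.ndarray
    waveform_duration_ms: float
    region: str

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, float)
        if st.size > 1 and np.any(np.diff(st) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times not strictly increasing")
        if self.waveform_duration_ms <= 0:
            raise ValueError("waveform duration must be positive")
        self.spike_times = st

    @property
    def cell_class(self) -> str:
        # RS / FS split at 0.4 ms waveform duration (boundary goes to FS)
        return "RS" if self.waveform_duration_ms > 0.4 else "FS"


@dataclass
class SpikeTrainSet:
    units: list[Unit] = field(default_factory=list)

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def select(self, region: str | None = None, cell_class: str | None = None) -> "SpikeTrainSet":
        out = [
            u
            for u in self.units
            if (region is None or u.region == region)
            and (cell_class is None or u.cell_class == cell_class)
        ]
        return SpikeTrainSet(out)

    def regions(self) -> list[str]:
        return sorted({u.region for u in self.units})


@dataclass
class SpeedSeries:
    """Running-wheel speed (cm/s) sampled uniformly over the session."""

    t: np.ndarray
    speed: np.ndarray

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def mean_in_window(self, t0: float, t1: float) -> float:
        sel = (self.t >= t0) & (self.t <= t1)
        if not np.any(sel):
            return np.nan
        return float(np.mean(self.speed[sel]))


@dataclass
class SessionData:
    trials: pd.DataFrame
    eeg: EEGEpochs | None = None
    lfp: dict[str, ProbeLFP] = field(default_factory=dict)
    units: SpikeTrainSet | None = None
    speed: SpeedSeries | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_trials(self.trials)


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def save_session(session: SessionData, path: str) -> None:
    """Write a session to the internal HDF5 format.

    Layout::

        /trials/{onset_s,state,stim_depth,stim_area,current_ua}
        /eeg/{data,fs,t,good_channel,pos_mm,stim_site_mm}
        /lfp/<probe>/{data,fs,t,depth_um,layer,region,surface_channels}
        /units/{spike_times,offsets,unit_id,waveform_duration_ms,region}
        /speed/{t,speed}
        /meta  (JSON-encoded attribute: config echo + seed)
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = session.trials[col].to_numpy()
            if vals.dtype.kind in "OU":
                vals = np.array([str(v) for v in vals], dtype="S32")
            g.create_dataset(col, data=vals)
        if session.eeg is not None:
            e = f.create_group("eeg")
            e.create_dataset("data", data=session.eeg.data, compression="gzip", compression_opts=1)
            e.create_dataset("t", data=session.eeg.t)
            e.create_dataset("good_channel", data=session.eeg.good_channel)
            e.create_dataset("pos_mm", data=session.eeg.pos_mm)
            e.create_dataset("stim_site_mm", data=session.eeg.stim_site_mm)
            e.attrs["fs"] = session.eeg.fs
        for name, probe in session.lfp.items():
            p = f.create_group(f"lfp/{name}")
            p.create_dataset("data", data=probe.data, compression="gzip", compression_opts=1)
            p.create_dataset("t", data=probe.t)
            p.create_dataset("depth_um", data=probe.depth_um)
            p.create_dataset("layer", data=np.array(probe.layer, dtype="S16"))
            p.create_dataset("region", data=np.array(probe.region, dtype="S16"))
            p.create_dataset("surface_channels", data=probe.surface_channels)
            p.attrs["fs"] = probe.fs
        if session.units is not None and len(session.units):
            u = f.create_group("units")
            counts = [u_.spike_times.size for u_ in session.units]
            offsets = np.concatenate([[0], np.cumsum(counts)])
            u.create_dataset(
                "spike_times",
                data=(
                    np.concatenate([u_.spike_times for u_ in session.units])
                    if offsets[-1]
                    else np.zeros(0)
                ),
            )
            u.create_dataset("offsets", data=offsets)
            u.create_dataset("unit_id", data=np.array([u_.unit_id for u_ in session.units]))
            u.create_dataset(
                "waveform_duration_ms",
                data=np.array([u_.waveform_duration_ms for u_ in session.units]),
            )
            u.create_dataset(
                "region", data=np.array([u_.region for u_ in session.units], dtype="S16")
            )
        if session.speed is not None:
            s = f.create_group("speed")
            s.create_dataset("t", data=session.speed.t)
            s.create_dataset("speed", data=session.speed.speed)
        f.attrs["meta"] = json.dumps(session.meta, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def load_session(path: str) -> SessionData:
    """Read a session from the internal HDF5 format (inverse of
    :func:`save_session`). Malformed files raise ``ValueError`` naming the
    missing group."""
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise ValueError(f"{path}: not a session file (missing /trials group)")
        cols = {}
        for col in TRIAL_COLUMNS:
            if col not in f["trials"]:
                raise ValueError(f"{path}: /trials missing dataset {col!r}")
            vals = f["trials"][col][()]
            if vals.dtype.kind == "S":
                vals = np.array([v.decode() for v in vals])
            cols[col] = vals
        trials = pd.DataFrame(cols)
        eeg = None
        if "eeg" in f:
            e = f["eeg"]
            eeg = EEGEpochs(
                data=e["data"][()],
                fs=float(e.attrs["fs"]),
                t=e["t"][()],
                good_channel=e["good_channel"][()].astype(bool),
                pos_mm=e["pos_mm"][()],
                stim_site_mm=e["stim_site_mm"][()],
            )
        lfp = {}
        if "lfp" in f:
            for name in f["lfp"]:
                p = f["lfp"][name]
                lfp[name] = ProbeLFP(
                    data=p["data"][()],
                    fs=float(p.attrs["fs"]),
                    t=p["t"][()],
                    depth_um=p["depth_um"][()],
                    layer=np.array([v.decode() for v in p["layer"][()]]),
                    region=np.array([v.decode() for v in p["region"][()]]),
                    surface_channels=p["surface_channels"][()],
                )
        units = None
        if "units" in f:
            u = f["units"]
            offsets = u["offsets"][()]
            times = u["spike_times"][()]
            regions = [v.decode() for v in u["region"][()]]
            units = SpikeTrainSet(
                [
                    Unit(
                        unit_id=int(u["unit_id"][i]),
                        spike_times=times[offsets[i] : offsets[i + 1]],
                        waveform_duration_ms=float(u["waveform_duration_ms"][i]),
                        region=regions[i],
                    )
                    for i in range(len(offsets) - 1)
                ]
            )
        speed = None
        if "speed" in f:
            speed = SpeedSeries(t=f["speed"]["t"][()], speed=f["speed"]["speed"][()])
        meta = json.loads(f.attrs.get("meta", "{}"))
    return SessionData(trials=trials, eeg=eeg, lfp=lfp, units=units, speed=speed, meta=meta)
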