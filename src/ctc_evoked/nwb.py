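"""Read-only adapter mapping NWB sessions (DANDI:000458 layout) onto the
internal session model.

Requires ``pynwb`` at call time; the rest of the package has no NWB
dependency, so synthetic-session workflows run without it. The adapter
maps the NWB electrode table, units table, running-speed time series and
stimulus-table onsets onto :class:`~ctc_evoked.session.SessionData`;
epoched EEG/LFP are cut from the continuous acquisitions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import epoch_array
from .session import (
    EEGEpochs,
    SessionData,
    SpeedSeries,
    SpikeTrainSet,
    Unit,
)


def read_nwb_session(path: str, epoch_window_s: tuple = (-2.0, 2.0)) -> SessionData:
    try:
        from pynwb import NWBHDF5IO
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading NWB sessions requires the optional dependency 'pynwb'"
        ) from exc

    with NWBHDF5IO(path, mode="r", load_namespaces=True) as io:
        nwb = io.read()
        stim = nwb.intervals.get("electrical_stimulation") or nwb.trials
        if stim is None:
            raise ValueError(f"{path}: no stimulus table found")
        sdf = stim.to_dataframe()
        trials = pd.DataFrame(
            {
                "onset_s": sdf["start_time"].to_numpy(float),
                "state": sdf.get("behavioral_epoch", "quiet"),
                "stim_depth": sdf.get("stimulus_depth", "deep"),
                "stim_area": sdf.get("stimulus_area", "unknown"),
                "current_ua": sdf.get("current", np.nan),
            }
        )

        eeg = None
        acq = nwb.acquisition
        eeg_key = next((k for k in acq if "eeg" in k.lower()), None)
        if eeg_key is not None:
            ts = acq[eeg_key]
            fs = float(ts.rate)
            raw = np.asarray(ts.data[:]).T  # channels x time
            epochs, t = epoch_array(raw, fs, trials["onset_s"].to_numpy(),
                                    epoch_window_s)
            n_ch = raw.shape[0]
            eeg = EEGEpochs(
                data=epochs.astype(np.float32),
                fs=fs,
                t=t,
                good_channel=np.ones(n_ch, bool),
                pos_mm=np.zeros((n_ch, 2)),
                stim_site_mm=np.zeros(2),
            )

        units = None
        if nwb.units is not None:
            udf = nwb.units.to_dataframe()
            unit_list = []
            for uid, row in udf.iterrows():
                st = np.sort(np.asarray(row["spike_times"], float))
                dur = float(row.get("waveform_duration", 0.5))
                region = str(row.get("location", row.get("region", "unknown")))
                unit_list.append(Unit(int(uid), np.unique(st), dur, region))
            units = SpikeTrainSet(unit_list)

        speed = None
        proc = getattr(nwb, "processing", {})
        for mod in proc.values():
            for name, obj in mod.data_interfaces.items():
                if "speed" in name.lower() or "running" in name.lower():
                    tt = np.asarray(obj.timestamps[:], float)
                    speed = SpeedSeries(t=tt, speed=np.asarray(obj.data[:], float))
                    break
        meta = {"source": path, "format": "nwb",
                "speed_available": speed is not None}
    return SessionData(trials=trials, eeg=eeg, lfp={}, units=units, speed=speed,
                       meta=meta)
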