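"""Spiking dynamics: modulation fractions, latencies, bursts, off
periods.

Loads the deep-stimulation session, removes artifact-window spikes, and
quantifies per state: the fraction of RS neurons significantly modulated
in the 2-25 / 25-150 / 150-300 ms windows (signed-rank + BH), the
population first-spike latencies in the early and rebound windows for
cortex vs thalamus, the thalamic burst probability, and the cortical
off-period duration. Expected pattern: cortex leads thalamus by ~ms in
the early window and lags it in the rebound; bursts and the off period
are a quiet-wakefulness phenomenon and vanish under anesthesia.
"""

import pathlib

import numpy as np
import pandas as pd

import ctc_evoked as ce
from ctc_evoked import spiking
from ctc_evoked.preprocess import remove_artifact_spikes
from ctc_evoked.synth import CORTEX, THALAMUS

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
session = ce.load_session(str(ROOT.parent / "scratch" / "sessions" / "deep_seed0.h5"))
units = remove_artifact_spikes(session.units, session.trials["onset_s"].to_numpy())
cortex = units.select(region=CORTEX, cell_class="RS")
thal = units.select(region=THALAMUS)

rows = []
for state in ("quiet", "running", "anesthetized"):
    onsets = session.trials.loc[session.trials["state"] == state, "onset_s"].to_numpy()
    mod = spiking.modulated_units(units, onsets)
    frac = (
        mod.assign(modulated=mod["label"] != "none")
        .groupby("window")["modulated"]
        .mean()
    )
    _, early_c = spiking.first_spike_latency(cortex, onsets, (0.002, 0.025))
    _, early_t = spiking.first_spike_latency(thal, onsets, (0.002, 0.025))
    _, late_c = spiking.first_spike_latency(cortex, onsets, (0.075, 0.300))
    _, late_t = spiking.first_spike_latency(thal, onsets, (0.075, 0.300))
    sd = spiking.spike_density(cortex, onsets, normalize=None)
    try:
        off_ms = spiking.off_period_duration(sd.t, sd.population) * 1000
    except ValueError:
        off_ms = np.nan
    rows.append(
        {
            "state": state,
            "frac_mod_2_25": round(frac.get("2-25ms", 0.0), 3),
            "frac_mod_25_150": round(frac.get("25-150ms", 0.0), 3),
            "frac_mod_150_300": round(frac.get("150-300ms", 0.0), 3),
            "early_latency_cortex_ms": round(early_c * 1000, 1),
            "early_latency_thal_ms": round(early_t * 1000, 1),
            "late_latency_cortex_ms": round(late_c * 1000, 1),
            "late_latency_thal_ms": round(late_t * 1000, 1),
            "burst_probability": round(spiking.burst_probability(thal, onsets), 3),
            "off_period_ms": round(off_ms, 1),
        }
    )

table = pd.DataFrame(rows)
table.to_csv(ROOT / "spiking_by_state.csv", index=False)
print(table.to_string(index=False))

bursts = spiking.burst_table(
    thal, session.trials.loc[session.trials["state"] == "quiet", "onset_s"].to_numpy()
)
bursts.to_csv(ROOT / "bursts_quiet.csv", index=False)
print(f"\n{len(bursts)} thalamic bursts in quiet trials "
      f"(median size {bursts['n_spikes'].median():.0f} spikes)")
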