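"""PCI-ST complexity of the state-resolved ERPs.

Loads both sessions, trial-matches the states within each session, and
computes PCI-ST (baseline -0.8..-0.002 s, response 0.002..0.8 s,
min SNR 1.6, max variance 99%, k = 1.2) on each state's trial-averaged
ERP. Expected pattern: quiet wakefulness > running > anesthetized for
deep stimulation, and superficial < deep in the awake state.
"""

import pathlib

import pandas as pd

import ctc_evoked as ce
from ctc_evoked import erp as erpm
from ctc_evoked import pci
from ctc_evoked.preprocess import preprocess_eeg

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"

rows = []
for path in sorted((ROOT.parent / "scratch" / "sessions").glob("*.h5")):
    session = ce.load_session(str(path))
    eeg = preprocess_eeg(session.eeg)
    states = sorted(session.trials["state"].unique())
    matched = pci.trial_matched_states(session.trials, states, seed=0)
    for state, idx in matched.items():
        erp, t = erpm.average_erp(eeg, idx)
        res = pci.compute_pci_st(erp, t)
        rows.append(
            {
                "session": path.stem,
                "stim_depth": session.trials["stim_depth"].iloc[0],
                "state": state,
                "pci_st": round(res.value, 2),
                "n_components": res.n_components,
                "n_trials": len(idx),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(ROOT / "pci.csv", index=False)
print(table.to_string(index=False))
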