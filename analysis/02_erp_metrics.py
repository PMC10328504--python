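"""ERP global-field-power metrics by state and stimulation depth.

Loads the simulated sessions, preprocesses the EEG (artifact mask,
common average reference, 0.1-100 Hz band-pass), and scores each
state's trial-averaged ERP by suprathreshold GFP duration and magnitude.
Expected pattern: the deep/quiet ERP carries both the ~25 ms and the
~180 ms component and scores longest/largest; anesthetized and
superficial ERPs lack the late component and score much lower.
"""

import pathlib

import numpy as np
import pandas as pd

import ctc_evoked as ce
from ctc_evoked import erp as erpm
from ctc_evoked.preprocess import preprocess_eeg

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"

rows = []
for path in sorted((ROOT.parent / "scratch" / "sessions").glob("*.h5")):
    session = ce.load_session(str(path))
    eeg = preprocess_eeg(session.eeg)
    depth = session.trials["stim_depth"].iloc[0]
    for state in session.trials["state"].unique():
        idx = np.nonzero((session.trials["state"] == state).to_numpy())[0]
        m = erpm.erp_metrics(eeg, idx)
        rows.append(
            {
                "session": path.stem,
                "stim_depth": depth,
                "state": state,
                "duration_s": round(m.duration_s, 4),
                "magnitude_sd_s": round(m.magnitude, 3),
                "n_trials": m.n_trials,
            }
        )

table = pd.DataFrame(rows).sort_values(["stim_depth", "state"])
table.to_csv(ROOT / "erp_metrics.csv", index=False)
print(table.to_string(index=False))

deep = table[(table.stim_depth == "deep")].set_index("state")
sup = table[table.stim_depth == "superficial"].iloc[0]
print(
    f"\ndeep/quiet magnitude {deep.loc['quiet', 'magnitude_sd_s']:.1f} SD*s vs "
    f"anesthetized {deep.loc['anesthetized', 'magnitude_sd_s']:.1f} vs "
    f"superficial {sup.magnitude_sd_s:.1f}"
)
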