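"""Statistical comparison layer across synthetic subjects.

Treats independently seeded sessions as subjects and reproduces the
study's comparison structure on synthetic data: paired PCI-ST quiet vs
anesthetized, repeated-measures comparison of ERP magnitude across the
three states, and the trial-wise Pearson correlation between the
fraction of bursting thalamic units and the late-ERP peak amplitude.
All comparisons are normality-gated (Shapiro-Wilk) and two-sided.
"""

import pathlib

import numpy as np
import pandas as pd

import ctc_evoked as ce
from ctc_evoked import erp as erpm
from ctc_evoked import pci, spiking
from ctc_evoked.preprocess import preprocess_eeg
from ctc_evoked.stats import (
    compare_two_groups,
    repeated_measures_compare,
    trialwise_correlation,
)
from ctc_evoked.synth import THALAMUS

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"
N_SUBJECTS = 6
N_TRIALS = 40

per_subject = []
corr_rows = []
for seed in range(N_SUBJECTS):
    cfg = ce.default_config(
        "deep", states=("quiet", "running", "anesthetized"),
        n_trials_per_state=N_TRIALS, seed=seed,
    )
    session = ce.simulate_session(cfg)
    eeg = preprocess_eeg(session.eeg)
    matched = pci.trial_matched_states(session.trials,
                                       ["quiet", "running", "anesthetized"], seed=seed)
    row = {"subject": seed}
    for state, idx in matched.items():
        erp, t = erpm.average_erp(eeg, idx)
        row[f"pci_{state}"] = pci.compute_pci_st(erp, t).value
        row[f"mag_{state}"] = erpm.erp_metrics(eeg, idx).magnitude
    per_subject.append(row)

    quiet_idx = np.nonzero((session.trials["state"] == "quiet").to_numpy())[0]
    onsets = session.trials["onset_s"].to_numpy()[quiet_idx]
    fb = spiking.fraction_bursting(session.units.select(region=THALAMUS), onsets)
    peak = erpm.late_component_peak_per_trial(eeg, quiet_idx)
    r, p = trialwise_correlation(fb, peak)
    corr_rows.append({"subject": seed, "r": round(r, 3), "p": p,
                      "significant": p < 0.05})
    print(f"subject {seed}: pci quiet {row['pci_quiet']:.1f} vs anesthetized "
          f"{row['pci_anesthetized']:.1f}; burst~ERP r={r:.2f} (p={p:.2g})")

subj = pd.DataFrame(per_subject)
out = []

res = compare_two_groups(subj["pci_quiet"], subj["pci_anesthetized"], paired=True)
out.append({"comparison": "pci quiet vs anesthetized", "test": res.test,
            "statistic": round(res.statistic, 3), "p": res.p,
            "direction": res.direction})

rm = repeated_measures_compare(subj[["mag_quiet", "mag_running", "mag_anesthetized"]])
out.append({"comparison": "erp magnitude across states", "test": rm.test,
            "statistic": round(rm.statistic, 3), "p": rm.p, "direction": rm.direction})

stats_table = pd.DataFrame(out)
stats_table.to_csv(ROOT / "state_stats.csv", index=False)
pd.DataFrame(corr_rows).to_csv(ROOT / "burst_erp_correlation.csv", index=False)
print("\n" + stats_table.to_string(index=False))
n_sig = sum(r["significant"] for r in corr_rows)
print(f"\nburst-fraction ~ late-ERP correlation significant in "
      f"{n_sig}/{N_SUBJECTS} subjects")
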