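"""Simulate the study's session types and write them to disk.

Generates one deep-stimulation session with quiet / running /
anesthetized blocks and one superficial-stimulation session (quiet
only), both with EEG and sorted spike trains, and stores them in the
internal HDF5 format under scratch/sessions/. These files feed the
numbered analyses that follow.
"""

import pathlib

import ctc_evoked as ce

# sessions are bulky HDF5 scratch data; only derived tables go to results/
OUT = pathlib.Path(__file__).resolve().parent.parent / "scratch" / "sessions"
OUT.mkdir(parents=True, exist_ok=True)

N_TRIALS = 60  # per state; enough for stable ERPs at script runtime scale
SEED = 0

for depth, states in [
    ("deep", ("quiet", "running", "anesthetized")),
    ("superficial", ("quiet",)),
]:
    cfg = ce.default_config(depth, states=states, n_trials_per_state=N_TRIALS,
                            seed=SEED)
    session = ce.simulate_session(cfg)
    path = OUT / f"{depth}_seed{SEED}.h5"
    ce.save_session(session, str(path))
    n_units = len(session.units)
    print(
        f"{depth}: {len(session.trials)} trials over {list(states)}, "
        f"{n_units} units, EEG {session.eeg.data.shape} -> {path.name}"
    )
print("done")
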