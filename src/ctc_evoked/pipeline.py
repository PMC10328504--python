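"""End-to-end orchestration: simulate or load a session, preprocess,
compute ERP metrics, CSD, spiking analytics and PCI-ST, and write tidy
result tables with a reproducibility manifest.

Stage order mirrors the acquisition-to-analysis flow: artifact masking
and preprocessing come first, then trial-state-resolved metrics. Every
run writes ``manifest.json`` (config hash, seed) from which the tables
can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csd as csd_mod
from . import erp as erp_mod
from . import pci as pci_mod
from . import spiking
from .preprocess import preprocess_eeg, preprocess_lfp, remove_artifact_spikes
from .session import SessionData, load_session, save_session
from .synth import CORTEX, THALAMUS, SimConfig, default_config, simulate_session


@dataclass
class RunConfig:
    """One pipeline run: a synthetic config or a session file, stage
    toggles, module parameters, output directory and master seed."""

    out_dir: str
    seed: int = 0
    session_path: str | None = None
    sim: SimConfig | None = None
    stages: dict = field(
        default_factory=lambda: {
            "erp": True,
            "csd": True,
            "spiking": True,
            "pci": True,
        }
    )
    pci_params: pci_mod.PCIParams = field(default_factory=pci_mod.PCIParams)
    burst_window_s: tuple = (0.075, 0.300)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        sim = raw.pop("sim", None)
        if sim is not None:
            depth = sim.pop("stim_depth", "deep")
            sim = default_config(depth, **sim)
        pci_params = pci_mod.PCIParams(**raw.pop("pci_params", {}))
        return cls(sim=sim, pci_params=pci_params, **raw)


def read_session(path: str, format: str = "internal") -> SessionData:
    """Load a session from the internal HDF5 format or from an NWB file
    (DANDI:000458 layout; requires ``pynwb``)."""
    if format == "internal":
        return load_session(path)
    if format == "nwb":
        from .nwb import read_nwb_session

        return read_nwb_session(path)
    raise ValueError(f"unknown session format {format!r}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write result tables under
    ``cfg.out_dir``. Returns the result bundle (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "config": asdict(cfg)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if cfg.session_path is not None:
        session = read_session(cfg.session_path)
    elif cfg.sim is not None:
        sim = cfg.sim
        if sim.seed is None:
            sim.seed = cfg.seed
        session = simulate_session(sim)
    else:
        raise StageError("input", ValueError("neither session_path nor sim configured"))

    bundle: dict = {"manifest": manifest}
    states = sorted(session.trials["state"].unique())

    eeg = None
    if session.eeg is not None:
        eeg = preprocess_eeg(session.eeg)
    units = session.units
    if units is not None:
        units = remove_artifact_spikes(units, session.trials["onset_s"].to_numpy())

    if cfg.stages.get("erp", True):
        if eeg is None:
            raise StageError("erp", ValueError("no EEG in session"))
        rows = []
        for state in states:
            idx = np.nonzero((session.trials["state"] == state).to_numpy())[0]
            m = erp_mod.erp_metrics(eeg, idx)
            rows.append(
                {
                    "state": state,
                    "stim_depth": session.trials["stim_depth"].iloc[0],
                    "duration_s": m.duration_s,
                    "magnitude_sd_s": m.magnitude,
                    "normalized_magnitude": m.normalized_magnitude,
                    "n_trials": m.n_trials,
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / "erp_metrics.csv", index=False)
        bundle["erp_metrics"] = table

    if cfg.stages.get("csd", True) and session.lfp:
        for name, probe in session.lfp.items():
            clean = preprocess_lfp(probe)
            cortical = clean.region == CORTEX
            if cortical.sum() < 3:
                warnings.warn(f"probe {name}: too few cortical channels for CSD")
                continue
            cmap = csd_mod.lfp_to_csd(
                clean.data[:, cortical, :], clean.fs,
                clean.depth_um[cortical], clean.t,
            )
            np.savez(out / f"csd_{name}.npz", values=cmap.values, depth=cmap.depth,
                     t=cmap.t, sigma=cmap.sigma)
            bundle[f"csd_{name}"] = cmap

    if cfg.stages.get("spiking", True) and units is not None:
        onsets = session.trials["onset_s"].to_numpy()
        mod = spiking.modulated_units(units, onsets)
        mod.to_csv(out / "modulated_units.csv", index=False)
        bundle["modulated_units"] = mod
        th = units.select(region=THALAMUS)
        if len(th):
            bt = spiking.burst_table(th, onsets, cfg.burst_window_s)
            bt.to_csv(out / "bursts.csv", index=False)
            bundle["bursts"] = bt

    if cfg.stages.get("pci", True):
        if eeg is None:
            raise StageError("pci", ValueError("no EEG in session"))
        matched = pci_mod.trial_matched_states(session.trials, states, seed=cfg.seed)
        rows = []
        for state, idx in matched.items():
            erp, t = erp_mod.average_erp(eeg, idx)
            res = pci_mod.compute_pci_st(erp, t, cfg.pci_params)
            rows.append(
                {
                    "state": state,
                    "pci_st": res.value,
                    "n_components": res.n_components,
                    "n_trials": len(idx),
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(out / "pci.csv", index=False)
        bundle["pci"] = table

    return bundle


__all__ = ["RunConfig", "run_pipeline", "read_session", "StageError",
            "save_session", "load_session"]
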