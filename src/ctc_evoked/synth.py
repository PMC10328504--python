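"""Seeded synthetic sessions with cortico-thalamo-cortical response structure.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without any recorded
data:

* stimulus-locked trials at 3.5-4.5 s inter-stimulus intervals, in
  per-state blocks (quiet wakefulness, running, anesthetized, recovery);
* state-dependent baseline firing (cortex 3.5 / 5.2 / 1.1 Hz and
  somatomotor thalamus 9.0 / 16.4 / 0.8 Hz for quiet / running /
  anesthetized);
* a triphasic evoked spiking pattern in cortex and thalamus - initial
  excitation within 25 ms, an *off* period of complete suppression, and a
  rebound excitation - with the thalamic rebound carried by injected
  low-threshold-spike-like bursts (>= 2 spikes, intra-burst ISI < 4 ms,
  preceded by an enforced silent gap >= 100 ms);
* a two-component ERP (peaks near 25 ms and 180 ms) whose late component
  exists only for deep stimulation in wakefulness and vanishes under
  anesthesia;
* optional trial-wise coupling: a latent per-trial burst drive scales the
  thalamic burst probability, the cortical rebound gain and the late-ERP
  amplitude together, producing the trial-by-trial correlations between
  thalamic bursting, cortical rebound firing and the late EEG component.

Spike trains are inhomogeneous Poisson processes with piecewise-constant
gain profiles (baseline 1; excitation gain set so the pooled population
peak rate matches the configured peak; off-period gain 0; rebound gain as
configured), except the thalamic bursts which are injected explicitly.
EEG/LFP epochs are sums of component-weight-map x waveform outer products
plus 1/f (pink) background noise and a brief stimulus artifact transient
in the 0..+2 ms window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .session import (
    STATES,
    EEGEpochs,
    ProbeLFP,
    SessionData,
    SpeedSeries,
    SpikeTrainSet,
    Unit,
)

CORTEX = "MO"
THALAMUS = "SM-TH"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ProbeSpec:
    n_channels: int = 384
    pitch_um: float = 20.0
    n_surface: int = 20
    region: str = CORTEX
    # layer name -> (top, bottom) in um below the brain surface
    layer_boundaries: dict = field(
        default_factory=lambda: {
            "L1": (0.0, 100.0),
            "L2/3": (100.0, 400.0),
            "L5": (400.0, 750.0),
            "L6": (750.0, 1000.0),
        }
    )


@dataclass
class EvokedProfile:
    """Piecewise evoked gain for one region: g(t) = 1 at baseline, a
    constant excitation gain in ``excitation_window``, 0 (or the per-state
    ``off_gain``) in ``off_window`` and the rebound gain in
    ``rebound_window``. Gains are derived from configured *peak population
    rates* divided by the state baseline rate."""

    excitation_window: tuple = (0.002, 0.025)
    off_window: tuple = (0.025, 0.150)
    rebound_window: tuple = (0.150, 0.300)
    excitation_peak_hz: dict = field(default_factory=dict)  # per state
    rebound_peak_hz: dict = field(default_factory=dict)  # per state
    off_gain: dict = field(default_factory=dict)  # per state


@dataclass
class BurstModel:
    p_burst: dict = field(
        default_factory=lambda: {
            "quiet": 0.4,
            "running": 0.15,
            "anesthetized": 0.0,
            "recovery": 0.3,
        }
    )
    size_range: tuple = (2, 6)
    intra_isi_ms: tuple = (1.5, 3.5)
    rebound_mean_s: float = 0.148
    rebound_sd_s: float = 0.015
    enforced_silence_s: float = 0.100


@dataclass
class ERPComponent:
    latency_s: float
    width_s: float
    amp_uv: float
    # traveling-wave latency gradient across the array (~0.3 m/s cortical
    # propagation); centered so the mean latency stays at ``latency_s``
    propagation_ms_per_mm: float = 0.0


@dataclass
class ERPModel:
    early: ERPComponent = field(
        default_factory=lambda: ERPComponent(0.025, 0.008, 30.0, 3.0)
    )
    late: ERPComponent = field(
        default_factory=lambda: ERPComponent(0.180, 0.040, 25.0, 8.0)
    )
    # per-state (early, late) amplitude scales
    state_scale: dict = field(
        default_factory=lambda: {
            "quiet": (1.0, 1.0),
            "running": (1.0, 0.3),
            "anesthetized": (0.6, 0.0),
            "recovery": (0.9, 0.7),
        }
    )
    # propagation scale per state: evoked activity travels across the
    # array during wakefulness but is stereotyped and local under
    # anesthesia (loss of spatiotemporal differentiation)
    state_propagation: dict = field(
        default_factory=lambda: {
            "quiet": 1.0,
            "running": 0.7,
            "anesthetized": 0.0,
            "recovery": 0.8,
        }
    )
    # early map: decays with distance from the stim site and flips sign
    # beyond ~2.4 mm (difference of exponentials); late map is a dipole
    # with a different center, giving genuinely multi-component signals
    early_decay_mm: float = 1.2
    early_neg_frac: float = 0.30
    early_neg_decay_mm: float = 3.0
    late_center_mm: tuple = (-0.5, 0.5)
    late_sigma_mm: float = 2.0


@dataclass
class Coupling:
    enabled: bool = True
    drive_sd: float = 0.3  # sigma of the log-normal latent burst drive


@dataclass
class NoiseModel:
    eeg_pink_uv: float = 5.0
    # background EEG is volume-conducted and hence spatially correlated:
    # most of its power lives in a few shared spatial modes, with a
    # smaller spatially independent residual per channel
    eeg_spatial_modes: int = 5
    eeg_shared_frac: float = 0.75
    lfp_pink_uv: float = 15.0
    lfp_common_uv: float = 10.0
    artifact_uv: float = 300.0


@dataclass
class SimConfig:
    n_trials_per_state: int = 100
    isi_range_s: tuple = (3.5, 4.5)
    states: tuple = ("quiet", "running", "anesthetized")
    stim_depth: str = "deep"
    stim_area: str = "MOs"
    current_ua: float = 50.0
    eeg_fs: float = 2500.0
    eeg_n_channels: int = 30
    probe_spec: ProbeSpec = field(default_factory=ProbeSpec)
    n_units: dict = field(default_factory=lambda: {CORTEX: 52, THALAMUS: 24})
    fs_fraction: float = 0.23  # fraction of cortical units that are FS
    baseline_rate_hz: dict = field(
        default_factory=lambda: {
            CORTEX: {"quiet": 3.5, "running": 5.2, "anesthetized": 1.1, "recovery": 3.0},
            THALAMUS: {"quiet": 9.0, "running": 16.4, "anesthetized": 0.8, "recovery": 8.0},
        }
    )
    evoked_profile: dict = field(default_factory=dict)
    burst_model: BurstModel = field(default_factory=BurstModel)
    erp: ERPModel = field(default_factory=ERPModel)
    coupling: Coupling = field(default_factory=Coupling)
    noise: NoiseModel = field(default_factory=NoiseModel)
    include_eeg: bool = True
    include_lfp: bool = False
    include_spikes: bool = True
    seed: int | None = None


def _deep_profiles() -> dict:
    """Evoked profiles for deep-layer stimulation in quiet wakefulness:
    cortical peak 38.1 Hz then a 125 ms off period then a 7.9 Hz rebound;
    thalamus follows with a ~7 ms delay, a 75 ms suppression and a
    14.7 Hz rebound (carried by bursts). Under anesthesia the off period
    and rebound are absent (gain 1) and the excitation is weaker."""
    return {
        CORTEX: EvokedProfile(
            excitation_window=(0.002, 0.025),
            off_window=(0.025, 0.150),
            rebound_window=(0.150, 0.300),
            excitation_peak_hz={"quiet": 38.1, "running": 38.1, "anesthetized": 20.0,
                                "recovery": 30.0},
            rebound_peak_hz={"quiet": 7.9, "running": 7.9, "anesthetized": 1.1,
                             "recovery": 6.0},
            off_gain={"quiet": 0.0, "running": 0.0, "anesthetized": 1.0, "recovery": 0.0},
        ),
        THALAMUS: EvokedProfile(
            excitation_window=(0.009, 0.032),
            off_window=(0.032, 0.107),
            rebound_window=(0.107, 0.300),
            excitation_peak_hz={"quiet": 22.3, "running": 22.3, "anesthetized": 8.0,
                                "recovery": 18.0},
            rebound_peak_hz={"quiet": 14.7, "running": 14.7, "anesthetized": 0.8,
                             "recovery": 12.0},
            off_gain={"quiet": 0.0, "running": 0.0, "anesthetized": 1.0, "recovery": 0.0},
        ),
    }


def _superficial_profiles() -> dict:
    """Superficial stimulation: local cortical response only, with a
    shorter (94 ms) silence; no thalamic evoked response, no bursts."""
    prof = _deep_profiles()
    c = prof[CORTEX]
    c.off_window = (0.025, 0.025 + 0.0942)
    c.rebound_window = (0.025 + 0.0942, 0.300)
    c.rebound_peak_hz = {k: 5.0 for k in c.rebound_peak_hz}
    c.rebound_peak_hz["anesthetized"] = 1.1
    th = prof[THALAMUS]
    th.excitation_peak_hz = {k: v for k, v in
                             zip(th.excitation_peak_hz, [9.0, 16.4, 0.8, 8.0])}
    th.rebound_peak_hz = dict(th.excitation_peak_hz)
    th.off_gain = {k: 1.0 for k in th.off_gain}
    return prof


def default_config(stim_depth: str = "deep", **overrides) -> SimConfig:
    """Build the default study-condition configuration for one session.

    ``stim_depth='superficial'`` switches to the superficial-stimulation
    variant: zero late-ERP amplitude, no thalamic evoked response or
    bursts, and a shorter cortical silent period.
    """
    cfg = SimConfig(stim_depth=stim_depth, **overrides)
    if not cfg.evoked_profile:
        cfg.evoked_profile = (
            _deep_profiles() if stim_depth == "deep" else _superficial_profiles()
        )
    if stim_depth == "superficial":
        cfg.erp.late.amp_uv = 0.0
        cfg.burst_model.p_burst = {k: 0.0 for k in cfg.burst_model.p_burst}
    return cfg


def _validate(cfg: SimConfig) -> None:
    if cfg.seed is None:
        raise ValueError("SimConfig.seed must be set (seeded generation only)")
    if cfg.isi_range_s[0] > cfg.isi_range_s[1]:
        raise ValueError("isi_range_s lower bound exceeds upper bound")
    bad = set(cfg.states) - set(STATES)
    if bad:
        raise ValueError(f"invalid state names: {sorted(bad)}")
    for region, rates in cfg.baseline_rate_hz.items():
        for state, r in rates.items():
            if r < 0:
                raise ValueError(f"negative baseline rate for {region}/{state}")
    for region, prof in cfg.evoked_profile.items():
        for table in (prof.excitation_peak_hz, prof.rebound_peak_hz):
            if any(v < 0 for v in table.values()):
                raise ValueError(f"negative evoked peak rate in {region}")
    if any(p > 0 for p in cfg.burst_model.p_burst.values()):
        if cfg.burst_model.intra_isi_ms[1] >= 4.0:
            raise ValueError("intra-burst ISI must stay below 4 ms")
    if cfg.erp.early.amp_uv < 0 or cfg.erp.late.amp_uv < 0:
        raise ValueError("ERP component amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# Trials, speed, latent drive
# ---------------------------------------------------------------------------

_BLOCK_GAP_S = 30.0


def _make_trials(cfg: SimConfig, rng: np.random.Generator):
    onsets, states = [], []
    t = 10.0
    blocks = {}
    for state in cfg.states:
        t0 = t
        for _ in range(cfg.n_trials_per_state):
            onsets.append(t)
            states.append(state)
            t += rng.uniform(*cfg.isi_range_s)
        blocks[state] = (t0 - 2.5, t + 2.5)
        t += _BLOCK_GAP_S
    trials = pd.DataFrame(
        {
            "onset_s": np.array(onsets),
            "state": states,
            "stim_depth": cfg.stim_depth,
            "stim_area": cfg.stim_area,
            "current_ua": cfg.current_ua,
        }
    )
    return trials, blocks


def simulate_running(cfg: SimConfig, trials: pd.DataFrame,
                     rng: np.random.Generator | None = None) -> SpeedSeries:
    """Running-wheel speed consistent with the trial states: exactly
    0 cm/s around quiet / anesthetized / recovery trials, positive around
    running trials."""
    if rng is None:
        if cfg.seed is None:
            raise ValueError("SimConfig.seed must be set")
        rng = np.random.default_rng(cfg.seed + 1)
    fs = 100.0
    t_end = float(trials["onset_s"].iloc[-1]) + 5.0
    t = np.arange(0.0, t_end, 1.0 / fs)
    speed = np.zeros_like(t)
    for onset, state in zip(trials["onset_s"], trials["state"]):
        if state != "running":
            continue
        sel = (t >= onset - 1.5) & (t <= onset + 1.5)
        speed[sel] = np.maximum(0.5, 8.0 + rng.normal(0.0, 1.5, sel.sum()))
    return SpeedSeries(t=t, speed=speed)


def _latent_drive(cfg: SimConfig, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.coupling.enabled:
        s = cfg.coupling.drive_sd
        return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n_trials)
    return np.ones(n_trials)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _poisson_times(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    dur = max(t1 - t0, 0.0)
    lam = rate * dur
    if lam <= 0:
        return np.zeros(0)
    n = rng.poisson(lam)
    return np.sort(rng.uniform(t0, t1, n)) if n else np.zeros(0)


def _delete_window(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    i0, i1 = np.searchsorted(times, [t0, t1])
    if i0 == i1:
        return times
    return np.concatenate([times[:i0], times[i1:]])


def _simulate_unit(
    cfg: SimConfig,
    region: str,
    eras: list,
    trial_onsets: np.ndarray,
    trial_states: list,
    drive: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    prof: EvokedProfile = cfg.evoked_profile[region]
    rates = cfg.baseline_rate_hz[region]
    parts = [_poisson_times(rates[state], t0, t1, rng) for t0, t1, state in eras]
    times = np.concatenate(parts) if parts else np.zeros(0)
    times.sort()

    span0 = prof.excitation_window[0]
    span1 = prof.rebound_window[1]
    bm = cfg.burst_model
    for onset, state, d in zip(trial_onsets, trial_states, drive):
        b = rates[state]
        times = _delete_window(times, onset + span0, onset + span1)
        if b > 0:
            ex_gain = prof.excitation_peak_hz[state] / b
            reb_gain = prof.rebound_peak_hz[state] / b
            if region == CORTEX and cfg.coupling.enabled:
                reb_gain *= d
            new = [
                _poisson_times(b * ex_gain, onset + prof.excitation_window[0],
                               onset + prof.excitation_window[1], rng),
                _poisson_times(b * prof.off_gain[state], onset + prof.off_window[0],
                               onset + prof.off_window[1], rng),
                _poisson_times(b * reb_gain, onset + prof.rebound_window[0],
                               onset + prof.rebound_window[1], rng),
            ]
            add = np.concatenate(new)
            if add.size:
                times = np.sort(np.concatenate([times, add]))
        if region == THALAMUS:
            p = min(bm.p_burst.get(state, 0.0) * d, 1.0)
            if p > 0 and rng.random() < p:
                t_b = onset + float(
                    np.clip(rng.normal(bm.rebound_mean_s, bm.rebound_sd_s), 0.115, 0.290)
                )
                size = int(rng.integers(bm.size_range[0], bm.size_range[1] + 1))
                isis = rng.uniform(*bm.intra_isi_ms, size - 1) * 1e-3
                btimes = t_b + np.concatenate([[0.0], np.cumsum(isis)])
                times = _delete_window(times, t_b - bm.enforced_silence_s,
                                       btimes[-1] + 0.002)
                times = np.sort(np.concatenate([times, btimes]))
    return np.unique(times)


def _simulate_spikes(cfg, rng, trials, blocks, drive) -> SpikeTrainSet:
    # baseline eras: one per state block, boundaries midway through the gaps
    t_end = float(trials["onset_s"].iloc[-1]) + 5.0
    block_list = [(t0, t1, s) for s, (t0, t1) in blocks.items()]
    block_list.sort()
    eras = []
    for i, (t0, t1, s) in enumerate(block_list):
        lo = 0.0 if i == 0 else 0.5 * (block_list[i - 1][1] + t0)
        hi = t_end if i == len(block_list) - 1 else 0.5 * (t1 + block_list[i + 1][0])
        eras.append((lo, hi, s))

    onsets = trials["onset_s"].to_numpy()
    states = list(trials["state"])
    units = []
    uid = 0
    for region, n in cfg.n_units.items():
        n_fs = int(round(n * cfg.fs_fraction)) if region == CORTEX else 0
        for i in range(n):
            is_fs = i < n_fs
            dur = float(rng.uniform(0.20, 0.40)) if is_fs else float(rng.uniform(0.45, 0.80))
            st = _simulate_unit(cfg, region, eras, onsets, states, drive, rng)
            units.append(Unit(uid, st, dur, region))
            uid += 1
    return SpikeTrainSet(units)


# ---------------------------------------------------------------------------
# EEG / LFP
# ---------------------------------------------------------------------------

def _eeg_layout(cfg: SimConfig):
    """30-channel grid over the skull (mm) plus the stim-site position."""
    nx, ny = 6, 5
    xs = np.linspace(-2.5, 2.5, nx)
    ys = np.linspace(-3.0, 3.0, ny)
    pos = np.array([(x, y) for y in ys for x in xs])[: cfg.eeg_n_channels]
    stim = np.array([1.0, 1.5])
    return pos, stim


def _component_waveform(t: np.ndarray, comp: ERPComponent) -> np.ndarray:
    w = np.exp(-0.5 * ((t - comp.latency_s) / comp.width_s) ** 2)
    w -= 0.35 * np.exp(
        -0.5 * ((t - comp.latency_s - 2.2 * comp.width_s) / (1.6 * comp.width_s)) ** 2
    )
    return w


def _component_field(
    t: np.ndarray, comp: ERPComponent, weights: np.ndarray,
    dist_mm: np.ndarray, prop_scale: float,
) -> np.ndarray:
    """Channels x time field of one ERP component: weight map times the
    waveform with a per-channel propagation delay (centered so the mean
    latency stays at the configured latency)."""
    shift = comp.propagation_ms_per_mm * 1e-3 * prop_scale * dist_mm
    shift = shift - shift.mean()
    tt = t[None, :] - shift[:, None]
    w = np.exp(-0.5 * ((tt - comp.latency_s) / comp.width_s) ** 2)
    w -= 0.35 * np.exp(
        -0.5 * ((tt - comp.latency_s - 2.2 * comp.width_s) / (1.6 * comp.width_s)) ** 2
    )
    return weights[:, None] * w


def _weight_maps(cfg: SimConfig, pos: np.ndarray, stim: np.ndarray):
    erp = cfg.erp
    d = np.linalg.norm(pos - stim, axis=1)
    w_early = np.exp(-d / erp.early_decay_mm) - erp.early_neg_frac * np.exp(
        -d / erp.early_neg_decay_mm
    )
    w_early /= np.max(np.abs(w_early))
    c = np.asarray(erp.late_center_mm)
    d2 = np.linalg.norm(pos - c, axis=1)
    w_late = ((pos[:, 0] - c[0]) / 2.0) * np.exp(-0.5 * (d2 / erp.late_sigma_mm) ** 2)
    w_late /= np.max(np.abs(w_late))
    return w_early, w_late


def _pink_noise(shape, n_t, fs, rng, amp, chunk=None):
    """Spectrally shaped (1/f amplitude above 1 Hz) Gaussian noise,
    normalized per trace to the requested standard deviation."""
    white = rng.standard_normal(shape + (n_t,)).astype(np.float32)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_t, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    scale[0] = 0.0
    spec *= scale
    out = np.fft.irfft(spec, n=n_t, axis=-1).astype(np.float32)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out * (amp / sd)


def _artifact(t: np.ndarray, amp: float, chan_scale: np.ndarray) -> np.ndarray:
    """Stimulus artifact transient in 0..+2 ms: sharp exponential decay."""
    win = (t >= 0) & (t < 0.002)
    wave = np.zeros_like(t)
    wave[win] = np.exp(-t[win] / 0.0005)
    return amp * chan_scale[:, None] * wave[None, :]


def _simulate_eeg(cfg, rng, trials, drive) -> EEGEpochs:
    fs = cfg.eeg_fs
    n_t = int(round(4.0 * fs))
    t = np.arange(n_t) / fs - 2.0
    pos, stim = _eeg_layout(cfg)
    n_ch = pos.shape[0]
    n_trials = len(trials)
    w_e, w_l = _weight_maps(cfg, pos, stim)
    dist_e = np.linalg.norm(pos - stim, axis=1)
    dist_l = np.linalg.norm(pos - np.asarray(cfg.erp.late_center_mm), axis=1)
    fields = {}
    for state in set(trials["state"]):
        prop = cfg.erp.state_propagation.get(state, 1.0)
        fields[state] = (
            _component_field(t, cfg.erp.early, w_e, dist_e, prop).astype(np.float32),
            _component_field(t, cfg.erp.late, w_l, dist_l, prop).astype(np.float32),
        )
    states = list(trials["state"])
    scales = np.array([cfg.erp.state_scale[s] for s in states])
    a_early = cfg.erp.early.amp_uv * scales[:, 0]
    a_late = cfg.erp.late.amp_uv * scales[:, 1] * drive
    chan_scale = rng.uniform(0.6, 1.0, n_ch) * rng.choice([-1.0, 1.0], n_ch)
    art = _artifact(t, cfg.noise.artifact_uv, chan_scale).astype(np.float32)

    # fixed spatial mixing of the shared background modes for the session
    k_modes = cfg.noise.eeg_spatial_modes
    mix = rng.standard_normal((n_ch, k_modes))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    shared_amp = cfg.noise.eeg_pink_uv * np.sqrt(cfg.noise.eeg_shared_frac)
    resid_amp = cfg.noise.eeg_pink_uv * np.sqrt(1.0 - cfg.noise.eeg_shared_frac)

    data = np.empty((n_trials, n_ch, n_t), dtype=np.float32)
    chunk = 32
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        block = _pink_noise((hi - lo, n_ch), n_t, fs, rng, resid_amp)
        modes = _pink_noise((hi - lo, k_modes), n_t, fs, rng, shared_amp)
        block += np.einsum("ck,tkx->tcx", mix.astype(np.float32), modes)
        for i in range(lo, hi):
            e_f, l_f = fields[states[i]]
            block[i - lo] += np.float32(a_early[i]) * e_f
            block[i - lo] += np.float32(a_late[i]) * l_f
        block += art[None, :, :]
        data[lo:hi] = block
    return EEGEpochs(
        data=data,
        fs=fs,
        t=t,
        good_channel=np.ones(n_ch, bool),
        pos_mm=pos,
        stim_site_mm=stim,
    )


def _laminar_profiles(depth_um: np.ndarray):
    """Voltage depth profiles for the two evoked components: an early
    profile with a deep (L5, ~600 um) sink and a late profile with a sink
    at the L2/3-L5 border (~400 um); each is a sink/source pair."""
    z = depth_um
    v_early = -np.exp(-0.5 * ((z - 600.0) / 120.0) ** 2) + 0.6 * np.exp(
        -0.5 * ((z - 250.0) / 150.0) ** 2
    )
    v_late = -np.exp(-0.5 * ((z - 400.0) / 100.0) ** 2) + 0.5 * np.exp(
        -0.5 * ((z - 700.0) / 150.0) ** 2
    )
    v_early[z < 0] = 0.0
    v_late[z < 0] = 0.0
    return v_early, v_late


def probe_geometry(spec: ProbeSpec):
    """Channel depths (um below the surface), layer and region labels."""
    idx = np.arange(spec.n_channels)
    depth = (idx + 0.5 - spec.n_surface) * spec.pitch_um
    layer = np.array([""] * spec.n_channels, dtype=object)
    region = np.array(["outside"] * spec.n_channels, dtype=object)
    for name, (top, bot) in spec.layer_boundaries.items():
        sel = (depth >= top) & (depth < bot)
        layer[sel] = name
        region[sel] = spec.region
    region[depth < 0] = "ACSF"
    return depth, layer.astype(str), region.astype(str)


def _simulate_lfp(cfg, rng, trials, drive) -> ProbeLFP:
    fs = cfg.eeg_fs
    n_t = int(round(4.0 * fs))
    t = np.arange(n_t) / fs - 2.0
    spec = cfg.probe_spec
    depth, layer, region = probe_geometry(spec)
    n_ch = spec.n_channels
    n_trials = len(trials)
    v_e, v_l = _laminar_profiles(depth)
    s_e = _component_waveform(t, cfg.erp.early).astype(np.float32)
    s_l = _component_waveform(t, cfg.erp.late).astype(np.float32)
    scales = np.array([cfg.erp.state_scale[s] for s in trials["state"]])
    amp = 100.0  # uV, scale of the evoked laminar LFP
    a_early = amp * scales[:, 0]
    a_late = amp * scales[:, 1] * drive
    if cfg.stim_depth == "superficial":
        a_late = np.zeros_like(a_late)
    chan_scale = rng.uniform(0.6, 1.0, n_ch) * rng.choice([-1.0, 1.0], n_ch)
    art = _artifact(t, cfg.noise.artifact_uv, chan_scale).astype(np.float32)

    data = np.empty((n_trials, n_ch, n_t), dtype=np.float32)
    chunk = 8
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        block = _pink_noise((hi - lo, n_ch), n_t, fs, rng, cfg.noise.lfp_pink_uv)
        common = _pink_noise((hi - lo, 1), n_t, fs, rng, cfg.noise.lfp_common_uv)
        block += common  # common-mode signal removed by surface-median ref
        block += (
            a_early[lo:hi, None, None] * v_e[None, :, None] * s_e[None, None, :]
        ).astype(np.float32)
        block += (
            a_late[lo:hi, None, None] * v_l[None, :, None] * s_l[None, None, :]
        ).astype(np.float32)
        block += art[None, :, :]
        data[lo:hi] = block
    return ProbeLFP(
        data=data,
        fs=fs,
        t=t,
        depth_um=depth,
        layer=layer,
        region=region,
        surface_channels=np.arange(spec.n_surface),
    )


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def simulate_session(cfg: SimConfig) -> SessionData:
    """Generate one deterministic synthetic session from ``cfg``.

    Identical config + seed produce bit-identical output. Trial onsets are
    spaced by uniform draws from ``isi_range_s`` within consecutive
    per-state blocks; the latent per-trial burst drive (when coupling is
    enabled) is shared by the thalamic burst probability, the cortical
    rebound gain and the late-ERP amplitude.
    """
    _validate(cfg)
    rng = np.random.default_rng(cfg.seed)
    trials, blocks = _make_trials(cfg, rng)
    drive = _latent_drive(cfg, len(trials), rng)
    speed = simulate_running(cfg, trials, rng)
    units = _simulate_spikes(cfg, rng, trials, blocks, drive) if cfg.include_spikes else None
    eeg = _simulate_eeg(cfg, rng, trials, drive) if cfg.include_eeg else None
    lfp = {"probeA": _simulate_lfp(cfg, rng, trials, drive)} if cfg.include_lfp else {}
    anesthesia = [list(blocks[s]) for s in blocks if s == "anesthetized"]
    recovery = [list(blocks[s]) for s in blocks if s == "recovery"]
    meta = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "anesthesia_intervals": anesthesia,
        "recovery_intervals": recovery,
        "latent_drive": drive.tolist(),
        "block_spans": {s: list(v) for s, v in blocks.items()},
    }
    return SessionData(trials=trials, eeg=eeg, lfp=lfp, units=units, speed=speed, meta=meta)
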