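"""Perturbational complexity index, state-transition variant (PCI-ST).

PCI-ST quantifies the spatiotemporal complexity of a trial-averaged
evoked response as the summed excess of temporal state transitions in
the response relative to the pre-stimulus baseline, over the principal
components of the response:

1. remove the per-channel baseline mean;
2. SVD of the response-window (channels x time) matrix; component time
   courses are the projections of the full epoch onto the left singular
   vectors;
3. retain components in descending variance order until the cumulative
   response-window variance reaches ``max_var`` (99%);
4. drop components whose SNR — RMS over the response window divided by
   RMS over the baseline window — does not exceed ``min_snr`` (1.6);
5. per surviving component, compute the number of state transitions
   (NST) of the response and baseline segments over a fixed threshold
   grid and take dNST* = max over thresholds of
   (NST_response - k * NST_baseline), with k = 1.2;
6. PCI-ST = sum of dNST* over components (0 when none survive).

NST convention (frozen here): for a scalar segment x of length N, with
distance matrix D_ij = |x_i - x_j| and transition matrix T = (D > eps),
NST(eps) = sum_{i,j} |T_{i+1,j} - T_{i,j}| / N — the average number of
temporal transitions per reference column. The threshold grid is
``n_thresholds`` values spaced linearly from 0 to ``max_thr_p`` times the
largest distance in either segment, which makes the index invariant to a
global rescaling of the input. Deterministic for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCIParams:
    baseline: tuple = (-0.8, -0.002)
    response: tuple = (0.002, 0.8)
    min_snr: float = 1.6
    max_var: float = 99.0
    k: float = 1.2
    n_thresholds: int = 100
    max_thr_p: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline[1] > self.response[0]:
            raise ValueError("baseline and response windows must be disjoint")
        if self.min_snr <= 0:
            raise ValueError("min_snr must be positive")
        if not 0 < self.max_var <= 100:
            raise ValueError("max_var must be in (0, 100]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class PCIResult:
    value: float
    dnst: np.ndarray  # per selected component
    n_components: int
    snr: np.ndarray  # all variance-retained components
    var_fraction: np.ndarray
    params: PCIParams = field(repr=False, default_factory=PCIParams)


def _nst_curve(x: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """NST(eps) for every threshold, via the pairwise-distance band trick.

    A (time-adjacent, column) pair contributes a transition at eps iff
    eps lies in [min(D_i, D_{i+1}), max(D_i, D_{i+1})), so NST(eps) is a
    difference of two sorted-array rank lookups — O(N^2 log N) once for
    the whole grid instead of O(N^2) per threshold.
    """
    x = np.asarray(x, np.float64)
    n = x.size
    d = np.abs(x[:, None] - x[None, :])
    lo = np.minimum(d[:-1], d[1:]).ravel()
    hi = np.maximum(d[:-1], d[1:]).ravel()
    lo.sort()
    hi.sort()
    counts = np.searchsorted(lo, thresholds, side="right") - np.searchsorted(
        hi, thresholds, side="right"
    )
    return counts / n


def compute_pci_st(
    erp: np.ndarray, t: np.ndarray, params: PCIParams | None = None
) -> PCIResult:
    """PCI-ST of a trial-averaged (channels x time) evoked response."""
    params = params or PCIParams()
    erp = np.asarray(erp, np.float64)
    t = np.asarray(t, float)
    if erp.ndim != 2 or erp.shape[0] < 2:
        raise ValueError("ERP must be channels x time with >= 2 channels")
    base_m = (t >= params.baseline[0]) & (t <= params.baseline[1])
    resp_m = (t >= params.response[0]) & (t <= params.response[1])
    if not base_m.any() or not resp_m.any():
        raise ValueError("ERP does not cover the baseline/response windows")

    signal = erp - erp[:, base_m].mean(axis=1, keepdims=True)
    resp = signal[:, resp_m]
    if not np.any(resp):
        return PCIResult(0.0, np.zeros(0), 0, np.zeros(0), np.zeros(0), params)

    u, s, _ = np.linalg.svd(resp, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(var_frac), params.max_var / 100.0) + 1)
    n_keep = min(n_keep, var.size)
    comps = u[:, :n_keep].T @ signal  # component time courses, full epoch

    rms_resp = np.sqrt(np.mean(comps[:, resp_m] ** 2, axis=1))
    rms_base = np.sqrt(np.mean(comps[:, base_m] ** 2, axis=1))
    with np.errstate(divide="ignore"):
        snr = np.where(rms_base > 0, rms_resp / np.maximum(rms_base, 1e-300), np.inf)
    selected = snr > params.min_snr

    dnst = []
    for c in np.nonzero(selected)[0]:
        xb = comps[c, base_m]
        xr = comps[c, resp_m]
        d_max = max(np.ptp(xb), np.ptp(xr))
        if d_max == 0:
            dnst.append(0.0)
            continue
        thr = np.linspace(0.0, params.max_thr_p * d_max, params.n_thresholds)
        delta = _nst_curve(xr, thr) - params.k * _nst_curve(xb, thr)
        dnst.append(float(delta.max()))
    dnst = np.array(dnst)
    return PCIResult(
        value=float(dnst.sum()),
        dnst=dnst,
        n_components=int(selected.sum()),
        snr=snr,
        var_fraction=var_frac[:n_keep],
        params=params,
    )


def trial_matched_states(
    trials, states: list[str], seed: int | None = 0
) -> dict[str, np.ndarray]:
    """Equal-size per-state trial subsets for state comparisons.

    Subset size is the minimum trial count over the requested states;
    larger states are randomly subsampled (seeded). Returns a mapping
    state -> trial indices into the trial table.
    """
    rng = np.random.default_rng(seed)
    idx = {s: np.nonzero((trials["state"] == s).to_numpy())[0] for s in states}
    for s, ix in idx.items():
        if ix.size == 0:
            raise ValueError(f"state {s!r} has no trials")
    n = min(ix.size for ix in idx.values())
    out = {}
    for s, ix in idx.items():
        out[s] = ix if ix.size == n else np.sort(rng.choice(ix, n, replace=False))
    return out
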