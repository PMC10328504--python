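"""Spike analytics: RS/FS split, density, bursts (vs brute force),
latencies, modulation calls, off period, permutation magnitude."""

import numpy as np
import pytest

from ctc_evoked import spiking
from ctc_evoked.session import SpikeTrainSet, Unit
from ctc_evoked.spiking import (
    burst_probability,
    classify_rs_fs,
    detect_bursts,
    first_spike_latency,
    fraction_bursting,
    modulated_units,
    off_period_duration,
    spike_density,
)
from ctc_evoked.synth import CORTEX, THALAMUS


@pytest.mark.parametrize(
    "duration,expected",
    [(0.5, "RS"), (0.41, "RS"), (0.4, "FS"), (0.39, "FS"), (0.2, "FS")],
)
def test_rs_fs_split(duration, expected):
    assert classify_rs_fs(duration) == expected


def test_rs_fs_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_rs_fs(0.0)


# ---------------------------------------------------------------------------
# Burst detection
# ---------------------------------------------------------------------------

def brute_force_bursts(st, max_isi=0.004, min_silence=0.1, t_start=None):
    """Independent oracle: enumerate every maximal run explicitly."""
    st = np.asarray(st, float)
    runs = []
    i = 0
    while i < len(st):
        j = i
        while j + 1 < len(st) and st[j + 1] - st[j] < max_isi:
            j += 1
        if j > i:
            runs.append((i, j))
        i = j + 1
    out = []
    for i, j in runs:
        if i == 0:
            sil = (st[0] - t_start) if t_start is not None else -np.inf
        else:
            sil = st[i] - st[i - 1]
        if sil >= min_silence:
            out.append((st[i], j - i + 1, sil))
    return out


class TestDetectBursts:
    def test_literal_example(self):
        bursts = detect_bursts([0.050, 0.200, 0.202, 0.204])
        assert len(bursts) == 1
        b = bursts[0]
        assert b.start_s == pytest.approx(0.200)
        assert b.n_spikes == 3
        assert b.preceding_silence_s == pytest.approx(0.150)

    def test_insufficient_silence(self):
        assert detect_bursts([0.150, 0.202, 0.204]) == []

    def test_first_spike_needs_observed_silence(self):
        st = [0.050, 0.052]
        assert detect_bursts(st) == []  # silence unobservable
        assert detect_bursts(st, t_start=-0.06) != []
        assert detect_bursts(st, t_start=0.0) == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts([0.2, 0.1])

    def test_matches_brute_force_on_poisson_trains(self, rng):
        # dense-rate trains to exercise runs, silences and adjacency
        for _ in range(200):
            rate = rng.uniform(1, 80)
            n = rng.poisson(rate * 10.0)
            st = np.unique(np.sort(rng.uniform(0, 10.0, n)))
            got = detect_bursts(st, t_start=0.0)
            exp = brute_force_bursts(st, t_start=0.0)
            assert len(got) == len(exp)
            for g, (s, k, sil) in zip(got, exp):
                assert g.start_s == pytest.approx(s)
                assert g.n_spikes == k
                assert g.preceding_silence_s == pytest.approx(sil)


class TestBurstRates:
    def _unit(self, st):
        return Unit(0, np.asarray(st), 0.6, THALAMUS)

    def test_no_bursts_zero(self):
        units = SpikeTrainSet([self._unit([1.0, 2.0, 3.0])])
        assert burst_probability(units, np.array([0.5, 1.5])) == 0.0

    def test_burst_every_trial_one(self):
        onsets = np.array([10.0, 20.0])
        st = np.sort(
            np.concatenate([[1.0], onsets + 0.2, onsets + 0.202, onsets + 0.204])
        )
        units = SpikeTrainSet([Unit(0, st, 0.6, THALAMUS)])
        assert burst_probability(units, onsets) == 1.0
        assert np.allclose(fraction_bursting(units, onsets), 1.0)

    def test_unit_relabeling_invariance(self, rng):
        onsets = 10.0 + np.arange(20) * 4.0
        sts = []
        for _ in range(5):
            st = np.unique(np.sort(rng.uniform(0, 95.0, 300)))
            sts.append(st)
        a = SpikeTrainSet([Unit(i, st, 0.6, THALAMUS) for i, st in enumerate(sts)])
        b = SpikeTrainSet(
            [Unit(99 - i, st, 0.6, THALAMUS) for i, st in enumerate(reversed(sts))]
        )
        assert burst_probability(a, onsets) == burst_probability(b, onsets)
        assert np.allclose(fraction_bursting(a, onsets), fraction_bursting(b, onsets))

    def test_configured_burst_probability_recovered(self, rng):
        # single synthetic thalamic unit, p = 0.5 per trial: empirical
        # region-level fraction must land in the 95% binomial CI
        import ctc_evoked as ce

        cfg = ce.default_config("deep", states=("quiet",), n_trials_per_state=200,
                                seed=5, include_eeg=False)
        cfg.coupling.enabled = False
        cfg.n_units = {THALAMUS: 1}
        cfg.burst_model.p_burst["quiet"] = 0.5
        # suppress rebound Poisson spiking so chance bursts cannot inflate p
        cfg.evoked_profile[THALAMUS].rebound_peak_hz["quiet"] = 0.0
        s = ce.simulate_session(cfg)
        p_hat = burst_probability(
            s.units.select(region=THALAMUS), s.trials["onset_s"].to_numpy()
        )
        half = 1.96 * np.sqrt(0.25 / 200)
        assert 0.5 - half <= p_hat <= 0.5 + half


# ---------------------------------------------------------------------------
# Density, latency, off period
# ---------------------------------------------------------------------------

class TestSpikeDensity:
    def test_silent_unit_zero_and_flagged(self):
        units = SpikeTrainSet([Unit(0, np.array([500.0]), 0.6, CORTEX)])
        onsets = 10.0 + np.arange(10) * 4.0
        sd = spike_density(units, onsets, normalize=None)
        assert np.allclose(sd.unit_rate, 0.0)
        sdz = spike_density(units, onsets)
        assert not sdz.valid_unit[0]

    def test_homogeneous_unit_z_near_zero(self, rng):
        T = 500.0
        st = np.unique(np.sort(rng.uniform(0, T, rng.poisson(20.0 * T))))
        units = SpikeTrainSet([Unit(0, st, 0.6, CORTEX)])
        onsets = 10.0 + np.arange(100) * 4.0
        sd = spike_density(units, onsets)
        base = (sd.t >= -2) & (sd.t < 0)
        # z is standardized per sample; its post-stimulus average obeys a
        # CLT bound (no systematic evoked deviation)
        assert abs(np.mean(sd.population[~base])) < 0.2

    def test_triphasic_profile(self, quiet_session):
        s = quiet_session
        sd = spike_density(
            s.units.select(region=CORTEX, cell_class="RS"),
            s.trials["onset_s"].to_numpy(),
        )
        t = sd.t
        peak_early = sd.population[(t > 0.002) & (t < 0.025)].max()
        off_level = sd.population[(t > 0.05) & (t < 0.12)].mean()
        rebound = sd.population[(t > 0.16) & (t < 0.29)].mean()
        assert peak_early > 10.0
        assert off_level < -0.5  # suppressed below baseline
        assert rebound > 0.5


class TestFirstSpikeLatency:
    def test_exact_latency(self):
        onsets = np.array([10.0, 20.0, 30.0])
        st = np.sort(onsets + 0.005)
        units = SpikeTrainSet([Unit(0, st, 0.6, CORTEX)])
        per_unit, pop = first_spike_latency(units, onsets, (0.002, 0.025))
        assert per_unit[0] == pytest.approx(0.005)
        assert pop == pytest.approx(0.005)

    def test_unresponsive_unit_excluded(self):
        onsets = np.array([10.0])
        units = SpikeTrainSet(
            [
                Unit(0, onsets + 0.005, 0.6, CORTEX),
                Unit(1, np.array([500.0]), 0.6, CORTEX),
            ]
        )
        per_unit, pop = first_spike_latency(units, onsets, (0.002, 0.025))
        assert list(per_unit.index) == [0]
        assert np.isfinite(pop)

    def test_no_responsive_units_flagged(self):
        units = SpikeTrainSet([Unit(0, np.array([500.0]), 0.6, CORTEX)])
        _, pop = first_spike_latency(units, np.array([10.0]), (0.002, 0.025))
        assert np.isnan(pop)

    def test_cortex_leads_early_thalamus_leads_rebound(self, quiet_session):
        s = quiet_session
        onsets = s.trials["onset_s"].to_numpy()
        cortex = s.units.select(region=CORTEX, cell_class="RS")
        thal = s.units.select(region=THALAMUS)
        _, c_early = first_spike_latency(cortex, onsets, (0.002, 0.025))
        _, t_early = first_spike_latency(thal, onsets, (0.002, 0.025))
        _, c_late = first_spike_latency(cortex, onsets, (0.075, 0.300))
        _, t_late = first_spike_latency(thal, onsets, (0.075, 0.300))
        assert c_early < t_early
        assert t_late < c_late


class TestOffPeriod:
    def test_rate_at_baseline_zero(self):
        t = np.arange(-2.0, 2.0, 1e-3)
        rate = np.full_like(t, 10.0)
        assert off_period_duration(t, rate) == 0.0

    def test_constructed_off_window(self):
        t = np.arange(-2.0, 2.0, 1e-3)
        rate = np.full_like(t, 10.0)
        rate[(t >= 0.025) & (t < 0.150)] = 0.0
        assert off_period_duration(t, rate) == pytest.approx(0.125, abs=2e-3)

    def test_zero_baseline_rejected(self):
        t = np.arange(-2.0, 2.0, 1e-3)
        with pytest.raises(ValueError):
            off_period_duration(t, np.zeros_like(t))

    def test_generator_off_period_recovered(self, quiet_session):
        s = quiet_session
        sd = spike_density(
            s.units.select(region=CORTEX, cell_class="RS"),
            s.trials["onset_s"].to_numpy(),
            normalize=None,
        )
        est = off_period_duration(sd.t, sd.population)
        assert abs(est - 0.125) <= 0.015


# ---------------------------------------------------------------------------
# Modulation calls
# ---------------------------------------------------------------------------

class TestModulatedUnits:
    def test_identical_pre_post_none(self, rng):
        onsets = 10.0 + np.arange(30) * 4.0
        # metronome unit: one spike per second everywhere -> matched counts
        st = np.arange(0.5, 140.0, 1.0)
        units = SpikeTrainSet([Unit(0, st, 0.6, CORTEX)])
        res = modulated_units(units, onsets, windows=((0.0, 1.0),))
        assert (res["label"] == "none").all()
        assert (res["p"] == 1.0).all()

    def test_strongly_modulated_unit_detected(self, rng):
        onsets = 10.0 + np.arange(100) * 4.0
        T = onsets[-1] + 5
        base = np.sort(rng.uniform(0, T, rng.poisson(5.0 * T)))
        evoked = np.concatenate(
            [o + np.sort(rng.uniform(0.002, 0.025, rng.poisson(3.0))) for o in onsets]
        )
        st = np.unique(np.sort(np.concatenate([base, evoked])))
        null = np.unique(np.sort(rng.uniform(0, T, rng.poisson(5.0 * T))))
        units = SpikeTrainSet(
            [Unit(0, st, 0.6, CORTEX), Unit(1, null, 0.6, CORTEX)]
        )
        res = modulated_units(units, onsets)
        r0 = res[(res["unit_id"] == 0) & (res["window"] == "2-25ms")]
        assert r0["label"].iloc[0] == "increased"
        assert res["q"].ge(res["p"]).all()

    def test_fs_units_excluded_by_default(self):
        onsets = np.array([10.0, 14.0, 18.0])
        units = SpikeTrainSet([Unit(0, np.array([1.0, 2.0]), 0.3, CORTEX)])
        res = modulated_units(units, onsets)
        assert res.empty


# ---------------------------------------------------------------------------
# Permutation evoked magnitude
# ---------------------------------------------------------------------------

class TestEvokedMagnitude:
    def test_seed_determinism(self, rng):
        T = 200.0
        onsets = 10.0 + np.arange(40) * 4.0
        st = np.unique(np.sort(rng.uniform(0, T, 1500)))
        sig = spiking.binned_rate(Unit(0, st, 0.6, CORTEX), T)
        z1 = spiking.evoked_magnitude_permutation(sig, 200.0, onsets, n_shuffles=200,
                                                  seed=3)
        z2 = spiking.evoked_magnitude_permutation(sig, 200.0, onsets, n_shuffles=200,
                                                  seed=3)
        assert z1 == z2

    def test_evoked_bump_detected(self, rng):
        T = 200.0
        onsets = 10.0 + np.arange(40) * 4.0
        base = rng.uniform(0, T, rng.poisson(5.0 * T))
        evoked = np.concatenate(
            [o + rng.uniform(0, 0.1, rng.poisson(2.5)) for o in onsets]
        )
        st = np.unique(np.sort(np.concatenate([base, evoked])))
        sig = spiking.binned_rate(Unit(0, st, 0.6, CORTEX), T)
        z = spiking.evoked_magnitude_permutation(sig, 200.0, onsets, n_shuffles=300,
                                                 seed=0)
        assert z > 3.0

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            spiking.evoked_magnitude_permutation(
                np.zeros(100), 200.0, np.array([1.0]), n_shuffles=10, seed=0
            )
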