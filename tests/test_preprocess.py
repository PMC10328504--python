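"""Artifact masking, filtering, referencing and state classification."""

import numpy as np
import pytest
from scipy import signal as sps

from ctc_evoked.preprocess import (
    classify_trial_state,
    epoch_array,
    mask_artifact,
    preprocess_eeg,
    preprocess_lfp,
    remove_artifact_spikes,
)
from ctc_evoked.session import EEGEpochs, ProbeLFP, SpeedSeries

FS = 2500.0


class TestMaskArtifact:
    def test_five_sample_reversal(self):
        # 2 ms at 2500 Hz = 5 samples: (1,2,3,4,5) before onset -> (5,4,3,2,1) after
        trace = np.zeros(20)
        trace[5:10] = [1, 2, 3, 4, 5]
        out = mask_artifact(trace, 10, FS)
        assert np.array_equal(out[10:15], [5, 4, 3, 2, 1])
        assert np.array_equal(out[:10], trace[:10])
        assert np.array_equal(out[15:], trace[15:])

    def test_constant_trace_unchanged(self):
        trace = np.full(100, 3.7)
        assert np.array_equal(mask_artifact(trace, 50, FS), trace)

    def test_matches_slice_reverse_oracle(self, rng):
        trace = rng.standard_normal(10_000)
        onset = 5000
        out = mask_artifact(trace, onset, FS)
        n = int(round(2e-3 * FS))
        oracle = trace.copy()
        oracle[onset : onset + n] = trace[onset - n : onset][::-1]
        assert np.array_equal(out, oracle)

    def test_idempotent(self, rng):
        trace = rng.standard_normal(1000)
        once = mask_artifact(trace, 500, FS)
        assert np.array_equal(mask_artifact(once, 500, FS), once)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mask_artifact(np.zeros(10), 2, FS)

    def test_artifact_spike_removal(self, quiet_session):
        onsets = quiet_session.trials["onset_s"].to_numpy()
        cleaned = remove_artifact_spikes(quiet_session.units, onsets)
        for u in cleaned:
            rel = u.spike_times[:, None] - onsets[None, :]
            assert not np.any((rel > 0) & (rel <= 0.002))


class TestEpoching:
    def test_sample_preservation(self, rng):
        cont = rng.standard_normal((3, 50_000))
        onsets = np.array([8.0, 12.0])
        epochs, t = epoch_array(cont, FS, onsets)
        i = int(round((8.0 - 2.0) * FS))
        assert np.array_equal(epochs[0, :, 0], cont[:, i])
        assert t[0] == pytest.approx(-2.0)
        assert epochs.shape == (2, 3, int(4 * FS))

    def test_window_out_of_span_rejected(self):
        with pytest.raises(ValueError):
            epoch_array(np.zeros((1, 1000)), FS, np.array([0.1]))


def _eeg_from_array(data, fs=FS):
    n_ch = data.shape[1]
    t = np.arange(data.shape[2]) / fs - 2.0
    return EEGEpochs(
        data=data.astype(np.float32),
        fs=fs,
        t=t,
        good_channel=np.ones(n_ch, bool),
        pos_mm=np.zeros((n_ch, 2)),
        stim_site_mm=np.zeros(2),
    )


class TestPreprocessEEG:
    def test_antisymmetric_channels_unchanged_by_referencing(self):
        # channels (+x, -x): common average is 0, so referencing is a no-op
        n_t = int(4 * FS)
        x = np.sin(2 * np.pi * 7 * (np.arange(n_t) / FS))
        data = np.stack([x, -x])[None, :, :]
        out = preprocess_eeg(_eeg_from_array(data), mask=False)
        ref = data[0] - data[0].mean(axis=0)
        assert np.allclose(ref, data[0])
        # band-pass keeps a 7 Hz tone essentially intact
        mid = slice(2000, -2000)
        assert np.corrcoef(out.data[0, 0, mid], x[mid])[0, 1] > 0.99

    def test_identical_channels_referenced_to_zero(self, rng):
        sig = rng.standard_normal(int(4 * FS))
        data = np.tile(sig, (1, 4, 1))
        out = preprocess_eeg(_eeg_from_array(data), mask=False)
        assert np.max(np.abs(out.data)) < 1e-6

    def test_car_mean_zero_invariant(self, quiet_session):
        out = preprocess_eeg(quiet_session.eeg)
        # filtering is linear so CAR's zero-mean survives it
        m = out.data[:5, out.good_channel, :].mean(axis=1)
        scale = np.abs(out.data[:5]).max()
        assert np.max(np.abs(m)) < 1e-6 * scale

    def test_stopband_attenuation(self, rng):
        # white noise: power above 150 Hz must drop >= 20 dB vs passband
        data = rng.standard_normal((2, 3, int(4 * FS)))
        out = preprocess_eeg(_eeg_from_array(data), mask=False)
        f, pxx_in = sps.welch(data[0, 0], fs=FS, nperseg=2048)
        _, pxx_out = sps.welch(out.data[0, 0].astype(float), fs=FS, nperseg=2048)
        gain = pxx_out / pxx_in
        passband = gain[(f > 5) & (f < 50)].mean()
        stopband = gain[f > 150].mean()
        assert 10 * np.log10(passband / stopband) >= 20

    def test_all_channels_bad_rejected(self, rng):
        data = rng.standard_normal((1, 3, int(4 * FS)))
        with pytest.raises(ValueError):
            preprocess_eeg(_eeg_from_array(data), good_channel=np.zeros(3, bool))


def _lfp_from_array(data, n_surface=2, fs=FS):
    n_ch = data.shape[1]
    t = np.arange(data.shape[2]) / fs - 2.0
    return ProbeLFP(
        data=data.astype(np.float32),
        fs=fs,
        t=t,
        depth_um=(np.arange(n_ch) - n_surface) * 20.0,
        layer=np.array([""] * n_ch),
        region=np.array(["MO"] * n_ch),
        surface_channels=np.arange(n_surface),
    )


class TestPreprocessLFP:
    def test_output_rate_is_half_input(self, rng):
        data = rng.standard_normal((1, 4, int(4 * FS)))
        out = preprocess_lfp(_lfp_from_array(data), mask=False)
        assert out.fs == 1250.0
        assert out.data.shape[-1] == data.shape[-1] // 2

    def test_common_mode_removed_by_median_reference(self, rng):
        n_t = int(4 * FS)
        tone = 40.0 * np.sin(2 * np.pi * 11 * np.arange(n_t) / FS)
        data = np.tile(tone, (1, 6, 1)) + rng.standard_normal((1, 6, n_t)) * 0.01
        out = preprocess_lfp(_lfp_from_array(data), mask=False)
        assert np.abs(out.data).max() < 0.01 * 40.0

    def test_anti_alias_attenuates_above_output_nyquist(self):
        # an 800 Hz tone (above the 625 Hz output Nyquist) must be
        # suppressed >= 20 dB by the anti-alias filter before decimation
        n_t = int(4 * FS)
        tone = np.sin(2 * np.pi * 800 * np.arange(n_t) / FS)
        tone *= sps.windows.tukey(n_t, 0.1)  # taper: no epoch-edge step
        data = np.tile(tone, (1, 4, 1))
        lfp = _lfp_from_array(data, n_surface=0)
        with pytest.warns(UserWarning):
            out = preprocess_lfp(lfp, mask=False)
        att = np.abs(out.data[0, 3, 1000:-1000]).max()
        assert 20 * np.log10(1.0 / att) >= 20


class TestClassifyTrialState:
    @staticmethod
    def _trials(onsets):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": onsets,
                "state": "quiet",
                "stim_depth": "deep",
                "stim_area": "MOs",
                "current_ua": 50.0,
            }
        )

    def test_rules_and_precedence(self):
        onsets = np.array([10.0, 20.0, 30.0, 40.0])
        t = np.arange(0, 50, 0.01)
        speed = np.zeros_like(t)
        speed[(t > 19) & (t < 21)] = 4.0  # running around trial 2
        out = classify_trial_state(
            self._trials(onsets),
            SpeedSeries(t, speed),
            anesthesia_intervals=[(28.0, 32.0)],
            recovery_intervals=[(38.0, 42.0)],
        )
        assert list(out["state"]) == ["quiet", "running", "anesthetized", "recovery"]

    def test_anesthesia_overrides_speed(self):
        onsets = np.array([10.0])
        t = np.arange(0, 20, 0.01)
        out = classify_trial_state(
            self._trials(onsets),
            SpeedSeries(t, np.zeros_like(t)),
            anesthesia_intervals=[(5.0, 15.0)],
        )
        assert out["state"].iloc[0] == "anesthetized"

    def test_missing_speed_flagged(self):
        out = classify_trial_state(self._trials(np.array([10.0])), None)
        assert out["state"].iloc[0] == "unclassifiable"

    def test_generator_states_recovered(self, three_state_session):
        s = three_state_session
        out = classify_trial_state(
            s.trials.drop(columns=["state"]).assign(state="quiet"),
            s.speed,
            anesthesia_intervals=s.meta["anesthesia_intervals"],
        )
        assert list(out["state"]) == list(s.trials["state"])
        counts = out["state"].value_counts()
        assert counts.sum() == len(s.trials)
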