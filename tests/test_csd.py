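"""Laminar CSD: channel rejection, smoothing, the second-derivative
stencil against analytic oracles, layer binning, population mask."""

import numpy as np
import pytest

from ctc_evoked.csd import (
    LayerMap,
    compute_csd,
    population_csd_mask,
    reject_channels_chebyshev,
    smooth_lfp,
    to_layer_space,
)


class TestChannelRejection:
    def test_identical_channels_none_rejected(self):
        data = np.tile(np.sin(np.linspace(0, 5, 100)), (10, 1))
        _, rejected = reject_channels_chebyshev(data)
        assert rejected == []

    def test_single_spiking_channel_interpolated(self, rng):
        # one huge instantaneous outlier among 50 smooth channels
        data = np.tile(np.sin(np.linspace(0, 5, 200)), (51, 1))
        data += rng.normal(0, 0.01, data.shape)
        data[17, 100] += 1000.0
        cleaned, rejected = reject_channels_chebyshev(data)
        assert rejected == [17]
        # replaced by depth interpolation between neighbors 16 and 18
        assert abs(cleaned[17, 100] - 0.5 * (data[16, 100] + data[18, 100])) < 1e-9

    def test_infinite_limit_is_identity(self, rng):
        data = rng.standard_normal((8, 50))
        cleaned, rejected = reject_channels_chebyshev(data, z_limit=np.inf)
        assert rejected == [] and np.array_equal(cleaned, data)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            reject_channels_chebyshev(np.zeros((2, 10)))


class TestSmoothing:
    def test_constant_unchanged(self):
        data = np.full((30, 100), 7.5)
        assert np.allclose(smooth_lfp(data, 1250.0, space_windows=(5, 2)), 7.5)

    def test_time_impulse_becomes_boxcar(self):
        fs = 1250.0
        width = int(round(8e-3 * fs))  # 10 samples
        data = np.zeros((1, 201))
        data[0, 100] = 1.0
        out = smooth_lfp(data, fs, space_windows=())
        nz = np.nonzero(out[0])[0]
        assert nz.size == width
        assert np.allclose(out[0, nz], 1.0 / width)

    def test_noise_variance_reduced(self, rng):
        data = rng.standard_normal((40, 500))
        out = smooth_lfp(data, 1250.0, space_windows=(26, 4))
        assert out.var() < 0.2 * data.var()

    def test_window_larger_than_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_lfp(rng.standard_normal((5, 100)), 1250.0, space_windows=(26, 4))


class TestComputeCSD:
    sigma = 0.3
    h = 20e-6

    def test_linear_profile_zero(self):
        z = np.arange(40) * self.h
        v = (2.5 * z + 1.0)[:, None] * np.ones((1, 4))
        m = compute_csd(v, self.h, sigma=self.sigma)
        # zero up to cancellation roundoff: eps * |V| / h^2
        roundoff = np.finfo(float).eps * np.abs(v).max() / self.h**2
        assert np.allclose(m.values[1:-1], 0.0, atol=10 * roundoff)

    def test_quadratic_profile_exact(self):
        # V = a z^2 -> interior CSD = -2 a sigma, exact for the 3-point stencil
        z = np.arange(40) * self.h
        a = 4.2
        v = (a * z**2)[:, None] * np.ones((1, 3))
        m = compute_csd(v, self.h, sigma=self.sigma)
        expected = -2.0 * a * self.sigma
        assert np.max(np.abs(m.values[1:-1] / expected - 1.0)) < 1e-9

    def test_sinusoid_analytic_oracle(self):
        # V = sin(kz) with kh < 0.1 -> CSD within 1% of sigma k^2 V
        z = np.arange(200) * self.h
        k = 0.08 / self.h
        v = np.sin(k * z)[:, None] * np.ones((1, 2))
        m = compute_csd(v, self.h, sigma=self.sigma)
        expected = self.sigma * k**2 * v
        interior = slice(1, -1)
        err = np.abs(m.values[interior] - expected[interior]) / np.abs(expected).max()
        assert err.max() < 0.01

    def test_linearity(self, rng):
        v1 = rng.standard_normal((30, 8))
        v2 = rng.standard_normal((30, 8))
        a, b = 2.0, -0.7
        m = compute_csd(a * v1 + b * v2, self.h)
        m1 = compute_csd(v1, self.h)
        m2 = compute_csd(v2, self.h)
        assert np.allclose(m.values, a * m1.values + b * m2.values)

    def test_sink_is_negative(self):
        # a local positive-voltage bump (source-like) -> positive CSD at
        # its center; a negative bump (sink) -> negative
        z = np.arange(60) * self.h
        bump = np.exp(-0.5 * ((z - z[30]) / (5 * self.h)) ** 2)
        m = compute_csd(-bump[:, None], self.h)
        assert m.values[30, 0] < 0

    def test_charge_balance_of_stencil(self):
        # compact dipole profile: spatial integral of CSD ~ 0
        z = np.arange(120) * self.h
        prof = np.exp(-0.5 * ((z - z[50]) / (6 * self.h)) ** 2) - np.exp(
            -0.5 * ((z - z[70]) / (6 * self.h)) ** 2
        )
        m = compute_csd(prof[:, None], self.h)
        total = m.values[:, 0].sum()
        assert abs(total) < 1e-3 * np.abs(m.values).max() * len(z)

    def test_non_uniform_spacing_rejected(self, rng):
        v = rng.standard_normal((10, 4))
        depth = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 10.0])
        with pytest.raises(ValueError):
            compute_csd(v, 1.0, depth=depth)


class TestLayerSpace:
    def test_linear_profile_preserved(self):
        layers = LayerMap({"L5": (0.0, 100.0)})
        depth = np.linspace(5.0, 95.0, 19)
        vals = (2.0 * depth + 1.0)[:, None]
        from ctc_evoked.csd import CSDMap

        m = CSDMap(values=vals, depth=depth, t=np.array([0.0]))
        out = to_layer_space(m, layers)
        centers = 0.0 + (np.arange(10) + 0.5) * 10.0
        assert out.values.shape == (10, 1)
        assert np.allclose(out.values[:, 0], 2.0 * centers + 1.0, atol=1e-9)

    def test_unequal_layers_get_equal_bins(self):
        from ctc_evoked.csd import CSDMap

        layers = LayerMap({"L2/3": (0.0, 300.0), "L5": (300.0, 350.0)})
        depth = np.concatenate([np.linspace(0, 299, 30), np.linspace(300, 349, 5)])
        m = CSDMap(values=np.ones((35, 2)), depth=depth, t=np.arange(2))
        out = to_layer_space(m, layers)
        assert out.values.shape == (20, 2)
        assert out.layers == ["L2/3"] * 10 + ["L5"] * 10

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            LayerMap({"a": (0.0, 100.0), "b": (50.0, 150.0)})


class TestPopulationMask:
    def test_all_zero_maps_empty_mask(self):
        maps = np.zeros((9, 10, 12))
        mask, _ = population_csd_mask(maps)
        assert not mask.any()

    def test_consistent_sink_detected_isolated_removed(self, rng):
        maps = rng.normal(0, 0.05, (9, 12, 20))
        maps[:, 4:7, 8:13] += -2.0  # consistent sink block
        maps[:, 0, 0] += -2.0  # isolated corner bin
        mask, p = population_csd_mask(maps)
        assert mask[5, 10]
        assert mask[4:7, 8:13].mean() > 0.8
        assert not mask[0, 0]  # isolated significant bin cleared
        # oracle: per-bin signed-rank on the block is significant
        from scipy import stats

        assert stats.wilcoxon(maps[:, 5, 10])[1] < 0.05

    def test_underpowered_warns(self):
        with pytest.warns(UserWarning):
            population_csd_mask(np.random.default_rng(0).normal(size=(3, 4, 4)))
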