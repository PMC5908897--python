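import numpy as np
import pytest

from oracles import (
    cumulative_oracle,
    peak_oracle,
    pearson_lag_oracle,
    running_percentile_oracle,
)
from voxcorr import (
    CorrelationParams,
    Hyperstack,
    correlation_map,
    cumulative_xcorr,
    normalize_trace,
    peak_xcorr,
    pearson_at_lag,
    responding_volume,
    shift_null,
    xy_boxmean,
)
from voxcorr.errors import LagError, MaskError, ParameterError, ShapeError


def stack_from(data, period=0.5):
    return Hyperstack(np.asarray(data, dtype=np.float32), stack_period_s=period)


class TestNormalizeTrace:
    def test_none_is_identity(self, rng):
        v = rng.normal(size=40)
        out = normalize_trace(v, method="none")
        assert np.array_equal(out.values, v)
        assert not out.degenerate

    def test_constant_trace_flagged_all_zero(self):
        out = normalize_trace(np.full(30, 7.0), method="dff_running_percentile",
                              window=5)
        assert out.degenerate
        assert not out.values.any()

    def test_zscore_constant_flagged(self):
        out = normalize_trace(np.full(30, 7.0), method="zscore")
        assert out.degenerate and not out.values.any()

    def test_running_percentile_matches_bruteforce(self, rng):
        v = np.linspace(0, 10, 50) + rng.normal(0, 0.5, 50)
        out = normalize_trace(v, method="dff_running_percentile", window=5)
        f0 = running_percentile_oracle(v, 5, 10.0)
        eps = 1e-6 * v.mean()
        want = (v - f0) / np.maximum(f0, eps)
        assert np.allclose(out.values, want, atol=1e-12)

    def test_zscore_values(self, rng):
        v = rng.normal(3, 2, size=100)
        out = normalize_trace(v, method="zscore")
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0, abs=1e-12)


class TestPearsonAtLag:
    def test_identical_series_r_one(self, rng):
        s = rng.integers(0, 2, size=30).astype(float)
        assert pearson_at_lag(s, s, 0) == pytest.approx(1.0)

    def test_negated_series_r_minus_one(self, rng):
        s = rng.normal(size=30)
        assert pearson_at_lag(-s + 5.0, s, 0) == pytest.approx(-1.0)

    def test_hand_computed_zero_covariance(self):
        # overlap pairs: s=(0,1,0) vs f=(2,3,4); covariance terms cancel
        f = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([0.0, 1.0, 0.0, 1.0])
        # minimum-overlap rule waived by direct oracle comparison at small T
        from voxcorr.xcorr import _pearson_block
        r = _pearson_block(s[:3], f[1:, None])[0]
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_overlap_gives_zero(self):
        f = np.full(20, 3.0)
        s = np.arange(20.0)
        assert pearson_at_lag(f, s, 0) == 0.0

    def test_minimum_overlap_enforced(self, rng):
        f = rng.normal(size=12)
        s = rng.normal(size=12)
        assert pearson_at_lag(f, s, 4) != 0  # overlap 8 allowed
        with pytest.raises(LagError):
            pearson_at_lag(f, s, 5)  # overlap 7 < 8
        with pytest.raises(LagError):
            pearson_at_lag(f, s, -1)

    def test_matches_oracle(self, rng):
        for _ in range(50):
            T = int(rng.integers(16, 60))
            f = rng.normal(size=T)
            s = (rng.random(T) < 0.2).astype(float)
            k = int(rng.integers(0, T - 8))
            assert pearson_at_lag(f, s, k) == pytest.approx(
                pearson_lag_oracle(f, s, k), abs=1e-12
            )


class TestCumulativeAndPeak:
    def test_k0_equals_single_lag(self, rng):
        f, s = rng.normal(size=30), rng.normal(size=30)
        assert cumulative_xcorr(f, s, 0) == pytest.approx(pearson_at_lag(f, s, 0))

    def test_delayed_copy_peaks_at_delay(self, rng):
        s = np.zeros(60)
        s[rng.choice(60, 8, replace=False)] = 1.0
        f = np.roll(s, 3)
        f[:3] = 0.0
        r, k = peak_xcorr(f, s, 5)
        assert k == 3
        assert r == pytest.approx(1.0, abs=1e-9)
        # cumulative includes that unit term
        assert cumulative_xcorr(f, s, 5) == pytest.approx(
            cumulative_oracle(f, s, 5), abs=1e-12
        )

    def test_random_triples_match_oracles(self, rng):
        for _ in range(60):
            T = int(rng.integers(25, 80))
            K = int(rng.integers(0, min(10, T - 9)))
            f = rng.normal(size=T)
            s = (rng.random(T) < 0.15).astype(float)
            assert cumulative_xcorr(f, s, K) == pytest.approx(
                cumulative_oracle(f, s, K), abs=1e-12
            )
            r, k = peak_xcorr(f, s, K)
            ro, ko = peak_oracle(f, s, K)
            assert r == pytest.approx(ro, abs=1e-12)
            assert k == ko

    def test_all_degenerate_peak_is_zero_at_lag_zero(self):
        f = np.full(30, 2.0)
        s = np.arange(30.0)
        assert peak_xcorr(f, s, 4) == (0.0, 0)

    def test_bounds(self, rng):
        f, s = rng.normal(size=40), rng.normal(size=40)
        K = 6
        assert abs(peak_xcorr(f, s, K)[0]) <= 1.0
        assert abs(cumulative_xcorr(f, s, K)) <= K + 1


class TestXyBoxmean:
    def test_m0_identity(self, small_stack):
        assert xy_boxmean(small_stack, 0) is small_stack

    def test_interior_mean_of_nine(self):
        data = np.zeros((1, 1, 1, 3, 3), dtype=np.float32)
        data[0, 0, 0] = np.arange(1, 10).reshape(3, 3)
        out = xy_boxmean(stack_from(data), 1)
        assert out.data[0, 0, 0, 1, 1] == pytest.approx(5.0)

    def test_corner_shrinks_to_inbounds(self):
        data = np.zeros((1, 1, 1, 3, 3), dtype=np.float32)
        data[0, 0, 0] = np.arange(1, 10).reshape(3, 3)
        out = xy_boxmean(stack_from(data), 1)
        assert out.data[0, 0, 0, 0, 0] == pytest.approx((1 + 2 + 4 + 5) / 4)

    def test_z_t_untouched(self, rng):
        data = rng.normal(size=(1, 4, 3, 6, 6)).astype(np.float32)
        out = xy_boxmean(stack_from(data), 1)
        # constant-in-plane stack: each plane mean equals the plane value
        const = np.ones_like(data) * np.arange(4)[None, :, None, None, None]
        outc = xy_boxmean(stack_from(const), 1)
        assert np.allclose(outc.data, const, atol=1e-6)
        assert out.data.shape == data.shape


class TestCorrelationMap:
    def test_stimulus_replica_gives_unit_peak(self, rng):
        T = 40
        s = (rng.random(T) < 0.3).astype(float)
        data = np.broadcast_to(
            s[None, :, None, None, None], (1, T, 2, 4, 4)
        ).astype(np.float32)
        hs = stack_from(data.copy())
        params = CorrelationParams(lag_window_frames=3, mode="peak",
                                   normalization="none")
        cmap = correlation_map(hs, s, 0, params)
        assert np.allclose(cmap.values, 1.0)
        assert np.all(cmap.lag_at_peak == 0)

    def test_zero_stimulus_flags_global_degenerate(self, rng):
        hs = stack_from(rng.normal(size=(1, 40, 2, 4, 4)))
        params = CorrelationParams(lag_window_frames=3, normalization="none")
        cmap = correlation_map(hs, np.zeros(40), 0, params)
        assert cmap.degenerate
        assert not cmap.values.any()

    def test_length_mismatch_rejected(self, rng):
        hs = stack_from(rng.normal(size=(1, 40, 2, 4, 4)))
        with pytest.raises(ShapeError):
            correlation_map(hs, np.zeros(39), 0, CorrelationParams())

    def test_affine_invariance(self, rng):
        T = 50
        s = (rng.random(T) < 0.2).astype(float)
        base = rng.normal(100, 10, size=(1, T, 2, 5, 5)).astype(np.float32)
        p = CorrelationParams(lag_window_frames=4, normalization="none")
        a = correlation_map(stack_from(base), s, 0, p).values
        b = correlation_map(stack_from(3.0 * base + 50.0), s, 0, p).values
        assert np.allclose(a, b, atol=1e-6)

    def test_blob_recovery_map_maximum_inside_blob(self):
        import voxcorr as vc

        cfg = vc.default_config(
            seed=11, shape=(1, 120, 4, 12, 12), spont_rate_per_voxel_hour=0.0,
            responder_fraction=0.02, delay_jitter_s=1.0,
        )
        proto = vc.make_sparse_protocol(rate_hz=0.2, events_per_epoch=4,
                                        n_epochs=2, gap_s=10)
        hs, truth = vc.simulate_stack(cfg, proto)
        s = vc.stim_vector_from_protocol(proto, 120, cfg.stack_period_s)
        cmap = correlation_map(hs, s, 0, CorrelationParams(lag_window_frames=6))
        peak_voxel = np.unravel_index(np.argmax(cmap.values), cmap.values.shape)
        assert truth.responder_mask[peak_voxel]

    def test_mask_restricts_voxels(self, rng):
        T = 40
        s = (rng.random(T) < 0.3).astype(float)
        hs = stack_from(rng.normal(size=(1, T, 2, 4, 4)))
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, :2, :2] = True
        p = CorrelationParams(lag_window_frames=3, normalization="none")
        cmap = correlation_map(hs, s, 0, p, mask=mask)
        assert not cmap.values[~mask].any()


class TestShiftNull:
    def test_deterministic_under_seed(self, rng):
        T = 80
        s = (rng.random(T) < 0.2).astype(float)
        hs = stack_from(rng.normal(size=(1, T, 2, 6, 6)))
        p = CorrelationParams(lag_window_frames=5, normalization="none",
                              n_null=20, seed=42)
        a = shift_null(hs, s, 0, p)
        b = shift_null(hs, s, 0, p)
        assert a.threshold == b.threshold
        assert np.array_equal(a.null_values, b.null_values)

    def test_single_shift_defined(self, rng):
        T = 80
        s = (rng.random(T) < 0.2).astype(float)
        hs = stack_from(rng.normal(size=(1, T, 1, 4, 4)))
        p = CorrelationParams(lag_window_frames=5, normalization="none",
                              n_null=1, seed=0)
        res = shift_null(hs, s, 0, p)
        assert res.null_values.size == 16
        assert np.isfinite(res.threshold)

    def test_insufficient_shift_space_rejected(self, rng):
        T = 24
        s = (rng.random(T) < 0.3).astype(float)
        hs = stack_from(rng.normal(size=(1, T, 1, 4, 4)))
        p = CorrelationParams(lag_window_frames=11, normalization="none", n_null=50)
        with pytest.raises(ParameterError):
            shift_null(hs, s, 0, p)


class TestRespondingVolume:
    def make_map(self, values, mask=None):
        from voxcorr.xcorr import CorrelationMap
        return CorrelationMap(np.asarray(values, dtype=float),
                              CorrelationParams(), mask=mask)

    def test_nothing_above_threshold(self):
        cmap = self.make_map(np.zeros((2, 3, 3)))
        frac, voxels = responding_volume(cmap, 0.5)
        assert frac == 0.0 and voxels == []

    def test_fraction_arithmetic(self, rng):
        values = np.zeros((8, 32, 32))
        idx = rng.choice(values.size, size=41, replace=False)
        values.ravel()[idx] = 1.0
        frac, voxels = responding_volume(self.make_map(values), 0.5)
        assert frac == pytest.approx(41 / 8192)
        assert len(voxels) == 41

    def test_sorted_descending_and_mask_respected(self):
        values = np.array([[[0.9, 0.2], [0.7, 0.95]]])
        mask = np.array([[[True, True], [True, False]]])
        frac, voxels = responding_volume(self.make_map(values, mask), 0.5)
        assert frac == pytest.approx(2 / 3)
        assert [v for _, v in voxels] == [0.9, 0.7]

    def test_empty_mask_rejected(self):
        cmap = self.make_map(np.zeros((2, 2, 2)), mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(MaskError):
            responding_volume(cmap, 0.0)
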