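import numpy as np
import pytest

from swcapacity import (
    OrderSelectionConfig,
    analyze_session,
    plan_windows,
    session_to_frame,
    single_window_measures,
    sliding_capacity,
    sliding_swc,
    time_average_matrix,
    trial_measures_batch,
    window_length_from_seconds,
)
from swcapacity.simulate import ChannelSimSpec, correlated_pair, simulate_pair
from swcapacity.sliding import RoiTimeSeriesSet


class TestWindowPlan:
    @pytest.mark.parametrize(
        "T, n, step, expected_starts",
        [
            (10, 10, 1, [0]),
            (12, 10, 1, [0, 1, 2]),
            (600, 50, 1, list(range(551))),
        ],
    )
    def test_maximal_contained_windows(self, T, n, step, expected_starts):
        plan = plan_windows(T, n, step)
        np.testing.assert_array_equal(plan.window_starts, expected_starts)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            plan_windows(10, 11, 1)

    def test_seconds_conversion(self):
        assert window_length_from_seconds(50.0, 0.5) == 100
        assert window_length_from_seconds(45.0, 1.0) == 45
        with pytest.warns(UserWarning):
            assert window_length_from_seconds(50.0, 0.7) == 71


class TestSlidingSwc:
    def test_identical_series_all_one(self, rng):
        x = rng.standard_normal(100)
        plan = plan_windows(100, 20, 5)
        np.testing.assert_allclose(sliding_swc(x, x, plan), 1.0)
        np.testing.assert_allclose(sliding_swc(x, -x, plan), -1.0)

    def test_independent_noise_centered_near_zero(self, rng):
        x = rng.standard_normal(550)
        y = rng.standard_normal(550)
        vals = sliding_swc(x, y, plan_windows(550, 50, 1))
        assert abs(np.mean(vals)) < 0.1

    def test_constant_segment_is_missing(self, rng):
        x = np.ones(30)
        y = rng.standard_normal(30)
        vals = sliding_swc(x, y, plan_windows(30, 10, 10))
        assert np.all(np.isnan(vals))


class TestSlidingCapacity:
    def test_pcorr_equals_correlation_at_order_one(self):
        x, y = correlated_pair(0.55, n=60, seed=9)
        plan = plan_windows(60, 60, 1)
        series = sliding_capacity(x, y, plan, OrderSelectionConfig(k_max=1))
        assert series.pcorr[0] == pytest.approx(0.55, abs=1e-9)
        assert series.swc[0] == pytest.approx(0.55, abs=1e-9)

    def test_noiseless_channel_pcorr_tends_to_one(self):
        ts = simulate_pair(ChannelSimSpec(taps=(0.7, 0.3), noise_sd=1e-6, length=300, seed=4))
        plan = plan_windows(300, 100, 50)
        series = sliding_capacity(
            ts.values[0], ts.values[1], plan, OrderSelectionConfig(criterion="BIC", k_max=4)
        )
        assert np.nanmin(series.pcorr) > 0.999

    def test_delayed_copy_duration_tracks_delay(self):
        delay = 2
        rng = np.random.default_rng(7)
        x = rng.standard_normal(400)
        y = np.concatenate([np.zeros(delay), x[:-delay]]) + 1e-4 * rng.standard_normal(400)
        plan = plan_windows(400, 80, 40)
        series = sliding_capacity(x, y, plan, OrderSelectionConfig(criterion="BIC", k_max=5))
        assert np.nanmedian(series.duration_trs) == delay + 1
        assert np.nanmin(series.pcorr) > 0.99

    def test_null_capacity_far_below_coupled(self):
        rng = np.random.default_rng(11)
        T, n = 600, 50
        plan = plan_windows(T, n, 1)
        cfg = OrderSelectionConfig(criterion="BIC", k_max=3)
        x0, y0 = rng.standard_normal(T), rng.standard_normal(T)
        null = sliding_capacity(x0, y0, plan, cfg, grid_size=512)
        ts = simulate_pair(ChannelSimSpec(taps=(1.0,), noise_sd=1.0, length=T, seed=13))
        coupled = sliding_capacity(ts.values[0], ts.values[1], plan, cfg, grid_size=512)
        assert np.nanmedian(coupled.capacity) >= 5 * np.nanmedian(null.capacity)

    def test_directed_coupling_yields_asymmetry(self):
        ts = simulate_pair(ChannelSimSpec(taps=(0.8, 0.8), noise_sd=0.8, length=400, seed=21))
        plan = plan_windows(400, 50, 3)
        cfg = OrderSelectionConfig(criterion="BIC", k_max=4)
        fwd = sliding_capacity(ts.values[0], ts.values[1], plan, cfg, grid_size=512)
        bwd = sliding_capacity(ts.values[1], ts.values[0], plan, cfg, grid_size=512)
        assert np.nanmean(fwd.capacity) > np.nanmean(bwd.capacity)

    def test_series_alignment_and_determinism(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        plan = plan_windows(200, 40, 10)
        cfg = OrderSelectionConfig(criterion="AICc", k_max=3)
        a = sliding_capacity(x, y, plan, cfg, grid_size=256)
        b = sliding_capacity(x, y, plan, cfg, grid_size=256)
        assert a.capacity.size == a.pcorr.size == a.swc.size == a.duration_trs.size
        for field in ("capacity", "pcorr", "swc", "duration_trs"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_degenerate_window_missing_in_all_series(self, rng):
        x = rng.standard_normal(60)
        x[:20] = 5.0  # constant first window
        y = rng.standard_normal(60)
        plan = plan_windows(60, 20, 20)
        series = sliding_capacity(x, y, plan, OrderSelectionConfig(k_max=1))
        assert np.isnan(series.capacity[0]) and np.isnan(series.swc[0])
        assert np.isnan(series.pcorr[0]) and np.isnan(series.duration_trs[0])
        assert np.isfinite(series.capacity[1:]).all()


class TestSessionLevel:
    def make_session(self, seed=0, R=3, T=150):
        rng = np.random.default_rng(seed)
        return RoiTimeSeriesSet(
            values=rng.standard_normal((R, T)),
            roi_labels=[f"r{i}" for i in range(R)],
            tr_seconds=0.5,
            scan_id="s0",
        )

    def test_all_directed_pairs_covered(self):
        ts = self.make_session()
        plan = plan_windows(ts.n_samples, 50, 25)
        series = analyze_session(ts, plan, OrderSelectionConfig(k_max=2), grid_size=128)
        assert set(series) == {(a, b) for a in ts.roi_labels for b in ts.roi_labels if a != b}
        frame = session_to_frame(series, ts.scan_id)
        assert len(frame) == 6 * plan.n_windows
        assert frame["window_start_s"].max() == pytest.approx(
            plan.window_starts[-1] * 0.5
        )

    def test_time_average_matrix_swc_symmetric(self):
        ts = self.make_session(seed=5)
        plan = plan_windows(ts.n_samples, 50, 10)
        series = analyze_session(ts, plan, OrderSelectionConfig(k_max=2), grid_size=128)
        swc = time_average_matrix(series, ts.roi_labels, "swc").to_numpy()
        np.testing.assert_allclose(swc, swc.T, atol=1e-12)
        assert np.isnan(np.diag(swc)).all()
        cap = time_average_matrix(series, ts.roi_labels, "capacity").to_numpy()
        offdiag = cap[~np.eye(3, dtype=bool)]
        assert np.all(offdiag >= 0)

    def test_constant_series_time_average(self):
        from swcapacity.sliding import DirectedMeasureSeries

        s = DirectedMeasureSeries(
            sender="a", receiver="b",
            capacity=np.full(5, 0.7), pcorr=np.full(5, 0.5),
            swc=np.full(5, 0.5), duration_trs=np.ones(5),
            window_starts=np.arange(5),
        )
        mat = time_average_matrix({("a", "b"): s}, ["a", "b"], "capacity")
        assert mat.loc["a", "b"] == pytest.approx(0.7)
        assert np.isnan(mat.loc["b", "a"])


class TestTrialLevel:
    def test_single_window_reproduces_trial_analysis(self):
        x, y = correlated_pair(0.4, n=16, seed=2)
        cap, pcorr, dur = single_window_measures(x, y, OrderSelectionConfig(criterion="AICc"))
        assert dur == 1
        assert cap == pytest.approx(-0.5 * np.log1p(-0.4**2), abs=1e-9)
        assert pcorr == pytest.approx(0.4, abs=1e-9)

    def test_batch_path_matches_generic_pipeline(self, rng):
        X = rng.standard_normal((40, 16))
        Y = rng.standard_normal((40, 16))
        cfg = OrderSelectionConfig(criterion="AICc")  # k_max resolves to 1 at n=16
        fast = trial_measures_batch(X, Y, cfg)
        slow = np.array(
            [single_window_measures(x, y, cfg)[0] for x, y in zip(X, Y)]
        )
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_batch_loop_path_at_higher_k_max(self, rng):
        X = rng.standard_normal((5, 40))
        Y = rng.standard_normal((5, 40))
        cfg = OrderSelectionConfig(criterion="BIC", k_max=3)
        fast = trial_measures_batch(X, Y, cfg)
        slow = np.array([single_window_measures(x, y, cfg)[0] for x, y in zip(X, Y)])
        np.testing.assert_allclose(fast, slow, atol=1e-12)
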