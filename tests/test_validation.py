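import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from swcapacity import (
    InsufficientDataError,
    bootstrap_matrix_correlation,
    bootstrap_window_correlation,
    sensitivity_test,
    specificity_test,
)
from swcapacity.simulate import simulate_task_rest
from tests.helpers import bh_qvalues_bruteforce, wilcoxon_left_p_enumeration


def paired_frame(task, rest):
    """task/rest: arrays (units, pairs) -> long paired-sample frame."""
    units, pairs = task.shape
    rows = []
    for u in range(units):
        for p in range(pairs):
            rows.append(
                {"unit_id": f"u{u}", "pair": f"p{p:02d}",
                 "task_value": task[u, p], "rest_value": rest[u, p]}
            )
    return pd.DataFrame(rows)


class TestSensitivity:
    def test_no_effect_no_discoveries(self, rng):
        vals = np.abs(rng.standard_normal((10, 5))) + 1.0
        report = sensitivity_test(paired_frame(vals, vals.copy()))
        assert report.significant_set == []

    def test_planted_effects_recovered(self):
        recovered, false_pos = [], []
        for seed in range(20):
            samples = simulate_task_rest(seed=seed)
            report = sensitivity_test(samples)
            sig = set(report.significant_set)
            planted = set(samples.loc[samples.planted, "pair"])
            recovered.append(len(sig & planted))
            false_pos.append(len(sig - planted))
        assert np.mean([r >= 3 for r in recovered]) >= 0.9
        assert np.mean([f == 0 for f in false_pos]) >= 0.9

    def test_cv_filter_excludes_noisy_pairs(self, rng):
        task = np.abs(rng.standard_normal((12, 3))) + 2.0
        task[:, 0] = rng.uniform(0.01, 5.0, 12)  # CV >> 30%
        rest = np.zeros_like(task)
        report = sensitivity_test(paired_frame(task, rest))
        row = report.table.set_index("pair").loc["p00"]
        assert not row["tested"]

    def test_nonpositive_mean_excluded(self):
        task = np.zeros((5, 2))
        task[:, 1] = 1.0 + 0.01 * np.arange(5)
        rest = np.zeros_like(task)
        report = sensitivity_test(paired_frame(task, rest))
        assert not report.table.set_index("pair").loc["p00", "tested"]

    def test_too_few_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            sensitivity_test(paired_frame(np.ones((2, 2)), np.zeros((2, 2))))

    def test_bh_qvalues_match_bruteforce(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.5])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh_qvalues_bruteforce(p), rtol=1e-12)
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.5], rtol=1e-12)
        # q-values dominate p-values elementwise
        assert np.all(q >= p)


class TestSpecificity:
    def frame(self, fwd, bwd):
        return pd.DataFrame(
            {"scan_id": [f"s{i}" for i in range(len(fwd))],
             "forward_mean": fwd, "backward_mean": bwd}
        )

    def test_asymmetry_equal_to_variability_not_rejected(self):
        fwd = np.linspace(1.0, 2.0, 10)
        bwd = fwd.copy()
        var = 0.0  # asymmetries are all exactly zero -> all differences zero
        report = specificity_test(self.frame(fwd, bwd), variability=var)
        assert not report.rejected and report.p_value >= 0.5

    def test_small_asymmetry_rejects_null(self, rng):
        fwd = 1.0 + 0.3 * rng.standard_normal(22)
        bwd = fwd + 0.001 * rng.standard_normal(22)
        report = specificity_test(self.frame(fwd, bwd))
        assert report.rejected and report.p_value < 0.02

    def test_large_asymmetry_does_not_reject(self, rng):
        fwd = 2.0 + 0.05 * rng.standard_normal(22)
        bwd = 1.0 + 0.05 * rng.standard_normal(22)
        report = specificity_test(self.frame(fwd, bwd))
        assert not report.rejected

    def test_matches_exact_sign_enumeration(self, rng):
        for _ in range(10):
            d = rng.standard_normal(9)
            fwd = np.abs(d) + 1.0
            bwd = np.ones(9)
            # variability=1 makes asymmetry - variability == |d| + 1 - 1... use direct d
            report = specificity_test(
                self.frame(fwd, bwd), variability=1.0
            )
            expected = wilcoxon_left_p_enumeration(np.abs(d) - 1.0)
            assert report.p_value == pytest.approx(expected, abs=1e-12)

    def test_too_few_scans(self):
        with pytest.raises(InsufficientDataError):
            specificity_test(self.frame(np.ones(4), np.zeros(4)))


class TestBootstrapWindows:
    def test_identical_series_all_replicates_one(self, rng):
        series = {f"s{i}": rng.standard_normal(30) for i in range(3)}
        summary = bootstrap_window_correlation(series, series, n_boot=200, seed=1)
        np.testing.assert_allclose(summary.replicates, 1.0)

    def test_seeded_reproducibility(self, rng):
        a = {f"s{i}": rng.standard_normal(40) for i in range(4)}
        b = {k: v + rng.standard_normal(40) for k, v in a.items()}
        s1 = bootstrap_window_correlation(a, b, n_boot=300, seed=7)
        s2 = bootstrap_window_correlation(a, b, n_boot=300, seed=7)
        np.testing.assert_array_equal(s1.replicates, s2.replicates)

    def test_mean_tracks_plugin_estimate(self, rng):
        a = {f"s{i}": rng.standard_normal(120) for i in range(5)}
        b = {k: v + rng.standard_normal(120) for k, v in a.items()}  # SNR 1
        summary = bootstrap_window_correlation(a, b, n_boot=500, seed=3)
        av = np.concatenate(list(a.values()))
        bv = np.concatenate(list(b.values()))
        plugin = np.corrcoef(av, bv)[0, 1]
        assert abs(summary.mean - plugin) < 0.1

    def test_independent_series_ci_covers_zero(self, rng):
        covered = 0
        for rep in range(20):
            a = {f"s{i}": rng.standard_normal(60) for i in range(4)}
            b = {f"s{i}": rng.standard_normal(60) for i in range(4)}
            s = bootstrap_window_correlation(a, b, n_boot=300, seed=rep)
            covered += s.ci_low <= 0 <= s.ci_high
        assert covered >= 15

    def test_nan_windows_dropped_short_scans_excluded(self, rng):
        a = {"s0": rng.standard_normal(30), "s1": np.full(5, np.nan)}
        b = {"s0": a["s0"] * 2, "s1": rng.standard_normal(5)}
        summary = bootstrap_window_correlation(a, b, n_boot=100, seed=0)
        assert summary.n_scans == 1
        np.testing.assert_allclose(summary.replicates, 1.0)


class TestBootstrapMatrices:
    def test_identical_matrices_all_one(self, rng):
        mats = [rng.uniform(0, 1, (4, 4)) for _ in range(5)]
        s = bootstrap_matrix_correlation(mats, mats, n_boot=100, seed=0)
        np.testing.assert_allclose(s.replicates, 1.0)

    def test_shared_structure_share_is_monotone(self, rng):
        base = rng.uniform(0, 1, (5, 5))
        means = []
        for share in (0.2, 0.6, 1.5):
            mats_a = [base + rng.normal(0, 0.5, (5, 5)) / share for _ in range(8)]
            mats_b = [base + rng.normal(0, 0.5, (5, 5)) / share for _ in range(8)]
            means.append(
                bootstrap_matrix_correlation(mats_a, mats_b, n_boot=200, seed=1).mean
            )
        assert means[0] < means[1] < means[2]

    def test_permuted_entries_ci_covers_zero(self, rng):
        mats_a = [rng.uniform(0, 1, (5, 5)) for _ in range(10)]
        mats_b = [m.copy() for m in mats_a]
        perm = rng.permutation(20)
        off = ~np.eye(5, dtype=bool)
        for m in mats_b:
            vals = m[off]
            m[off] = vals[perm]
        s = bootstrap_matrix_correlation(mats_a, mats_b, n_boot=300, seed=2)
        assert s.ci_low <= 0 <= s.ci_high

    def test_single_scan_degenerate(self, rng):
        with pytest.raises(InsufficientDataError):
            bootstrap_matrix_correlation([np.ones((3, 3))], [np.ones((3, 3))], 100, 0)
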