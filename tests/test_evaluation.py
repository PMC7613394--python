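import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uavtraits.evaluation import (
    compare_report,
    friedman_test,
    metrics,
    paired_ttest,
    pairwise_posthoc,
)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        m = metrics(obs, obs)
        assert m.r2 == 1.0 and m.rmse == 0.0 and m.nrmse_pct == 0.0

    def test_nrmse_arithmetic(self):
        obs = np.array([0.0, 5.0, 2.5, 1.0])
        pred = obs + 0.5  # rmse exactly 0.5, range 5
        m = metrics(obs, pred)
        assert m.rmse == pytest.approx(0.5)
        assert m.nrmse_pct == pytest.approx(10.0)
        assert m.range_used == 5.0

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.random(50), rng.random(50)
        m = metrics(obs, pred)
        rmse = (sum((o - p) ** 2 for o, p in zip(obs, pred)) / 50) ** 0.5
        assert m.rmse == pytest.approx(rmse, abs=1e-12)
        assert m.nrmse_pct == pytest.approx(
            100 * rmse / (max(obs) - min(obs)), abs=1e-10)
        assert m.r2 == pytest.approx(
            stats.pearsonr(obs, pred).statistic ** 2, abs=1e-12)

    def test_explained_variance_mode(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        m = metrics(obs, pred, r2_mode="explained")
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.array([2.0, 2.0]), np.array([1.0, 3.0]))


class TestFriedman:
    def test_consistent_ranking_statistic(self):
        """Five blocks ranking three methods identically give chi2 = 10."""
        E = np.tile([1.0, 2.0, 3.0], (5, 1))
        stat, p = friedman_test(E)
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10.0, 2))

    def test_identical_columns_null(self):
        E = np.tile([[2.0, 2.0, 2.0]], (6, 1))
        stat, p = friedman_test(E)
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        E = rng.random((12, 4))
        stat, p = friedman_test(E)
        ref = stats.friedmanchisquare(*E.T)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_p_close_to_exact_permutation_distribution(self):
        """Chi-squared p within 0.02 of the exhaustive within-block
        permutation distribution on a 4x3 fixture."""
        E = np.array([[1.0, 2.0, 3.0],
                      [1.5, 2.5, 2.0],
                      [1.0, 3.0, 2.0],
                      [2.0, 2.5, 3.0]])
        stat, p = friedman_test(E)
        perm_stats = [
            friedman_test(np.array(rows))[0]
            for rows in itertools.product(
                *[list(itertools.permutations(r)) for r in E])
        ]
        p_exact = float(np.mean(np.array(perm_stats) >= stat - 1e-9))
        assert p == pytest.approx(p_exact, abs=0.02)

    def test_invariant_to_monotone_block_transform(self):
        rng = np.random.default_rng(2)
        E = rng.random((8, 3))
        stat, _ = friedman_test(E)
        stat2, _ = friedman_test(np.exp(3 * E))
        assert stat == pytest.approx(stat2, abs=1e-10)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))


class TestPosthoc:
    def test_two_methods_adjusted_equals_raw(self):
        rng = np.random.default_rng(3)
        E = rng.random((10, 2))
        ph = pairwise_posthoc(E)
        assert ph["p_adjusted"].iloc[0] == pytest.approx(
            ph["p_raw"].iloc[0])

    def test_identical_columns_all_one(self):
        E = np.tile([[1.0, 1.0, 1.0]], (8, 1))
        ph = pairwise_posthoc(E)
        assert (ph["p_adjusted"] == 1.0).all()

    def test_dominance_between_raw_and_bonferroni(self):
        """Bergmann-Hommel adjusted p lies between the raw p and the
        Bonferroni adjustment for a 3-method fixture."""
        rng = np.random.default_rng(4)
        E = rng.random((15, 3)) + np.array([0.0, 0.15, 0.4])
        ph = pairwise_posthoc(E)
        m = len(ph)
        assert (ph["p_adjusted"] >= ph["p_raw"] - 1e-12).all()
        assert (ph["p_adjusted"]
                <= np.minimum(1.0, m * ph["p_raw"]) + 1e-12).all()

    def test_holm_fallback_for_many_methods(self):
        rng = np.random.default_rng(5)
        E = rng.random((10, 6))
        ph = pairwise_posthoc(E)  # silently falls back to Holm
        assert len(ph) == 15
        with pytest.raises(ValueError, match="k <= 4"):
            pairwise_posthoc(E, fallback=False)


class TestPairedT:
    def test_hand_computed_fixture(self):
        b = np.zeros(4)
        a = np.array([1.0, 0.0, -1.0, 2.0])
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(0.7746, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(10), rng.random(10)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_equal_samples_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_ttest(a, a.copy())


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(7)
    n = 40
    meas = pd.DataFrame({
        "plot_id": [f"P{i}" for i in range(n)],
        "date": np.repeat(["d1", "d2"], n // 2),
        "nitrogen": np.tile([80, 180, 280, 180], n // 4),
        "lai": rng.uniform(1, 6, n),
        "fcover": rng.uniform(0.1, 1, n),
        "ccc": rng.uniform(0.5, 3, n),
    })
    frames = []
    for i, method in enumerate(["m1", "m2", "m3"]):
        p = meas[["plot_id", "lai", "fcover", "ccc"]].copy()
        for t in ("lai", "fcover", "ccc"):
            p[t] = p[t] + rng.normal(0, 0.1 * (i + 1), n)
        p.insert(0, "method", method)
        frames.append(p)
    return pd.concat(frames, ignore_index=True), meas


class TestCompareReport:
    def test_report_layout(self, toy_data):
        preds, meas = toy_data
        rep = compare_report(preds, meas)
        # 3 methods x 3 variables x (2 dates + pooled)
        assert len(rep.metrics) == 3 * 3 * 3
        assert set(rep.friedman["variable"]) == {"lai", "fcover", "ccc"}

    def test_single_method_single_date_no_tests(self, toy_data):
        preds, meas = toy_data
        one = preds[preds["method"] == "m1"]
        meas1 = meas[meas["date"] == "d1"]
        rep = compare_report(one.merge(meas1[["plot_id"]], on="plot_id"),
                             meas1, groupings=("pooled",))
        assert len(rep.metrics) == 3  # one row per variable
        assert rep.friedman.empty

    def test_order_invariance(self, toy_data):
        preds, meas = toy_data
        rep1 = compare_report(preds, meas)
        shuffled = preds.sample(frac=1, random_state=0).reset_index(drop=True)
        rep2 = compare_report(shuffled, meas)
        a = rep1.metrics.sort_values(
            ["method", "variable", "group_type", "group"]).reset_index(drop=True)
        b = rep2.metrics.sort_values(
            ["method", "variable", "group_type", "group"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_nrmse_identity_on_every_row(self, toy_data):
        preds, meas = toy_data
        rep = compare_report(preds, meas, groupings=("pooled", "date",
                                                     "nitrogen"))
        np.testing.assert_allclose(
            rep.metrics["nrmse_pct"],
            100 * rep.metrics["rmse"] / rep.metrics["range_used"],
            atol=1e-10,
        )

    def test_better_method_ranks_better(self, toy_data):
        preds, meas = toy_data
        rep = compare_report(preds, meas, groupings=("pooled",))
        pooled = rep.metrics.set_index(["method", "variable"])
        assert (pooled.loc[("m1", "lai"), "nrmse_pct"]
                < pooled.loc[("m3", "lai"), "nrmse_pct"])
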