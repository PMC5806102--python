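import numpy as np
import pandas as pd
import pytest

from pairsig.evaluation import (
    TdROC,
    classify,
    compare_cindex,
    group_hr,
    harrell_cindex,
    km_estimate,
    optimal_cutoff,
    subgroup_analysis,
    td_roc_nne,
)


def brute_force_km(time, event, grid):
    """Hand product-limit: S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""
    out = []
    for t in grid:
        s = 1.0
        for tj in sorted(set(time[event == 1])):
            if tj > t:
                break
            n_j = (time >= tj).sum()
            d_j = ((time == tj) & (event == 1)).sum()
            s *= 1.0 - d_j / n_j
        out.append(s)
    return np.array(out)


def brute_force_cindex(scores, time, event):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestKaplanMeier:
    def test_three_events_hand_values(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        km = km_estimate(surv)
        np.testing.assert_allclose(km([1.0, 2.0, 3.0]), [2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert km(0.5) == 1.0

    def test_no_events_curve_stays_at_one(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 5.0], "event": [0, 0, 0]})
        km = km_estimate(surv)
        assert (km(np.array([0.5, 3.0, 10.0])) == 1.0).all()

    def test_trailing_censoring_adds_no_step(self):
        """A sample censored after the last event leaves the curve flat there."""
        b = pd.DataFrame({"time": [1.0, 2.0, 3.0, 9.0], "event": [1, 1, 1, 0]})
        km = km_estimate(b)
        assert km(9.5) == km(3.0)  # no drop at or after the censoring time
        np.testing.assert_allclose(
            km([1.0, 2.0, 3.0]), [3 / 4, 2 / 4, 1 / 4], atol=1e-12
        )

    def test_matches_brute_force_with_censoring(self, small_surv):
        time = small_surv["time"].to_numpy()
        event = small_surv["event"].to_numpy()
        km = km_estimate(small_surv)
        grid = np.linspace(0.1, time.max() + 1, 37)
        np.testing.assert_allclose(km(grid), brute_force_km(time, event, grid), atol=1e-12)

    def test_empty_group_rejected(self, small_surv):
        with pytest.raises(ValueError):
            km_estimate(small_surv, mask=np.zeros(len(small_surv), bool))


class TestTdROC:
    def test_perfect_marker_no_censoring_auc_one(self):
        n = 60
        time = np.arange(1.0, n + 1)
        scores = -time  # higher score = earlier event
        # neighborhood below the rank spacing: the estimator is the empirical ROC
        roc = td_roc_nne(scores, time, np.ones(n, int), t=30.5, span=0.01)
        assert roc.auc == pytest.approx(1.0, abs=1e-12)
        assert roc.tpr.min() == 0.0 and roc.tpr.max() == 1.0
        assert roc.fpr.min() == 0.0 and roc.fpr.max() == 1.0

    def test_null_marker_auc_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 300
            scores = rng.normal(size=n)
            time = rng.exponential(60, n)
            event = (rng.random(n) < 0.7).astype(int)
            aucs.append(td_roc_nne(scores, time, event, t=60.0).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        n = 200
        scores = rng.normal(size=n)
        time = rng.exponential(40, n)
        event = (rng.random(n) < 0.6).astype(int)
        a = td_roc_nne(scores, time, event, t=40.0).auc
        b = td_roc_nne(-scores, time, event, t=40.0).auc
        assert a + b == pytest.approx(1.0, abs=1e-6)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(8)
        n = 150
        scores = rng.normal(size=n)
        time = rng.exponential(30, n)
        event = (rng.random(n) < 0.5).astype(int)
        roc = td_roc_nne(scores, time, event, t=25.0)
        assert (np.diff(roc.tpr) <= 1e-12).all()  # thresholds ascend, rates descend
        assert (np.diff(roc.fpr) <= 1e-12).all()
        assert 0.0 <= roc.auc <= 1.0
        assert roc.tpr[0] == pytest.approx(1.0) and roc.fpr[0] == pytest.approx(1.0)
        assert roc.tpr[-1] == 0.0 and roc.fpr[-1] == 0.0

    def test_no_events_by_horizon_rejected(self):
        time = np.array([10.0, 20.0, 30.0])
        with pytest.raises(ValueError):
            td_roc_nne(np.array([1.0, 2.0, 3.0]), time, np.array([1, 1, 1]), t=5.0)

    def test_matches_plain_roc_without_censoring(self):
        """With no censoring and a sub-rank span, NNE reduces to the
        empirical ROC of the binary event-by-t outcome."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        n = 120
        scores = rng.normal(size=n)
        time = rng.exponential(30 * np.exp(-scores), n) + 1e-6
        event = np.ones(n, int)
        t = float(np.median(time))
        roc = td_roc_nne(scores, time, event, t=t, span=1.0 / (2 * n))
        sk = roc_auc_score((time <= t).astype(int), scores)
        assert roc.auc == pytest.approx(sk, abs=1e-10)


class TestCutoffAndClassification:
    def test_toy_curve_minimum_distance(self):
        roc = TdROC(
            horizon=60.0,
            span=0.1,
            thresholds=np.array([-1.0, 0.0, 1.0]),
            tpr=np.array([1.0, 0.9, 0.2]),
            fpr=np.array([0.5, 0.3, 0.1]),
            auc=0.8,
        )
        # distances: 0.5, ~0.316, ~0.806 -> middle threshold wins
        assert optimal_cutoff(roc) == 0.0

    def test_perfect_corner_and_tie_break(self):
        roc = TdROC(
            horizon=60.0, span=0.1,
            thresholds=np.array([0.0, 1.0, 2.0]),
            tpr=np.array([1.0, 1.0, 0.5]),
            fpr=np.array([0.3, 0.0, 0.0]),
            auc=1.0,
        )
        assert optimal_cutoff(roc) == 1.0
        tie = TdROC(
            horizon=60.0, span=0.1,
            thresholds=np.array([0.0, 1.0]),
            tpr=np.array([0.8, 0.8]),
            fpr=np.array([0.2, 0.2]),
            auc=0.5,
        )
        assert optimal_cutoff(tie) == 0.0  # ties toward the lower threshold

    def test_classify_boundary_goes_high(self):
        groups = classify(np.array([-0.2, -0.154, -0.1]), cutoff=-0.154)
        assert groups.tolist() == [0, 1, 1]
        # the published all-indicators-one score clears the published cutoff
        assert classify(np.array([-0.086106771]), cutoff=-0.154).tolist() == [1]
        assert classify(np.array([-1.0, -2.0]), cutoff=0.0).sum() == 0


class TestGroupHR:
    def test_identical_groups_hr_one(self):
        time = np.r_[np.arange(1.0, 21.0), np.arange(1.0, 21.0)]
        event = np.r_[np.ones(20, int), np.ones(20, int)]
        surv = pd.DataFrame({"time": time, "event": event})
        groups = np.r_[np.ones(20, int), np.zeros(20, int)]
        comp = group_hr(surv, groups)
        assert comp.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert comp.ci_low < 1.0 < comp.ci_high

    def test_label_swap_inverts_hr(self, planted_cohort):
        expr = planted_cohort.expression
        groups = (expr.iloc[0] > expr.iloc[1]).astype(int).to_numpy()
        a = group_hr(planted_cohort.survival, groups)
        b = group_hr(planted_cohort.survival, 1 - groups)
        assert a.hazard_ratio == pytest.approx(1.0 / b.hazard_ratio, abs=1e-9)

    def test_generating_log_hazard_within_two_se(self, planted_cohort):
        """The planted pair's indicator groups have ln(HR) near beta = 1.5."""
        a_gene, b_gene, beta = planted_cohort.truth[0]
        expr = planted_cohort.expression
        groups = (expr.loc[a_gene] > expr.loc[b_gene]).astype(int).to_numpy()
        comp = group_hr(planted_cohort.survival, groups)
        se = (np.log(comp.ci_high) - np.log(comp.ci_low)) / (2 * 1.959964)
        assert abs(np.log(comp.hazard_ratio) - beta) < 2 * se

    def test_no_event_group_flagged(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 0, 0]})
        comp = group_hr(surv, np.array([1, 1, 0, 0]))
        assert comp.warning


class TestConcordance:
    def test_perfect_marker_c_one(self):
        time = np.arange(1.0, 11.0)
        res = harrell_cindex(-time, time, np.ones(10, int))
        assert res.cindex == 1.0

    def test_matches_brute_force_with_censoring_and_ties(self):
        rng = np.random.default_rng(17)
        for n in (5, 20, 50):
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            scores = rng.integers(0, 4, n).astype(float)  # force score ties
            if not ((time[:, None] < time[None, :]) & (event[:, None] == 1)).any():
                continue
            res = harrell_cindex(scores, time, event)
            assert res.cindex == pytest.approx(
                brute_force_cindex(scores, time, event), abs=1e-12
            )

    def test_matches_lifelines_on_tie_free_fixture(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(23)
        n = 40
        time = np.sort(rng.exponential(10, n)) + np.linspace(0, 1e-3, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        scores = rng.normal(size=n)
        res = harrell_cindex(scores, time, event)
        # lifelines orders by predicted survival time = -risk
        assert res.cindex == pytest.approx(
            concordance_index(time, -scores, event), abs=1e-12
        )

    def test_random_marker_near_half_with_sane_ci(self):
        rng = np.random.default_rng(31)
        n = 300
        time = rng.exponential(60, n)
        event = (rng.random(n) < 0.7).astype(int)
        res = harrell_cindex(rng.normal(size=n), time, event)
        assert abs(res.cindex - 0.5) < 0.06
        assert res.ci_low < res.cindex < res.ci_high
        assert 0.0 < res.se < 0.1

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex(np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.array([0, 0]))


class TestCompareCindex:
    def test_identical_markers(self, planted_cohort):
        scores = np.arange(300, dtype=float)
        delta, p, _ = compare_cindex(scores, scores, planted_cohort.survival, B=50, seed=0)
        assert delta == 0.0 and p == pytest.approx(1.0)

    def test_swap_negates_delta(self, planted_cohort):
        rng = np.random.default_rng(2)
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        d1, p1, _ = compare_cindex(a, b, planted_cohort.survival, B=200, seed=3)
        d2, p2, _ = compare_cindex(b, a, planted_cohort.survival, B=200, seed=3)
        assert d1 == pytest.approx(-d2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_perfect_vs_random_marker_detected(self):
        rng = np.random.default_rng(4)
        n = 200
        time = rng.exponential(30, n)
        event = (rng.random(n) < 0.8).astype(int)
        surv = pd.DataFrame({"time": time, "event": event})
        for seed in range(3):
            rng_s = np.random.default_rng(seed)
            _, p, _ = compare_cindex(-time, rng_s.normal(size=n), surv, B=200, seed=seed)
            assert p < 0.05


class TestSubgroups:
    def test_single_stratum_equals_whole_cohort(self, planted_cohort):
        expr = planted_cohort.expression
        groups = (expr.iloc[0] > expr.iloc[1]).astype(int).to_numpy()
        table = subgroup_analysis(
            planted_cohort.survival,
            groups,
            planted_cohort.clinical,
            {"all": ("age", lambda v: True)},
        )
        whole = group_hr(planted_cohort.survival, groups)
        row = table.iloc[0]
        assert row["hazard_ratio"] == pytest.approx(whole.hazard_ratio, abs=1e-12)
        assert row["logrank_p"] == pytest.approx(whole.logrank_p, abs=1e-12)

    def test_age_strata_lnhr_within_two_se(self, planted_cohort):
        """Age is independent of risk, so each stratum recovers beta = 1.5."""
        a_gene, b_gene, beta = planted_cohort.truth[0]
        expr = planted_cohort.expression
        groups = (expr.loc[a_gene] > expr.loc[b_gene]).astype(int).to_numpy()
        table = subgroup_analysis(
            planted_cohort.survival,
            groups,
            planted_cohort.clinical,
            {
                "age<65": ("age", lambda v: v < 65),
                "age>=65": ("age", lambda v: v >= 65),
            },
        )
        for _, row in table.iterrows():
            assert not row["flagged"]
            se = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.959964)
            assert abs(np.log(row["hazard_ratio"]) - beta) < 2 * se

    def test_empty_stratum_flagged_not_fabricated(self, planted_cohort):
        groups = np.r_[np.ones(150, int), np.zeros(150, int)]
        table = subgroup_analysis(
            planted_cohort.survival,
            groups,
            planted_cohort.clinical,
            {"nobody": ("age", lambda v: v > 1000)},
        )
        assert bool(table.iloc[0]["flagged"])
        assert np.isnan(table.iloc[0]["hazard_ratio"])

    def test_unknown_column_rejected(self, planted_cohort):
        with pytest.raises(KeyError):
            subgroup_analysis(
                planted_cohort.survival,
                np.ones(300, int),
                planted_cohort.clinical,
                {"x": ("tnm_stage", lambda v: True)},
            )
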