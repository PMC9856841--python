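import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from sigsurv import survival as sv
from sigsurv.errors import ValidationError
from sigsurv.survival import _logrank_components


def _random_cohort(n, seed, censor=0.3):
    rng = np.random.default_rng(seed)
    time = rng.exponential(10.0, n) + 1e-3
    event = (rng.random(n) > censor).astype(int)
    scores = rng.normal(size=n)
    return time, event, scores


def brute_force_maxstat(time, event, scores, eps=0.1):
    """Independent oracle: enumerate every admissible split and evaluate the
    standardized log-rank statistic by direct tabulation."""
    n = len(scores)
    k_min = int(np.ceil(eps * n - 1e-12))
    best_mu, best_z = None, -np.inf
    for mu in np.unique(scores)[:-1]:
        low = scores <= mu
        k = int(low.sum())
        if k < k_min or n - k < k_min:
            continue
        o1, e1, v1 = _logrank_components(time, event, low)
        z = abs(o1 - e1) / np.sqrt(v1) if v1 > 0 else 0.0
        if z > best_z + 1e-12:
            best_mu, best_z = float(mu), z
    return best_mu, best_z


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = sv.km_estimate([1, 2, 3], [1, 1, 1], ["g", "g", "g"])
        surv = km.set_index("time")["survival"]
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = sv.km_estimate([1, 2, 3, 4], [0, 0, 0, 0], ["g"] * 4)
        assert (km["survival"] == 1.0).all()

    def test_doubling_subjects_leaves_curve_unchanged(self):
        time = [1.0, 2.0, 3.0, 5.0]
        event = [1, 0, 1, 1]
        km1 = sv.km_estimate(time, event, ["g"] * 4)
        km2 = sv.km_estimate(time * 2, event * 2, ["g"] * 8)
        np.testing.assert_allclose(km1["survival"], km2["survival"])

    def test_curves_non_increasing_start_at_one(self):
        time, event, scores = _random_cohort(80, 1)
        labels = np.where(scores > 0, "high", "low")
        km = sv.km_estimate(time, event, labels)
        for _, grp in km.groupby("group"):
            s = grp.sort_values("time")["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert (np.diff(s) <= 1e-12).all()


class TestLogrank:
    def test_identical_multisets_null(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 0, 1, 1, 0]
        stat, p = sv.logrank(time, event, ["a"] * 3 + ["b"] * 3)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_six_subjects(self):
        # groups X: (1,e),(3,e),(5,c); Y: (2,e),(4,e),(6,e)
        # O1 = 2, E1 = 0.5 + 0.4 + 0.5 + 1/3, V1 = 0.25+0.24+0.25+2/9
        time = [1, 3, 5, 2, 4, 6]
        event = [1, 1, 0, 1, 1, 1]
        labels = ["X"] * 3 + ["Y"] * 3
        stat, p = sv.logrank(time, event, labels)
        e1 = 0.5 + 0.4 + 0.5 + 1 / 3
        v1 = 0.25 + 0.24 + 0.25 + 2 / 9
        assert stat == pytest.approx((2 - e1) ** 2 / v1, abs=1e-12)

    def test_matches_lifelines(self):
        time, event, scores = _random_cohort(60, 2)
        labels = np.where(scores > 0, "a", "b")
        stat, p = sv.logrank(time, event, labels)
        ref = ll_logrank(
            time[labels == "a"], time[labels == "b"],
            event[labels == "a"], event[labels == "b"],
        )
        assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_relabel_invariance(self):
        time, event, scores = _random_cohort(40, 3)
        labels = np.where(scores > 0, "a", "b")
        flipped = np.where(labels == "a", "b", "a")
        assert sv.logrank(time, event, labels)[0] == pytest.approx(
            sv.logrank(time, event, flipped)[0]
        )

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            sv.logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])


class TestMaxstat:
    def test_matches_bruteforce_enumeration(self):
        for seed in range(8):
            time, event, scores = _random_cohort(25, seed)
            res = sv.maxstat_cutpoint(time, event, scores)
            mu, z = brute_force_maxstat(time, event, scores)
            assert res.cutpoint == pytest.approx(mu, abs=0)
            assert res.statistic == pytest.approx(z, abs=1e-9)

    def test_recovers_planted_separation(self):
        # two survival-disjoint groups separated perfectly by the score
        time = np.r_[np.linspace(1, 3, 10), np.linspace(20, 30, 10)]
        event = np.ones(20, dtype=int)
        scores = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        res = sv.maxstat_cutpoint(time, event, scores, eps=0.1)
        assert res.cutpoint == -1.0
        assert res.n_low == 10
        o1, e1, v1 = _logrank_components(time, event, scores <= res.cutpoint)
        assert res.statistic == pytest.approx(abs(o1 - e1) / np.sqrt(v1))

    def test_monotone_transform_invariance(self):
        time, event, scores = _random_cohort(50, 4)
        r1 = sv.maxstat_cutpoint(time, event, scores)
        r2 = sv.maxstat_cutpoint(time, event, np.exp(scores))
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-9)
        assert r2.n_low == r1.n_low
        assert r2.cutpoint == pytest.approx(np.exp(r1.cutpoint))

    def test_max_dominates_median_split(self):
        time, event, scores = _random_cohort(101, 5)
        res = sv.maxstat_cutpoint(time, event, scores)
        low = scores <= np.median(scores)
        o1, e1, v1 = _logrank_components(time, event, low)
        z_median = abs(o1 - e1) / np.sqrt(v1)
        assert res.statistic >= z_median - 1e-12

    def test_adjusted_p_at_least_unadjusted(self):
        for seed in range(5):
            time, event, scores = _random_cohort(40, seed + 10)
            res = sv.maxstat_cutpoint(time, event, scores)
            assert res.p_adjusted >= res.p_unadjusted - 1e-12
            assert 0.0 <= res.p_adjusted <= 1.0

    def test_permutation_is_seeded(self):
        time, event, scores = _random_cohort(40, 6)
        r1 = sv.maxstat_cutpoint(time, event, scores, method="permutation",
                                 n_perm=99, seed=5)
        r2 = sv.maxstat_cutpoint(time, event, scores, method="permutation",
                                 n_perm=99, seed=5)
        assert r1.p_adjusted == r2.p_adjusted

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"scores": np.ones(30)}, "identical"),
            ({"eps": 0.6}, "eps"),
        ],
    )
    def test_invalid_inputs(self, kwargs, match):
        time, event, scores = _random_cohort(30, 7)
        args = {"time": time, "event": event, "scores": scores}
        args.update(kwargs)
        with pytest.raises(ValidationError, match=match):
            sv.maxstat_cutpoint(**args)


class TestDichotomize:
    def test_median_split(self):
        labels, cut, _ = sv.dichotomize([1, 2, 3, 4], "median")
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        labels, cut, _ = sv.dichotomize([1, 2, 2, 3], "median")
        assert list(labels) == ["low", "low", "low", "high"]

    def test_optimal_delegates_to_maxstat(self):
        time, event, scores = _random_cohort(60, 8)
        labels, cut, res = sv.dichotomize(
            scores, "optimal", time=time, event=event
        )
        direct = sv.maxstat_cutpoint(time, event, scores)
        assert cut == direct.cutpoint
        assert (labels == "low").sum() == direct.n_low

    def test_constant_scores_rejected(self):
        with pytest.raises(ValidationError):
            sv.dichotomize(np.ones(10), "median")


class TestCox:
    def test_matches_lifelines_on_tiefree_data(self):
        time, event, scores = _random_cohort(120, 9)
        labels = np.where(scores > 0.2, "high", "low")
        hr, ci, wald_p = sv.cox_hr(time, event, labels)
        df = pd.DataFrame(
            {"t": time, "e": event, "x": (labels == "high").astype(float)}
        )
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.log(hr) == pytest.approx(cph.params_["x"], abs=1e-6)
        assert wald_p == pytest.approx(
            cph.summary.loc["x", "p"], abs=1e-6
        )
        assert ci[0] < hr < ci[1]

    def test_null_hr_near_one(self):
        rng = np.random.default_rng(11)
        n = 400
        time = rng.exponential(10, n) + 1e-3
        event = (rng.random(n) > 0.2).astype(int)
        labels = np.where(rng.random(n) > 0.5, "high", "low")
        hr, ci, wald_p = sv.cox_hr(time, event, labels)
        assert 0.7 < hr < 1.4
        assert ci[0] < 1.0 < ci[1]

    def test_time_rescaling_invariance(self):
        time, event, scores = _random_cohort(80, 12)
        labels = np.where(scores > 0, "high", "low")
        hr1, ci1, p1 = sv.cox_hr(time, event, labels)
        hr2, ci2, p2 = sv.cox_hr(time * 365.25, event, labels)
        assert hr1 == pytest.approx(hr2, rel=1e-8)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_score_test_equals_logrank_on_tiefree_data(self):
        # U(0)^2 / I(0) of the partial likelihood equals the log-rank
        # chi-square when every event time is unique
        time, event, scores = _random_cohort(70, 13)
        labels = np.where(scores > 0, "high", "low")
        low = labels == "low"
        o1, e1, v1 = _logrank_components(time, event, low)
        u0 = o1 - e1
        i0 = 0.0
        for t in np.unique(time[event == 1]):
            risk = time >= t
            p_low = (risk & low).sum() / risk.sum()
            d = int(((time == t) & (event == 1)).sum())
            i0 += d * p_low * (1 - p_low)
        stat, _ = sv.logrank(time, event, labels)
        assert u0**2 / i0 == pytest.approx(stat, abs=1e-6)

    def test_complete_separation_capped(self):
        time = np.r_[np.linspace(1, 2, 10), np.linspace(50, 60, 10)]
        event = np.r_[np.ones(10), np.ones(10)].astype(int)
        labels = np.array(["low"] * 10 + ["high"] * 10)
        with pytest.warns(UserWarning, match="monotone"):
            hr, ci, wald_p = sv.cox_hr(time, event, labels)
        assert hr < 1e-5

    def test_requires_events_in_both_groups(self):
        time = [1, 2, 3, 4]
        event = [1, 1, 0, 0]
        labels = ["low", "low", "high", "high"]
        with pytest.raises(ValidationError):
            sv.cox_hr(time, event, labels)


class TestFitSurvival:
    def test_fit_reports_consistent_groups(self):
        time, event, scores = _random_cohort(90, 14)
        fit = sv.fit_survival(time, event, scores, cutoff_method="median")
        assert fit.n_low + fit.n_high == 90
        assert fit.ci95[0] < fit.hazard_ratio < fit.ci95[1]
        assert set(fit.km["group"]) == {"low", "high"}

    def test_pooled_at_risk_equals_group_sum(self):
        time, event, scores = _random_cohort(60, 15)
        labels = np.where(scores > 0, "high", "low")
        km = sv.km_estimate(time, event, labels)
        pooled = sv.km_estimate(time, event, ["all"] * 60)
        for t in np.unique(time[event == 1]):
            total = sum(
                (time[labels == g] >= t).sum() for g in ("low", "high")
            )
            row = pooled[pooled["time"] == t]
            assert int(row["at_risk"].iloc[0]) == total
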