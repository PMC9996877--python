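"""KM, log-rank, maximally selected cutpoint and Cox: hand fixtures,
independent-oracle equivalence (lifelines) and null behavior."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from _oracles import km_direct
from crscore.io_formats import ClinicalTable
from crscore.survival_stats import (
    SurvivalError,
    cox_score_test_at_zero,
    cox_univariate,
    km_curve,
    logrank_test,
    optimal_cutpoint,
)


def clinical(times, events):
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(times))],
                "os_time_days": times,
                "os_event": events,
            }
        )
    )


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        c = km_curve(clinical([1, 2, 3], [1, 1, 1]))
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_one(self):
        c = km_curve(clinical([1, 2, 3], [0, 0, 0]))
        assert np.allclose(c.survival, 1.0)

    def test_censoring_between_events(self):
        # {(1,event),(2,censor),(3,event)}: S(1)=2/3, S(3)=2/3*(1-1/1)=0
        c = km_curve(clinical([1, 2, 3], [1, 0, 1]))
        assert c.survival_at(1) == pytest.approx(2 / 3)
        assert c.survival_at(2) == pytest.approx(2 / 3)
        assert c.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=40)
        c = km_curve(clinical(t, np.ones(40, int)))
        for tt in c.times:
            assert c.survival_at(tt) == pytest.approx(np.mean(t > tt))

    def test_matches_direct_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 8, size=30).astype(float)
        e = rng.integers(0, 2, size=30)
        c = km_curve(clinical(t, e))
        for tt, at_risk, d, s in km_direct(t, e):
            i = list(c.times).index(tt)
            assert (c.at_risk[i], c.events[i]) == (at_risk, d)
            assert c.survival[i] == pytest.approx(s)

    def test_empty_group_rejected(self):
        with pytest.raises(SurvivalError, match="empty"):
            km_curve(clinical([1.0], [1]), np.array([False]))


class TestLogrank:
    def test_duplicated_groups_chi2_zero(self):
        c = clinical([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        res = logrank_test(c, ["a", "a", "a", "b", "b", "b"])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_expansion_vs_independent_implementation(self):
        # group A events at (1,2), B at (3,4): O/E/V summed over 4 times
        c = clinical([1, 2, 3, 4], [1, 1, 1, 1])
        groups = ["A", "A", "B", "B"]
        res = logrank_test(c, groups)
        ll = ll_logrank(
            [1, 2], [3, 4], event_observed_A=[1, 1], event_observed_B=[1, 1]
        )
        assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-10)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        c = clinical(rng.exponential(5, 30), rng.integers(0, 2, 30))
        g = np.array(["x"] * 15 + ["y"] * 15)
        assert logrank_test(c, g).chi2 == pytest.approx(
            logrank_test(c, np.where(g == "x", "y", "x")).chi2
        )

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            t = rng.exponential(5, n)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            g = rng.integers(0, 2, n).astype(bool)
            if g.all() or not g.any():
                continue
            res = logrank_test(clinical(t, e), g)
            ll = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert res.chi2 == pytest.approx(ll.test_statistic, rel=1e-10)

    def test_zero_events_rejected(self):
        with pytest.raises(SurvivalError, match="no events"):
            logrank_test(clinical([1, 2], [0, 0]), ["a", "b"])

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(7)
        n = 60
        t = rng.exponential(5, n)
        e = rng.integers(0, 2, n)
        g = np.array([0] * 30 + [1] * 30)
        c = clinical(t, e)
        ps = []
        for _ in range(500):
            ps.append(logrank_test(c, rng.permutation(g)).p)
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - (np.arange(1, 501)) / 501))
        assert ks < 0.1


def _brute_force_cutpoint(values, c, minprop):
    """Independent exhaustive scan using lifelines' log-rank statistic."""
    n = len(values)
    best = None
    for v in np.unique(values):
        high = values > v
        if high.sum() < minprop * n or (~high).sum() < minprop * n or not high.any():
            continue
        t, e = c.time, c.event
        stat = ll_logrank(t[high], t[~high], e[high], e[~high]).test_statistic
        if best is None or stat > best[1] + 1e-12:
            best = (v, stat)
    return best


class TestOptimalCutpoint:
    def test_separating_marker_found_near_true_split(self):
        rng = np.random.default_rng(11)
        values = np.arange(1.0, 21.0)
        # top-10 marker values die fast, bottom-10 survive long
        times = np.where(values > 10, rng.uniform(1, 5, 20), rng.uniform(50, 100, 20))
        events = np.where(values > 10, 1, rng.integers(0, 2, 20))
        res = optimal_cutpoint(values, clinical(times, events), minprop=0.1)
        assert 10.0 <= res.cutpoint < 11.0

    def test_equals_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            n = int(rng.integers(12, 41))
            values = rng.normal(size=n)
            t = rng.exponential(10 * np.exp(-0.5 * values))
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            c = clinical(t, e)
            want = _brute_force_cutpoint(values, c, 0.1)
            if want is None:
                continue
            got = optimal_cutpoint(values, c, minprop=0.1)
            assert got.cutpoint == pytest.approx(want[0])
            assert got.max_abs_standardized_statistic**2 == pytest.approx(
                want[1], rel=1e-9
            )
            checked += 1

    def test_monotone_transform_preserves_partition(self):
        rng = np.random.default_rng(17)
        n = 30
        values = rng.normal(size=n)
        t = rng.exponential(10 * np.exp(-values))
        c = clinical(t, np.ones(n, int))
        r1 = optimal_cutpoint(values, c)
        r2 = optimal_cutpoint(np.exp(values), c)
        assert np.array_equal(values > r1.cutpoint, np.exp(values) > r2.cutpoint)

    def test_minprop_respected(self):
        rng = np.random.default_rng(19)
        n = 40
        values = rng.normal(size=n)
        c = clinical(rng.exponential(5, n), np.ones(n, int))
        res = optimal_cutpoint(values, c, minprop=0.25)
        n_high = (values > res.cutpoint).sum()
        assert n_high >= 10 and n - n_high >= 10

    def test_no_admissible_candidate_rejected(self):
        c = clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(SurvivalError, match="admissible"):
            optimal_cutpoint([1.0, 1.0, 1.0], c)


class TestCox:
    def test_constant_covariate_rejected(self):
        c = clinical([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(SurvivalError, match="constant"):
            cox_univariate([1.0, 1.0, 1.0, 1.0], c)

    def test_matches_lifelines_untied(self):
        # Breslow == Efron without tied event times, so lifelines is a
        # fully independent check here
        rng = np.random.default_rng(23)
        for _ in range(5):
            n = 80
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x))
            e = rng.integers(0, 2, n)
            c = clinical(t, e)
            res = cox_univariate(x, c)
            cph = CoxPHFitter()
            cph.fit(
                pd.DataFrame({"T": t, "E": e, "x": x}),
                duration_col="T",
                event_col="E",
            )
            assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
            assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)
            assert res.converged

    def test_score_test_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(29)
        n = 50
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-x), n) + rng.random(n) * 1e-9  # untie
        e = np.ones(n, int)
        c = clinical(t, e)
        chi2 = cox_score_test_at_zero(x, c)
        lr = logrank_test(c, x > 0.5)
        assert chi2 == pytest.approx(lr.chi2, abs=1e-8)

    def test_direction_agrees_with_logrank(self):
        rng = np.random.default_rng(31)
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-1.2 * x), n)
        c = clinical(t, np.ones(n, int))
        res = cox_univariate(x, c)
        # x=1 has higher hazard -> beta > 0 and group 1 has more observed
        # events than expected
        lr = logrank_test(c, x > 0.5)
        assert res.beta > 0
        assert lr.observed[1] > lr.expected[1]

    def test_separation_flagged_not_silent(self):
        # perfectly separating covariate: likelihood is monotone in beta
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_univariate(x, clinical(t, e))
        assert (not res.converged) or res.flags
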