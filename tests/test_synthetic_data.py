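"""Generator contracts: determinism, invariants, planted-signal structure."""

import numpy as np
import pandas as pd
import pytest

from crscore import io_formats as io
from crscore.crs_model import GeneSetPair, compute_crs
from crscore.enrichment import ssgsea_score
from crscore.survival_stats import cox_univariate, logrank_test
from crscore.synthetic_data import (
    CohortParams,
    KnockoutParams,
    SimulationError,
    TimecourseParams,
    simulate_cohort,
    simulate_compound_library,
    simulate_fractions,
    simulate_genomics,
    simulate_knockout,
    simulate_timecourse,
)

SMALL = CohortParams(n_genes_background=100, n_tumor=30, n_normal=10, seed=42)


class TestDeterminism:
    def test_cohort_identical_under_same_seed(self):
        a = simulate_cohort(SMALL)
        b = simulate_cohort(SMALL)
        assert np.array_equal(a.expr.values.to_numpy(), b.expr.values.to_numpy())
        assert a.clinical.data.equals(b.clinical.data)
        assert np.array_equal(a.true_score.to_numpy(), b.true_score.to_numpy())

    def test_different_seed_differs(self):
        a = simulate_cohort(SMALL)
        b = simulate_cohort(
            CohortParams(n_genes_background=100, n_tumor=30, n_normal=10, seed=43)
        )
        assert not np.array_equal(a.expr.values.to_numpy(), b.expr.values.to_numpy())

    def test_generated_objects_pass_their_invariants(self):
        c = simulate_cohort(SMALL)
        # re-validating through the constructors raises on violation
        io.ExpressionMatrix(c.expr.values, unit="log2")
        io.ClinicalTable(c.clinical.data.copy())
        mut, cnv, expr = simulate_genomics(n_genes=20, n_samples=30, seed=1)
        io.MutationTable(mut.data.copy(), mut.cohort_sizes)
        frac, _ = simulate_fractions(n_samples=25, seed=2)
        io.FractionMatrix(frac.values)


class TestCohort:
    def test_param_validation(self):
        with pytest.raises(SimulationError):
            CohortParams(n_tumor=1)
        with pytest.raises(SimulationError):
            CohortParams(censor_rate=1.0)
        with pytest.raises(SimulationError):
            CohortParams(control_set_size=0)

    def test_null_effects_make_groups_indistinguishable(self):
        from scipy.stats import mannwhitneyu

        ps = []
        for seed in range(20):
            p = CohortParams(
                n_genes_background=100,
                n_tumor=25,
                n_normal=25,
                effect_core_log2=0.0,
                effect_control_log2=0.0,
                seed=seed,
            )
            c = simulate_cohort(p)
            pair = GeneSetPair(c.control_genes, c.core_genes)
            crs = compute_crs(c.expr, pair, tissue=c.tissue)
            d = crs.data
            ps.append(
                mannwhitneyu(
                    d.loc[d.tissue == "tumor", "crs"],
                    d.loc[d.tissue == "normal", "crs"],
                    alternative="two-sided",
                ).pvalue
            )
        # under the null, p-values should not pile up near 0
        assert np.mean(np.array(ps) < 0.05) <= 0.25
        assert np.median(ps) > 0.1

    def test_censor_rate_realized(self):
        p = CohortParams(
            n_genes_background=50, n_tumor=400, n_normal=2, censor_rate=0.4, seed=3
        )
        c = simulate_cohort(p)
        frac_censored = 1 - c.clinical.event.mean()
        assert frac_censored == pytest.approx(0.4, abs=0.1)

    def test_cox_recovers_hazard_beta_single_cohort(self):
        p = CohortParams(n_genes_background=50, n_tumor=300, n_normal=2, seed=5)
        c = simulate_cohort(p)
        z = c.true_score.loc[c.clinical.sample_ids].to_numpy()
        res = cox_univariate(z, c.clinical)
        assert res.beta == pytest.approx(p.hazard_beta, abs=3 * res.se)

    def test_zero_hazard_beta_null_logrank(self):
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            p = CohortParams(
                n_genes_background=20,
                n_tumor=40,
                n_normal=2,
                hazard_beta=0.0,
                seed=seed,
            )
            c = simulate_cohort(p)
            z = c.true_score.loc[c.clinical.sample_ids].to_numpy()
            groups = z > np.median(z)
            if logrank_test(c.clinical, groups).p < 0.05:
                rejections += 1
        # ~5% nominal; binomial(100, 0.05) comfortably below 13
        assert rejections <= 13


class TestKnockout:
    def test_factor_one_is_identity(self):
        base = SMALL
        a, _ = simulate_knockout(
            KnockoutParams(("CORE001",), knockdown_factor=1.0, seed=7), base
        )
        b, _ = simulate_knockout(
            KnockoutParams(("CORE002",), knockdown_factor=1.0, seed=7), base
        )
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_full_core_knockout_lowers_core_es_everywhere(self):
        core = tuple(f"CORE{i:03d}" for i in range(1, 36))
        full = CohortParams(n_genes_background=100, seed=9)
        expr, labels = simulate_knockout(
            KnockoutParams(core, n_ko=6, n_ctrl=6, knockdown_factor=0.0, seed=9), full
        )
        es = ssgsea_score(expr, list(core), set_name="core").scores
        assert es[labels == "ko"].max() < es[labels == "ctrl"].min()

    def test_unknown_target_rejected(self):
        with pytest.raises(SimulationError, match="universe"):
            simulate_knockout(KnockoutParams(("NOPE",), seed=1), SMALL)


class TestTimecourse:
    def test_zero_cdt_amplitude_range_near_noise_floor(self):
        tp = TimecourseParams(
            amplitude_normal=1.5, amplitude_cdt=0.0, n_replicates=4, seed=21
        )
        expr, ann = simulate_timecourse(tp, SMALL)
        pair = GeneSetPair(
            tuple(f"CTRL{i:03d}" for i in range(1, 14)),
            tuple(f"CORE{i:03d}" for i in range(1, 36)),
        )
        from crscore.crs_model import rhythm_amplitude

        crs = compute_crs(expr, pair).crs
        df = ann.assign(crs=crs.loc[ann["sample_id"]].to_numpy())
        r = rhythm_amplitude(df)
        assert r["cdt"] < 0.5 * r["normal"]

    def test_single_timepoint_generation_allowed(self):
        tp = TimecourseParams(timepoints_h=(8.0,), seed=1)
        expr, ann = simulate_timecourse(tp, SMALL)
        assert set(ann["timepoint_h"]) == {8.0}

    def test_amplitude_ordering_enforced(self):
        with pytest.raises(SimulationError):
            TimecourseParams(amplitude_normal=0.5, amplitude_cdt=1.0)


class TestGenomics:
    def test_zero_mut_rate_empty_table(self):
        mut, _, _ = simulate_genomics(per_gene_mut_rate=0.0, seed=1)
        assert len(mut.data) == 0

    def test_zero_coupling_uncorrelated(self):
        from crscore.differential_genomics import cnv_expression_correlation

        _, cnv, expr = simulate_genomics(
            n_genes=40, n_samples=500, coupling=0.0, seed=2
        )
        res = cnv_expression_correlation(cnv, expr)
        assert abs(res["rho"].mean()) < 0.05

    def test_strong_coupling_correlated(self):
        from crscore.differential_genomics import cnv_expression_correlation

        # a high event rate is needed for Spearman on the raw focal score to
        # see the coupling: neutral samples contribute independent ranks and
        # dilute rho toward ~(1 - f_neutral^3) even under perfect coupling
        _, cnv, expr = simulate_genomics(
            n_genes=40, n_samples=500, cnv_event_rate=0.5, coupling=3.0, seed=3
        )
        res = cnv_expression_correlation(cnv, expr)
        cat = np.abs(cnv.values.to_numpy()) > 0.3
        enough = pd.Series(cat.sum(axis=1), index=cnv.values.index) >= 10
        rho = res.set_index("gene_id")["rho"]
        assert (rho[enough[rho.index]] > 0.5).all()


class TestCompoundLibrary:
    def test_planted_extremes(self):
        universe = [f"g{i}" for i in range(100)]
        up, down = universe[:5], universe[5:10]
        lib = simulate_compound_library(
            20, universe, planted=[("M", "mimic"), ("R", "revert")],
            up_genes=up, down_genes=down, seed=4
        )
        from crscore.connectivity import QuerySignature, score_library

        raw = score_library(QuerySignature(up, down, 5), lib)
        assert raw.idxmax() == "M" and raw.idxmin() == "R"
        assert raw["M"] == -raw["R"] == raw.max()

    def test_decoys_center_near_zero(self):
        from crscore.connectivity import QuerySignature, scale_scores, score_library

        universe = [f"g{i}" for i in range(200)]
        up, down = universe[:10], universe[10:20]
        lib = simulate_compound_library(
            1000, universe, planted=[("M", "mimic"), ("R", "revert")],
            up_genes=up, down_genes=down, seed=5
        )
        scaled = scale_scores(score_library(QuerySignature(up, down, 10), lib))
        decoys = scaled.drop(["M", "R"])
        assert abs(decoys.median()) < 20


class TestFractions:
    def test_columns_sum_to_one(self):
        frac, _ = simulate_fractions(n_samples=50, seed=6)
        assert np.allclose(frac.values.sum(axis=0), 1.0)

    def test_null_link_uncorrelated(self):
        from crscore.immune_therapy import fraction_crs_correlation

        frac, score = simulate_fractions(n_samples=300, seed=7)
        res = fraction_crs_correlation(frac, score)
        assert abs(res["rho"].mean()) < 0.05
        assert (res["q"] > 0.05).mean() > 0.9

    def test_positive_link_detected(self):
        from crscore.immune_therapy import fraction_crs_correlation

        link = np.zeros(22)
        link[0] = 1.0
        frac, score = simulate_fractions(n_samples=300, crs_link=link, seed=8)
        res = fraction_crs_correlation(frac, score).set_index("feature_id")
        assert res.loc["cell_type_01", "rho"] > 0
        assert res.loc["cell_type_01", "q"] < 0.05
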