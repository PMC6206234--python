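"""Odds-ratio contrasts, logistic regression and the combined analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from snpassoc import (
    COMBINED,
    SimulationConfig,
    adjusted_contrast,
    combined_group_contrast,
    combined_group_counts,
    fit_logistic,
    genotype_contrast,
    pearson_chi2,
    protective_genotype_count,
    simulate_cohort,
    simulate_dose_arrays,
    stratified_contrasts,
    two_by_two_or,
)
from snpassoc.association import StratumSpec, Z_95
from snpassoc.cohort import GenotypeCounts, Subject


class TestTwoByTwo:
    @pytest.mark.parametrize(
        "cells, or_, lo, hi",
        [
            ((118, 150, 355, 279), 0.62, 0.46, 0.82),  # rs110419 het
            ((16, 297, 28, 734), 1.41, 0.75, 2.65),  # rs204938 recessive
            ((163, 150, 483, 279), 0.63, 0.48, 0.82),  # rs110419 dominant
            ((175, 138, 506, 256), 0.64, 0.49, 0.84),  # rs4758051 dominant
        ],
    )
    def test_study_tables(self, cells, or_, lo, hi):
        res = two_by_two_or(*cells)
        assert round(res.or_estimate, 2) == or_
        assert round(res.ci_low, 2) == lo
        assert round(res.ci_high, 2) == hi

    def test_het_p_value(self):
        assert two_by_two_or(118, 150, 355, 279).p_value == pytest.approx(
            0.0011, abs=5e-5
        )

    def test_balanced_table_is_null(self):
        res = two_by_two_or(10, 10, 10, 10)
        assert res.or_estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_ci_reconstructs_from_se(self):
        res = two_by_two_or(118, 150, 355, 279)
        assert res.ci_low == pytest.approx(
            math.exp(math.log(res.or_estimate) - Z_95 * res.se_log_or), rel=1e-9
        )

    @given(st.tuples(*[st.integers(1, 300)] * 4))
    def test_transposed_or_is_reciprocal(self, cells):
        a, b, c, d = cells
        r1 = two_by_two_or(a, b, c, d)
        r2 = two_by_two_or(b, a, d, c)
        assert r1.or_estimate * r2.or_estimate == pytest.approx(1.0, rel=1e-12)

    def test_zero_cell_inestimable_unless_haldane(self):
        res = two_by_two_or(0, 10, 5, 5)
        assert not res.estimable
        res = two_by_two_or(0, 10, 5, 5, haldane=True)
        assert res.estimable and res.or_estimate < 1


class TestPearson:
    def test_genotype_distribution_p(self, study_counts):
        gc = study_counts["rs110419"]
        res = pearson_chi2([gc.case_counts, gc.control_counts])
        assert res.p_value == pytest.approx(0.0026, abs=5e-5)
        assert res.df == 2

    def test_dominant_collapsed_p(self):
        res = pearson_chi2([[163, 150], [483, 279]])
        assert res.p_value == pytest.approx(0.0006, abs=5e-5)

    def test_identical_proportions_null(self):
        res = pearson_chi2([[10, 20, 30], [20, 40, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 10], [0, 20]])


class TestFitLogistic:
    def test_slope_equals_log_odds_ratio(self):
        # grouped 2x2: exposure indicator recovers the cross-product ratio
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        y = [1.0, 1.0, 0.0, 0.0]
        w = [118, 150, 355, 279]
        fit = fit_logistic(X, y, weights=w, names=["exposed"])
        res2 = two_by_two_or(118, 150, 355, 279)
        assert math.exp(fit.coef[1]) == pytest.approx(res2.or_estimate, rel=1e-7)
        assert fit.wald_or("exposed").p_value == pytest.approx(res2.p_value, rel=1e-4)

    def test_intercept_only_recovers_logit(self):
        y = [1.0] * 30 + [0.0] * 70
        fit = fit_logistic(np.zeros((100, 0)), y, add_intercept=True)
        assert fit.coef[0] == pytest.approx(math.log(30 / 70), rel=1e-6)

    def test_grouped_equals_expanded(self):
        X = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]])
        y = [1, 1, 1, 0, 0, 0]
        w = [150, 118, 45, 279, 355, 128]
        grouped = fit_logistic(X, y, weights=w, names=["dose"])
        Xe = np.repeat(X, w, axis=0)
        ye = np.repeat(y, w)
        expanded = fit_logistic(Xe, ye, names=["dose"])
        assert np.allclose(grouped.coef, expanded.coef, atol=1e-9)

    def test_matches_brute_force_likelihood_maximizer(self):
        """Two-parameter grouped toy vs direct likelihood optimization."""
        w = np.array([150.0, 118, 45, 279, 355, 128])
        dose = np.array([0.0, 1, 2, 0, 1, 2])
        y = np.array([1.0, 1, 1, 0, 0, 0])

        def negll(theta):
            eta = theta[0] + theta[1] * dose
            return -np.sum(w * (y * eta - np.log1p(np.exp(eta))))

        oracle = minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12}).x
        fit = fit_logistic(dose[:, None], y, weights=w, names=["dose"])
        assert np.allclose(fit.coef, oracle, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 1)), [1, 1, 1, 1, 1])

    def test_separation_detected(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = [0.0, 0.0, 1.0, 1.0]
        with pytest.raises(ValueError):
            fit_logistic(X, y, weights=[50, 50, 50, 50])


class TestGenotypeContrast:
    def test_additive_model_study_value(self, study_counts):
        res = genotype_contrast(study_counts["rs110419"], "additive")
        assert round(res.or_estimate, 2) == 0.76
        assert round(res.ci_low, 2) == 0.63
        assert round(res.ci_high, 2) == 0.92

    def test_dominant_model_study_value(self, study_counts):
        res = genotype_contrast(study_counts["rs4758051"], "dominant")
        assert round(res.or_estimate, 2) == 0.64
        assert round(res.ci_low, 2) == 0.49
        assert round(res.ci_high, 2) == 0.84

    def test_identical_proportions_all_models_null(self):
        gc = GenotypeCounts("rsX", (10, 20, 10), (20, 40, 20))
        for model in ("het", "hom", "dominant", "recessive", "additive"):
            res = genotype_contrast(gc, model)
            assert res.or_estimate == pytest.approx(1.0, abs=1e-8), model

    def test_genotype_chi2_is_two_df(self, study_counts):
        res = genotype_contrast(study_counts["rs110419"], "genotype_chi2")
        assert res.df == 2


class TestProtectiveScore:
    def _subject(self, doses, panel):
        return Subject("S1", "case", 10, "M", "adrenal",
                       {s.rsid: d for s, d in zip(panel, doses)})

    @pytest.mark.parametrize(
        "doses, expected",
        [((1, 1, 1, 1, 1), 5), ((0, 0, 0, 0, 0), 0), ((1, 0, 0, 0, 0), 1),
         ((2, 2, 2, 2, 2), 5), ((2, 0, 1, 0, 0), 2)],
    )
    def test_scores(self, doses, expected, panel):
        assert protective_genotype_count(self._subject(doses, panel), panel) == expected

    def test_missing_genotype_excluded(self, panel):
        subj = self._subject((1, 1, 1, 1, None), panel)
        assert protective_genotype_count(subj, panel) is None


class TestCombined:
    def test_study_grouping(self):
        res = combined_group_contrast(213, 100, 401, 361)
        assert round(res.or_estimate, 2) == 0.52
        assert round(res.ci_low, 2) == 0.40
        assert round(res.ci_high, 2) == 0.69

    def test_equal_proportions_null(self):
        res = combined_group_contrast(50, 50, 100, 100)
        assert res.or_estimate == pytest.approx(1.0)

    def test_group_counts_match_brute_force(self, medium_cohort):
        cohort, _ = medium_cohort
        cl, ch, tl, th = combined_group_counts(cohort)
        brute = {"case": [0, 0], "control": [0, 0]}
        for s in cohort.subjects:
            score = protective_genotype_count(s, cohort.panel)
            if score is None:
                continue
            brute[s.status][1 if score >= 4 else 0] += 1
        assert [cl, ch] == brute["case"]
        assert [tl, th] == brute["control"]


class TestAdjusted:
    def test_no_covariates_reduces_to_crude(self, medium_cohort):
        cohort, _ = medium_cohort
        from snpassoc import tabulate_genotypes

        crude = genotype_contrast(tabulate_genotypes(cohort, "rs110419"), "dominant")
        adj = adjusted_contrast(cohort, "rs110419", "dominant", covariates=())
        assert adj.or_estimate == pytest.approx(crude.or_estimate, rel=1e-6)
        assert adj.p_value == pytest.approx(crude.p_value, rel=1e-4)

    def test_independent_covariates_barely_move_estimate(self, medium_cohort):
        cohort, _ = medium_cohort
        crude = adjusted_contrast(cohort, "rs110419", "dominant", covariates=())
        adj = adjusted_contrast(cohort, "rs110419", "dominant")
        assert abs(
            math.log(adj.or_estimate) - math.log(crude.or_estimate)
        ) < 0.1

    def test_adjustment_removes_noncollapsibility_bias(self):
        """With a strong age effect on risk, the marginal (crude) dominant
        OR is attenuated toward 1; adjusting for age recovers the
        conditional effect."""
        truth = math.log(0.6)
        crude_est, adj_est = [], []
        for rep in range(150):
            cfg = SimulationConfig(
                n_cases=313, n_controls=762,
                effect_model={"rs2168101": (truth, truth)},
                beta_age=0.04, baseline_logit=-3.2, seed=90_000 + rep,
            )
            arrays = simulate_dose_arrays(cfg)
            rows, ys = [], []
            for grp, yval in (("case", 1.0), ("control", 0.0)):
                dom = (arrays[grp]["doses"][:, 4] >= 1).astype(float)
                age = arrays[grp]["age"]
                for d, a in zip(dom, age):
                    rows.append([d, a])
                    ys.append(yval)
            X = np.array(rows)
            crude_fit = fit_logistic(X[:, :1], ys, names=["dom"])
            adj_fit = fit_logistic(X, ys, names=["dom", "age"])
            crude_est.append(crude_fit.coef[1])
            adj_est.append(adj_fit.coef[1])
        crude_bias = abs(np.mean(crude_est) - truth)
        adj_bias = abs(np.mean(adj_est) - truth)
        assert adj_bias < crude_bias


class TestStratified:
    def test_single_stratum_covering_cohort_equals_unstratified(self, medium_cohort):
        cohort, _ = medium_cohort
        # every simulated age is positive, so >0-months stratification
        # via the sex strata partitions; use an age cut below the minimum
        all_ages = [s.age_months for s in cohort.subjects]
        assert min(all_ages) > 0
        rows = stratified_contrasts(
            cohort, "rs110419", "dominant",
            strata=[StratumSpec("age_months", "gt18"), StratumSpec("age_months", "le18")],
        )
        # recombine check: each stratum result is estimable and the union
        # of members is the cohort
        members = set()
        for spec, _ in rows:
            members |= {s.subject_id for s in spec.members(cohort.subjects)}
        assert members == {s.subject_id for s in cohort.subjects}

    def test_empty_stratum_inestimable_row(self, panel):
        subjects = [
            Subject(f"S{i}", "case" if i % 3 == 0 else "control", 30, "M",
                    "adrenal" if i % 3 == 0 else "NA",
                    {s.rsid: (i + j) % 3 for j, s in enumerate(panel)})
            for i in range(30)
        ]
        from snpassoc.cohort import Cohort

        cohort = Cohort(panel=list(panel), subjects=subjects)
        rows = stratified_contrasts(
            cohort, "rs110419", "dominant",
            strata=[StratumSpec("age_months", "le18")],
        )
        assert len(rows) == 1
        assert not rows[0][1].estimable

    def test_site_strata_use_all_controls(self, medium_cohort):
        cohort, _ = medium_cohort
        spec = StratumSpec("site", "adrenal")
        members = spec.members(cohort.subjects)
        n_controls = sum(1 for s in members if not s.is_case)
        assert n_controls == len(cohort.controls)
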