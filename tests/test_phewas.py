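import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from phemr.grs import GRSVector
from phemr.phenome import CaseControlSet
from phemr.phewas import (
    fdr_threshold,
    fit_logistic,
    or_from_beta,
    run_phewas,
)


def _ccs(case_scores, control_scores):
    n_case, n_ctrl = len(case_scores), len(control_scores)
    cases = [f"c{i}" for i in range(n_case)]
    controls = [f"k{i}" for i in range(n_ctrl)]
    grs = GRSVector(cases + controls,
                    np.concatenate([case_scores, control_scores]), 1)
    return CaseControlSet("t", cases, controls), grs


class TestOrFromBeta:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [
            # printed association-table rows this transform must reproduce
            (0.077, 0.015, (1.08, 1.05, 1.11)),  # essential hypertension
            (1.511, 0.112, (4.53, 3.64, 5.64)),  # gout, IVW
            (0.098, 0.038, (1.10, 1.02, 1.19)),  # coronary heart disease, IVW
            (0.105, 0.041, (1.11, 1.02, 1.20)),  # myocardial infarction, IVW
            (0.031, 0.015, (1.03, 1.00, 1.06)),  # systolic blood pressure, IVW
            (-0.075, 0.026, (0.93, 0.88, 0.98)),  # HDL cholesterol, IVW
            (0.029, 0.052, (1.03, 0.93, 1.14)),  # ischemic stroke, IVW
        ],
    )
    def test_reproduces_printed_or_ci(self, beta, se, expected):
        assert or_from_beta(beta, se) == expected

    def test_null_beta_gives_unit_or(self):
        assert or_from_beta(0.0, 0.5)[0] == 1.00

    def test_exp_log_consistency_at_full_precision(self):
        for x in [0.37, 1.0, 2.718, 5.37]:
            assert np.exp(np.log(x)) == pytest.approx(x, rel=1e-12)
            point, _, _ = or_from_beta(np.log(x), 1.0)
            assert point == round(x, 2)


class TestFitLogistic:
    def test_independence_gives_null_fit(self):
        # balanced 2x2 with identical score distribution in cases and controls
        ccs, grs = _ccs([0.0] * 25 + [1.0] * 25, [0.0] * 25 + [1.0] * 25)
        res = fit_logistic(ccs, grs)
        assert res.converged
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_toy_fit_matches_reference_mle(self):
        # overlapping score distributions, so the MLE exists and is unique
        ccs, grs = _ccs([1.0, 1.0, 2.0, 0.0], [0.0, 0.0, 1.0, 2.0])
        res = fit_logistic(ccs, grs)
        X = sm.add_constant(grs.score)
        ref = sm.GLM(np.r_[1, 1, 1, 1, 0, 0, 0, 0], X,
                     family=sm.families.Binomial()).fit()
        assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert res.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_matches_reference_mle_on_fuzzed_datasets(self, rng):
        checked = 0
        for _ in range(50):
            n = int(rng.integers(40, 120))
            x = rng.normal(size=n)
            eta = rng.normal(-0.5, 0.5) + rng.normal(0, 0.8) * x
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            if y.sum() < 3 or y.sum() > n - 3:
                continue
            ccs, grs = _ccs(x[y], x[~y])
            res = fit_logistic(ccs, grs)
            if not res.converged:
                continue
            ref = sm.GLM(np.r_[np.ones(int(y.sum())), np.zeros(int((~y).sum()))],
                         sm.add_constant(grs.score),
                         family=sm.families.Binomial()).fit()
            assert res.beta == pytest.approx(ref.params[1], abs=1e-6)
            assert res.se == pytest.approx(ref.bse[1], rel=1e-4)
            checked += 1
        assert checked >= 40

    def test_separation_withholds_estimates(self):
        ccs, grs = _ccs([10.0] * 30, [-10.0] * 30)
        res = fit_logistic(ccs, grs)
        assert not res.converged
        assert np.isnan(res.beta)

    def test_positive_liability_effect_recovered(self, default_cohort, default_grs,
                                                 default_phenome,
                                                 screened_covariates):
        res = fit_logistic(default_phenome["274.1"], default_grs,
                           screened_covariates)
        assert res.converged and res.beta > 0
        assert res.p < 1e-6  # strong exposure-driven disease at n=50,000

    def test_null_disease_beta_within_4_se(self, default_grs, default_phenome,
                                           screened_covariates):
        res = fit_logistic(default_phenome["495"], default_grs, screened_covariates)
        assert abs(res.beta) < 4 * res.se


class TestFdrThreshold:
    def test_worked_example(self):
        thr, flags = fdr_threshold([0.001, 0.01, 0.02, 0.8], q=0.05)
        assert thr == pytest.approx(0.02)
        assert flags.sum() == 3

    def test_all_unit_pvalues_no_discoveries(self):
        thr, flags = fdr_threshold([1.0, 1.0, 1.0], q=0.05)
        assert flags.sum() == 0 and thr < 1.0

    def test_single_test_reduces_to_alpha(self):
        _, flags = fdr_threshold([0.04], q=0.05)
        assert flags.sum() == 1

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60)) ** rng.uniform(0.5, 3)
            _, flags = fdr_threshold(p, q=0.05)
            ref, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(flags, ref)

    def test_discoveries_monotone_in_q(self, rng):
        p = rng.uniform(size=40) ** 2
        _, f1 = fdr_threshold(p, q=0.01)
        _, f2 = fdr_threshold(p, q=0.10)
        assert np.all(f2[f1])  # every q=0.01 discovery survives at q=0.10


class TestRunPhewas:
    def test_single_phecode_reduces_to_p_leq_q(self, rng):
        x_cases = rng.normal(0.6, 1, 120)
        x_ctrl = rng.normal(0.0, 1, 400)
        ccs, grs = _ccs(x_cases, x_ctrl)
        rep = run_phewas({"t": ccs}, grs, q=0.05)
        res = rep.results[0]
        assert ("t" in rep.discoveries) == (res.p <= 0.05)

    def test_empty_phenome_is_error(self, default_grs):
        with pytest.raises(ValueError):
            run_phewas({}, default_grs)

    def test_gout_discovered_nulls_not(self, default_grs, default_phenome,
                                       screened_covariates):
        rep = run_phewas(default_phenome, default_grs, screened_covariates)
        assert "274.1" in rep.discoveries
        for null_ph in ["495", "530", "591"]:
            assert null_ph not in rep.discoveries

    def test_permuted_score_controls_discovery_rate(self, default_grs,
                                                    default_phenome,
                                                    screened_covariates, rng):
        # under the permutation null each replicate has <=q probability of
        # any discovery; over a small batch most replicates must be clean
        from phemr.phewas import phenome_positions

        positions = phenome_positions(default_phenome, default_grs.person_ids)
        with_discovery = 0
        for _ in range(20):
            perm = GRSVector(default_grs.person_ids,
                             rng.permutation(default_grs.score), 1)
            rep = run_phewas(default_phenome, perm, screened_covariates,
                             positions=positions)
            with_discovery += bool(rep.discoveries)
        assert with_discovery <= 4
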