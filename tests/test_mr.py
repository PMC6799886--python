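import numpy as np
import pytest
import statsmodels.api as sm

from phemr.io_formats import SummaryStatRecord, ValidationError
from phemr.mr import (
    MRSummarySet,
    egger,
    harmonize_summary_stats,
    ivw,
    mode_based,
    select_estimator,
    wald_ratio,
    weighted_median,
)

from .oracles import meta_analysis_of_ratios


def _set(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return MRSummarySet(
        rsids=[f"rs{i}" for i in range(len(bx))],
        beta_exposure=bx, se_exposure=sx,
        beta_outcome=np.asarray(by, float), se_outcome=np.asarray(sy, float),
    )


def _random_set(rng, m=12, tau=0.2, pleiotropy=0.0):
    bx = rng.uniform(0.05, 0.4, m)
    sy = rng.uniform(0.01, 0.1, m)
    by = tau * bx + pleiotropy + rng.normal(0, sy)
    return _set(bx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(0.5, 0.25, 0.1) == (0.5, 0.2)

    def test_null_outcome_gives_zero_ratio(self):
        assert wald_ratio(0.5, 0.0, 0.1)[0] == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError):
            wald_ratio(0.0, 0.1, 0.1)

    def test_single_variant_ivw_equals_wald(self):
        s = _set([0.5], [0.25], [0.1])
        res = ivw(s)
        assert res.method == "wald_ratio"
        assert (res.beta, res.se) == wald_ratio(0.5, 0.25, 0.1)


class TestIvw:
    def test_consensus_ratio_returned_exactly(self):
        s = _set([0.2, 0.4], [0.1, 0.2], [0.05, 0.08])
        assert ivw(s).beta == pytest.approx(0.5, abs=1e-12)

    def test_equals_meta_analysis_of_wald_ratios(self, rng):
        for _ in range(30):
            s = _random_set(rng, m=int(rng.integers(2, 20)))
            res = ivw(s)
            beta, se = meta_analysis_of_ratios(s.beta_exposure, s.beta_outcome,
                                               s.se_outcome)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_equals_wls_through_origin(self, rng):
        s = _random_set(rng)
        fit = sm.WLS(s.beta_outcome, s.beta_exposure,
                     weights=1 / s.se_outcome**2).fit()
        assert ivw(s).beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_ci_coverage_is_nominal(self, rng):
        # exact SEs, no pleiotropy: the 95% Wald interval must cover ~95%
        tau, m, covered = 0.3, 31, 0
        bx_true = rng.uniform(0.05, 0.4, m)
        sy = rng.uniform(0.02, 0.08, m)
        for _ in range(1000):
            by = tau * bx_true + rng.normal(0, sy)
            res = ivw(_set(bx_true, by, sy))
            lo, hi = res.beta - 1.96 * res.se, res.beta + 1.96 * res.se
            covered += lo <= tau <= hi
        assert 930 <= covered <= 970

    def test_order_and_sign_flip_invariance(self, rng):
        s = _random_set(rng)
        perm = rng.permutation(s.n_snps)
        s2 = _set(s.beta_exposure[perm], s.beta_outcome[perm], s.se_outcome[perm])
        assert ivw(s).beta == pytest.approx(ivw(s2).beta, abs=1e-12)
        flip = np.where(rng.random(s.n_snps) < 0.5, -1.0, 1.0)
        s3 = _set(s.beta_exposure * flip, s.beta_outcome * flip, s.se_outcome)
        assert ivw(s).beta == pytest.approx(ivw(s3).beta, abs=1e-12)


class TestEgger:
    def test_directional_pleiotropy_recovered_in_intercept(self, rng):
        delta = 0.05
        s = _random_set(rng, m=25, tau=0.2, pleiotropy=delta)
        res = egger(s)
        intercept = float(res.note.split("=")[1])
        # recover the simulated intercept within 2 SE-ish of the slope scale
        assert intercept == pytest.approx(delta, abs=0.04)

    def test_zero_constrained_intercept_reproduces_ivw(self, rng):
        s = _random_set(rng)
        fit = sm.WLS(s.beta_outcome, s.beta_exposure,
                     weights=1 / s.se_outcome**2).fit()
        assert float(fit.params[0]) == pytest.approx(ivw(s).beta, abs=1e-10)

    def test_equal_exposure_effects_not_identifiable(self):
        s = _set([0.2, 0.2, 0.2], [0.1, 0.12, 0.08], [0.05, 0.05, 0.05])
        assert not egger(s).applicable

    def test_fewer_than_three_variants_not_applicable(self):
        s = _set([0.2, 0.3], [0.1, 0.12], [0.05, 0.05])
        assert not egger(s).applicable

    def test_sign_flip_invariance_after_orientation(self, rng):
        s = _random_set(rng)
        flip = np.where(rng.random(s.n_snps) < 0.5, -1.0, 1.0)
        s2 = _set(s.beta_exposure * flip, s.beta_outcome * flip, s.se_outcome)
        assert egger(s).beta == pytest.approx(egger(s2).beta, abs=1e-12)
        assert egger(s).p_pleiotropy == pytest.approx(egger(s2).p_pleiotropy,
                                                      abs=1e-12)


class TestMedianAndMode:
    def test_equal_weight_median(self):
        s = _set([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert weighted_median(s, n_boot=10).beta == pytest.approx(2.0)

    def test_median_resists_forty_percent_outliers(self, rng):
        tau = 0.3
        bx = rng.uniform(0.1, 0.4, 20)
        sy = np.full(20, 0.01)
        by = tau * bx
        by[:8] += 0.5  # 40% of variants carry a large pleiotropic offset
        res = weighted_median(_set(bx, by, sy), n_boot=100, seed=1)
        assert abs(res.beta - tau) < 0.05

    def test_mode_of_identical_ratios(self):
        s = _set([0.2, 0.25, 0.5], [0.2 * 0.7, 0.25 * 0.7, 0.5 * 0.7],
                 [0.02, 0.02, 0.02])
        assert mode_based(s, n_boot=10).beta == pytest.approx(0.7, abs=0.01)

    def test_mode_finds_heavier_cluster(self, rng):
        tau = 0.3
        bx = rng.uniform(0.1, 0.4, 30)
        sy = np.full(30, 0.005)
        by = tau * bx
        by[:10] += 0.3  # lighter, biased cluster
        res = mode_based(_set(bx, by, sy), n_boot=50, seed=2)
        assert abs(res.beta - tau) < 0.05

    def test_order_invariance(self, rng):
        s = _random_set(rng)
        perm = rng.permutation(s.n_snps)
        s2 = _set(s.beta_exposure[perm], s.beta_outcome[perm], s.se_outcome[perm])
        assert weighted_median(s, n_boot=50, seed=3).beta == pytest.approx(
            weighted_median(s2, n_boot=50, seed=3).beta, abs=1e-9
        )
        assert mode_based(s, n_boot=10, seed=3).beta == pytest.approx(
            mode_based(s2, n_boot=10, seed=3).beta, abs=1e-9
        )


class TestSelection:
    def test_single_variant_selects_wald(self):
        res = select_estimator(_set([0.5], [0.25], [0.1]))
        assert res.method == "wald_ratio"

    def test_clean_set_selects_ivw(self, rng):
        s = _random_set(np.random.default_rng(5), m=20, tau=0.25)
        res = select_estimator(s, n_boot=50)
        assert res.method == "ivw"

    def test_directional_pleiotropy_triggers_mode(self):
        rng = np.random.default_rng(12)
        triggered = 0
        for _ in range(20):
            s = _random_set(rng, m=31, tau=0.0, pleiotropy=0.08)
            if select_estimator(s, n_boot=20).method == "mode_based":
                triggered += 1
        assert triggered >= 18  # >=90% of replicates


class TestHarmonization:
    def test_swapped_outcome_alleles_flip_outcome_beta(self):
        exp = [SummaryStatRecord("rs1", "A", "G", 0.2, 0.02, "urate", 0.3)]
        out = [SummaryStatRecord("rs1", "G", "A", -0.1, 0.05, "chd", 0.7)]
        s = harmonize_summary_stats(exp, out)
        assert s.beta_outcome[0] == pytest.approx(0.1)

    def test_palindromic_ambiguous_dropped(self):
        exp = [SummaryStatRecord("rs1", "A", "T", 0.2, 0.02, "urate", 0.5)]
        out = [SummaryStatRecord("rs1", "A", "T", 0.1, 0.05, "chd", 0.5),
               SummaryStatRecord("rs2", "A", "G", 0.1, 0.05, "chd", 0.3)]
        exp.append(SummaryStatRecord("rs2", "A", "G", 0.3, 0.02, "urate", 0.3))
        s = harmonize_summary_stats(exp, out)
        assert s.rsids == ["rs2"]
        assert ("rs1", "palindromic-ambiguous") in s.dropped

    def test_orientation_to_exposure_increasing_allele(self):
        exp = [SummaryStatRecord("rs1", "A", "G", -0.2, 0.02, "urate", 0.3)]
        out = [SummaryStatRecord("rs1", "A", "G", 0.1, 0.05, "chd", 0.3)]
        s = harmonize_summary_stats(exp, out)
        assert s.beta_exposure[0] == pytest.approx(0.2)
        assert s.beta_outcome[0] == pytest.approx(-0.1)
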