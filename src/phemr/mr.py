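"""Two-sample mendelian randomization estimators and diagnostics.

Given harmonized per-variant exposure and outcome effects, this module
provides the Wald ratio, fixed-effect inverse-variance-weighted (IVW)
estimator with Cochran's Q heterogeneity statistic, MR-Egger regression
with its directional-pleiotropy intercept test, the weighted-median and
kernel-mode estimators (bootstrap SEs), and a transparent, deterministic
rule ladder that picks the estimator most robust to the diagnosed
pleiotropy pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grs import harmonize
from .io_formats import SummaryStatRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MRSummarySet:
    """Per-variant exposure/outcome effects on a common effect allele."""

    rsids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure: str = "exposure"
    outcome: str = "outcome"
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_snps < 1:
            raise ValidationError("summary set needs at least one variant")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValidationError("all SEs must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def oriented(self) -> "MRSummarySet":
        """Flip variants so every exposure effect is non-negative
        (orientation to the exposure-increasing allele)."""
        sign = np.where(self.beta_exposure < 0, -1.0, 1.0)
        return replace(
            self,
            beta_exposure=self.beta_exposure * sign,
            beta_outcome=self.beta_outcome * sign,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rsid": self.rsids,
             "beta_exposure": self.beta_exposure, "se_exposure": self.se_exposure,
             "beta_outcome": self.beta_outcome, "se_outcome": self.se_outcome}
        )


def harmonize_summary_stats(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
) -> MRSummarySet:
    """Pair exposure and outcome records on shared variants.

    Allele alignment (swaps, strand flips, palindromic frequency rule)
    reuses the risk-score harmonization logic, treating the exposure side
    as the reference orientation.
    """
    out_by_rsid = {r.rsid: r for r in outcome}
    genotype_like = [
        (r.rsid, r.effect_allele, r.other_allele, r.eaf if r.eaf is not None else np.nan)
        for r in outcome
    ]
    weights_like = [
        # reuse the VariantWeight-based aligner on the exposure records
        _as_weight(r) for r in exposure
    ]
    aligned = harmonize(weights_like, genotype_like)
    rsids, bx, sx, by, sy = [], [], [], [], []
    for a in aligned:
        e = next(r for r in exposure if r.rsid == a.rsid)
        o = out_by_rsid[a.rsid]
        sign = -1.0 if a.flip else 1.0
        rsids.append(a.rsid)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(sign * o.beta)
        sy.append(o.se)
    return MRSummarySet(
        rsids=rsids,
        beta_exposure=np.array(bx), se_exposure=np.array(sx),
        beta_outcome=np.array(by), se_outcome=np.array(sy),
        exposure=exposure[0].trait if exposure else "exposure",
        outcome=outcome[0].trait if outcome else "outcome",
        dropped=list(getattr(aligned, "dropped", [])),
    ).oriented()


def _as_weight(r: SummaryStatRecord):
    from .io_formats import VariantWeight

    return VariantWeight(r.rsid, r.effect_allele, r.other_allele, r.beta, r.se,
                         r.eaf if r.eaf is not None else 0.5)


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    p_effect: float
    n_snps: int
    p_pleiotropy: Optional[float] = None  # Egger intercept test
    q_stat: Optional[float] = None
    q_p: Optional[float] = None
    applicable: bool = True
    note: str = ""

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return float(np.exp(self.beta - 1.96 * self.se)), float(np.exp(self.beta + 1.96 * self.se))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def wald_ratio(beta_exposure: float, beta_outcome: float, se_outcome: float
               ) -> tuple[float, float]:
    """Single-variant causal estimate β_Y/β_X with first-order SE."""
    if beta_exposure == 0:
        raise ValidationError("Wald ratio undefined for a null exposure effect")
    return beta_outcome / beta_exposure, se_outcome / abs(beta_exposure)


def _ratios(s: MRSummarySet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    keep = s.beta_exposure != 0
    if not np.all(keep):
        logger.info("excluding %d variant(s) with zero exposure effect",
                    int((~keep).sum()))
    bx, by, sy = s.beta_exposure[keep], s.beta_outcome[keep], s.se_outcome[keep]
    return by / bx, sy / np.abs(bx), [r for r, k in zip(s.rsids, keep) if k]


def ivw(s: MRSummarySet) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    beta = Σ(β_X β_Y/se_Y²)/Σ(β_X²/se_Y²), se = 1/√Σ(β_X²/se_Y²); this is
    identical to the 1/se_ratio²-weighted mean of the Wald ratios and to
    weighted least squares of β_Y on β_X through the origin.  Cochran's Q
    against the pooled estimate is attached.
    """
    keep = s.beta_exposure != 0
    bx, by, sy = s.beta_exposure[keep], s.beta_outcome[keep], s.se_outcome[keep]
    if bx.size == 0:
        raise ValidationError("no usable variants for IVW")
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    if bx.size == 1:
        b1, se1 = wald_ratio(bx[0], by[0], sy[0])
        return MRResult("wald_ratio", b1, se1,
                        float(2.0 * stats.norm.sf(abs(b1 / se1))), 1)
    ratios = by / bx
    q = float(np.sum(w * (ratios - beta) ** 2))
    q_p = float(stats.chi2.sf(q, bx.size - 1))
    return MRResult("ivw", beta, se, p, int(bx.size), q_stat=q, q_p=q_p)


def egger(s: MRSummarySet) -> MRResult:
    """MR-Egger: weighted regression of β_Y on β_X with a free intercept.

    The slope is the pleiotropy-adjusted causal estimate; the intercept's
    two-sided p (t-test with estimated dispersion, the usual Egger
    convention) is the directional-pleiotropy test.  Variants are
    oriented to the exposure-increasing allele first, which makes the fit
    invariant to per-variant sign flips.
    """
    if s.n_snps < 3:
        return MRResult("egger", np.nan, np.nan, np.nan, s.n_snps,
                        applicable=False, note="needs >=3 variants")
    o = s.oriented()
    bx, by, sy = o.beta_exposure, o.beta_outcome, o.se_outcome
    if np.ptp(bx) == 0:
        return MRResult("egger", np.nan, np.nan, np.nan, s.n_snps,
                        applicable=False, note="rank-deficient: all exposure effects equal")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    return MRResult(
        "egger",
        beta=float(fit.params[1]), se=float(fit.bse[1]),
        p_effect=float(fit.pvalues[1]), n_snps=s.n_snps,
        p_pleiotropy=float(fit.pvalues[0]),
        note=f"intercept={fit.params[0]:.6g}",
    )


def weighted_median(
    s: MRSummarySet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median of the Wald ratios (50% breakdown point).

    Weights are 1/se_ratio²; the estimate interpolates the weighted
    empirical CDF at one half.  The SE comes from a seeded parametric
    bootstrap of both effect vectors.
    """
    if s.n_snps < 3:
        return MRResult("weighted_median", np.nan, np.nan, np.nan, s.n_snps,
                        applicable=False, note="needs >=3 variants")
    beta = _weighted_median_point(s)
    rng = np.random.default_rng(seed)
    draws = _bootstrap(s, _weighted_median_point, n_boot, rng)
    se = float(np.std(draws, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MRResult("weighted_median", beta, se, p, s.n_snps)


def _weighted_median_point(s: MRSummarySet) -> float:
    ratios, se_ratios, _ = _ratios(s)
    w = 1.0 / se_ratios**2
    order = np.argsort(ratios)
    r, w = ratios[order], w[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def mode_based(
    s: MRSummarySet, bandwidth_factor: float = 1.0,
    n_boot: int = 1000, seed: int = 0,
) -> MRResult:
    """Kernel-density mode of the Wald ratios.

    Gaussian kernel with a Silverman-style bandwidth scaled by
    ``bandwidth_factor``; density weights are 1/se_ratio².  SE by seeded
    parametric bootstrap.
    """
    if s.n_snps < 3:
        return MRResult("mode_based", np.nan, np.nan, np.nan, s.n_snps,
                        applicable=False, note="needs >=3 variants")
    point = _mode_point(s, bandwidth_factor)
    rng = np.random.default_rng(seed)
    draws = _bootstrap(s, lambda x: _mode_point(x, bandwidth_factor), n_boot, rng)
    se = float(np.std(draws, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(point / se)))
    return MRResult("mode_based", point, se, p, s.n_snps)


def _mode_point(s: MRSummarySet, bandwidth_factor: float) -> float:
    ratios, se_ratios, _ = _ratios(s)
    w = 1.0 / se_ratios**2
    w = w / w.sum()
    m = ratios.size
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * max(spread, 1e-12) * m ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[int(np.argmax(dens))])


def _bootstrap(s: MRSummarySet, statistic, n_boot: int, rng: np.random.Generator
               ) -> np.ndarray:
    out = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(s.beta_exposure, s.se_exposure)
        by = rng.normal(s.beta_outcome, s.se_outcome)
        bx = np.where(bx == 0, 1e-12, bx)
        out[b] = statistic(replace(s, beta_exposure=bx, beta_outcome=by))
    return out


def select_estimator(
    s: MRSummarySet,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Deterministic estimator selection.

    Rule ladder: one variant → Wald ratio; a significant Egger intercept
    (directional pleiotropy) → kernel-mode estimator; otherwise
    significant heterogeneity (Cochran's Q) → weighted median; otherwise
    IVW.  The triggering rule is recorded in ``note``.
    """
    crude = ivw(s)
    if s.n_snps == 1:
        crude.note = "rule: single variant -> wald_ratio"
        return crude
    eg = egger(s)
    if eg.applicable and eg.p_pleiotropy is not None and eg.p_pleiotropy < alpha:
        chosen = mode_based(s, n_boot=n_boot, seed=seed)
        chosen.p_pleiotropy = eg.p_pleiotropy
        chosen.note = f"rule: Egger intercept p={eg.p_pleiotropy:.3g} < {alpha} -> mode_based"
        return chosen
    if crude.q_p is not None and crude.q_p < alpha:
        chosen = weighted_median(s, n_boot=n_boot, seed=seed)
        if eg.applicable:
            chosen.p_pleiotropy = eg.p_pleiotropy
        chosen.note = f"rule: heterogeneity Q p={crude.q_p:.3g} < {alpha} -> weighted_median"
        return chosen
    if eg.applicable:
        crude.p_pleiotropy = eg.p_pleiotropy
    crude.note = "rule: no pleiotropy or heterogeneity detected -> ivw"
    return crude


def results_frame(results: Sequence[MRResult]) -> pd.DataFrame:
    """Report table in the standard layout: beta, SE, OR (95% CI), p-values."""
    from .phewas import or_from_beta

    rows = []
    for r in results:
        if r.applicable and np.isfinite(r.beta):
            point, lo, hi = or_from_beta(r.beta, r.se)
            or_str = f"{point:.2f} ({lo:.2f}-{hi:.2f})"
        else:
            or_str = "NA"
        rows.append(
            {"method": r.method, "n_snps": r.n_snps, "beta": r.beta, "se": r.se,
             "or_95ci": or_str, "p_effect": r.p_effect,
             "p_pleiotropy": r.p_pleiotropy, "q_stat": r.q_stat, "q_p": r.q_p,
             "note": r.note}
        )
    return pd.DataFrame(rows)
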