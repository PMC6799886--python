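"""Per-phenotype logistic association scan with FDR control.

Each phecode's case/control status is regressed on the risk score plus
screened covariates by maximum-likelihood logistic regression (iteratively
reweighted least squares).  Wald standard errors come from the observed
information; two-sided normal p-values feed a Benjamini–Hochberg step-up
over the converged fits.  The odds-ratio/CI transform used in all report
tables lives here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grs import GRSVector
from .phenome import CaseControlSet

logger = logging.getLogger(__name__)

DEVIANCE_TOL = 1e-8
MAX_ITER = 25


@dataclass
class AssociationResult:
    """One phenotype's logistic fit: log-odds per unit of score."""

    phenotype: str
    n_cases: int
    n_controls: int
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    converged: bool = False

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return float(np.exp(self.beta - 1.96 * self.se)), float(np.exp(self.beta + 1.96 * self.se))


@dataclass
class PhewasReport:
    results: list[AssociationResult]
    fdr_q: float
    significance_threshold: float
    discoveries: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            lo, hi = r.ci if r.converged else (np.nan, np.nan)
            rows.append(
                {"phenotype": r.phenotype, "n_cases": r.n_cases, "n_controls": r.n_controls,
                 "beta": r.beta, "se": r.se,
                 "or": r.or_point if r.converged else np.nan,
                 "ci_low": lo, "ci_high": hi, "p": r.p, "converged": r.converged,
                 "discovery": r.phenotype in self.discoveries}
            )
        return pd.DataFrame(rows)


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """exp(beta) and the 95% Wald interval, rounded to 2 decimals for display.

    Full precision is retained internally everywhere; this is the
    report-display transform (OR and CI as printed in association tables).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    point = np.exp(beta)
    lo = np.exp(beta - 1.96 * se)
    hi = np.exp(beta + 1.96 * se)
    return round(float(point), 2), round(float(lo), 2), round(float(hi), 2)


# ---------------------------------------------------------------------------
# logistic regression by IRLS
# ---------------------------------------------------------------------------


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit.

    Newton/IRLS iterations until the deviance changes by less than
    ``DEVIANCE_TOL`` or ``MAX_ITER`` iterations; returns (beta, cov,
    converged).  Quasi-separation is reported as non-convergence.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
    beta[0] = np.log(ybar / (1 - ybar))  # column 0 is the intercept
    dev_old = np.inf
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        if abs(dev_old - dev) < DEVIANCE_TOL:
            converged = True
            break
        dev_old = dev
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if converged and (np.max(np.abs(eta)) >= 29.0 or np.max(np.abs(y - mu)) < 1e-4):
        converged = False  # log-odds at the clip boundary or perfect prediction
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return beta, cov, converged


def _design(
    grs_values: np.ndarray, covariates: Optional[pd.DataFrame]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + score + covariates; categorical columns dummy-coded,
    constant columns dropped."""
    cols = [np.ones_like(grs_values), grs_values]
    names = ["intercept", "grs"]
    if covariates is not None and covariates.shape[1]:
        enc = pd.get_dummies(covariates, columns=[
            c for c in covariates.columns
            if not pd.api.types.is_float_dtype(covariates[c])
            and covariates[c].nunique() <= 10
        ], drop_first=True)
        for c in enc.columns:
            v = enc[c].to_numpy(dtype=float)
            if np.std(v) == 0:
                logger.warning("dropping constant covariate column %s", c)
                continue
            cols.append(v)
            names.append(str(c))
    return np.column_stack(cols), names


def fit_logistic(
    case_control: CaseControlSet,
    grs: GRSVector,
    covariates: Optional[pd.DataFrame] = None,
) -> AssociationResult:
    """Logistic regression of case status on the score with covariates.

    On separation or non-convergence the estimates are withheld
    (``converged=False``) but the phenotype is still reported.
    """
    score = grs.as_series()
    ids = list(case_control.case_ids) + list(case_control.control_ids)
    y = np.zeros(len(ids))
    y[: case_control.n_cases] = 1.0
    x = score.loc[ids].to_numpy()
    cov = covariates.loc[ids] if covariates is not None else None
    X, _ = _design(x, cov)
    beta, vcov, converged = _irls(X, y)
    res = AssociationResult(
        phenotype=case_control.phecode,
        n_cases=case_control.n_cases,
        n_controls=case_control.n_controls,
        converged=converged,
    )
    if converged:
        res.beta = float(beta[1])
        res.se = float(np.sqrt(vcov[1, 1]))
        z = res.beta / res.se
        res.p = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    return res


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def fdr_threshold(p_values: Sequence[float], q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini–Hochberg step-up.

    Returns (threshold, flags): the threshold is the largest p among the
    discoveries, i.e. p(k) for the largest k with p(k) ≤ k·q/m; with no
    discoveries it sits below the smallest p and the flag set is empty.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = np.nonzero(ranked <= (np.arange(1, m + 1) * q / m))[0]
    if passing.size == 0:
        return float(np.nextafter(ranked[0], 0) / 2), np.zeros(m, dtype=bool)
    k = passing[-1]
    threshold = float(ranked[k])
    return threshold, p <= threshold


def phenome_positions(
    phenome: Mapping[str, CaseControlSet], person_ids: Sequence[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Integer row positions of each phecode's cases/controls.

    Computing these once lets many score vectors (e.g. the stratified-GRS
    sensitivity scan) reuse the same phenome without re-hashing ids.
    """
    idx = pd.Index(person_ids)
    return {
        ph: (idx.get_indexer(ccs.case_ids), idx.get_indexer(ccs.control_ids))
        for ph, ccs in phenome.items()
    }


def run_phewas(
    phenome: Mapping[str, CaseControlSet],
    grs: GRSVector,
    covariates: Optional[pd.DataFrame] = None,
    q: float = 0.05,
    positions: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None,
) -> PhewasReport:
    """One logistic fit per eligible phecode, then FDR over converged fits.

    Non-converged fits are excluded from the Benjamini–Hochberg family
    (they carry no valid p-value) but remain listed in the report.
    """
    if not phenome:
        raise ValueError("phenome contains no eligible phecodes")
    if positions is None:
        positions = phenome_positions(phenome, grs.person_ids)
    cov = covariates.loc[grs.person_ids] if covariates is not None else None
    Xfull, _ = _design(grs.score, cov)
    results = []
    for ph, ccs in phenome.items():
        case_pos, ctrl_pos = positions[ph]
        pos = np.concatenate([case_pos, ctrl_pos])
        y = np.zeros(pos.size)
        y[: case_pos.size] = 1.0
        beta, vcov, converged = _irls(Xfull[pos], y)
        res = AssociationResult(
            phenotype=ph, n_cases=ccs.n_cases, n_controls=ccs.n_controls,
            converged=converged,
        )
        if converged:
            res.beta = float(beta[1])
            res.se = float(np.sqrt(vcov[1, 1]))
            res.p = float(max(2.0 * stats.norm.sf(abs(res.beta / res.se)),
                              np.nextafter(0, 1)))
        results.append(res)
    fitted = [r for r in results if r.converged]
    if len(fitted) < len(results):
        logger.warning("%d phenotype fit(s) did not converge", len(results) - len(fitted))
    threshold, flags = fdr_threshold([r.p for r in fitted], q)
    discoveries = [r.phenotype for r, f in zip(fitted, flags) if f]
    return PhewasReport(
        results=results,
        fdr_q=q,
        significance_threshold=threshold,
        discoveries=discoveries,
    )
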