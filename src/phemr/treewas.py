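"""Tree-structured Bayesian association scan over the ICD-10 hierarchy.

A discretized genetic coefficient evolves down the classification tree
under a Markov process: the root draws from a spike-and-slab prior (zero
with probability 1−π, otherwise uniform over the nonzero grid), and each
child copies its parent's state with probability 1−θ or redraws from the
root prior.  Per-node logistic summaries (b_hat, se_hat) enter as a
Gaussian working likelihood attached at the leaves; exact per-node
marginal posteriors are computed by upward/downward sum-product passes in
log space.  The prior is stationary along any path, so with flat
likelihoods every node's marginal probability of a nonzero state equals π.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .grs import GRSVector
from .phenome import CaseControlSet, PhenoTree
from .phewas import _design, _irls

logger = logging.getLogger(__name__)


@dataclass
class CoefficientGrid:
    """Discrete support for the genetic coefficient.

    ``values`` must be strictly increasing and contain exactly one zero;
    ``prior_nonzero`` is π, the prior probability of a nonzero root state;
    ``stay_prob`` is 1−θ, the probability a child copies its parent.
    """

    values: np.ndarray
    prior_nonzero: float = 0.001
    stay_prob: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("grid values must be strictly increasing")
        if np.count_nonzero(self.values == 0.0) != 1:
            raise ValueError("grid must contain exactly one zero")
        if not (0.0 < self.prior_nonzero < 1.0 and 0.0 < self.stay_prob < 1.0):
            raise ValueError("prior_nonzero and stay_prob must lie in (0,1)")

    @property
    def theta(self) -> float:
        return 1.0 - self.stay_prob

    @property
    def zero_index(self) -> int:
        return int(np.nonzero(self.values == 0.0)[0][0])

    def log_prior(self) -> np.ndarray:
        k = self.values.size
        prior = np.full(k, self.prior_nonzero / (k - 1))
        prior[self.zero_index] = 1.0 - self.prior_nonzero
        return np.log(prior)


def default_grid(
    summaries: Mapping[str, "NodeSummary"],
    leaves: Sequence[str],
    n_nonzero: int = 20,
    prior_nonzero: float = 0.001,
    stay_prob: float = 2.0 / 3.0,
) -> CoefficientGrid:
    """Zero plus ``n_nonzero`` points spanning ±4·(median leaf SE·√n_leaves)."""
    ses = [summaries[v].se_hat for v in leaves
           if v in summaries and summaries[v].informative]
    if not ses:
        half_width = 1.0
    else:
        half_width = 4.0 * float(np.median(ses)) * np.sqrt(len(leaves))
    values = half_width * np.linspace(-1.0, 1.0, n_nonzero + 1)
    values[n_nonzero // 2] = 0.0
    return CoefficientGrid(values, prior_nonzero, stay_prob)


@dataclass
class NodeSummary:
    """Gaussian working likelihood for one node: b_hat ~ N(b, se_hat²)."""

    node: str
    n_cases: int
    b_hat: float = np.nan
    se_hat: float = np.nan
    informative: bool = False


@dataclass
class TreewasResult:
    node: str
    pp_nonzero: float
    map_estimate: float
    ci_low: float
    ci_high: float
    n_cases: int = 0


def node_summaries(
    tree: PhenoTree,
    grs: GRSVector,
    covariates: Optional[pd.DataFrame] = None,
    min_cases: int = 20,
) -> dict[str, NodeSummary]:
    """Per-node logistic summary of the score effect (cases vs all others).

    Nodes with fewer than ``min_cases`` cases, or whose fit does not
    converge, receive an uninformative (flat-likelihood) summary.
    """
    if not tree.indicators:
        raise ValueError("tree carries no case indicators; run propagate_cases first")
    cov = covariates.loc[tree.person_ids] if covariates is not None else None
    idx = pd.Index(tree.person_ids)
    score = grs.as_series().loc[idx].to_numpy()
    Xfull, _ = _design(score, cov)
    out: dict[str, NodeSummary] = {}
    for node in tree.graph.nodes:
        y = tree.indicators[node].astype(float)
        n_cases = int(y.sum())
        summary = NodeSummary(node, n_cases)
        if min_cases <= n_cases <= len(y) - min_cases:
            beta, vcov, converged = _irls(Xfull, y)
            if converged and np.isfinite(vcov[1, 1]) and vcov[1, 1] > 0:
                summary.b_hat = float(beta[1])
                summary.se_hat = float(np.sqrt(vcov[1, 1]))
                summary.informative = True
        out[node] = summary
    return out


# ---------------------------------------------------------------------------
# exact marginals by sum-product
# ---------------------------------------------------------------------------


def _log_transition(grid: CoefficientGrid) -> np.ndarray:
    """log T[s, s'] = log P(child=s' | parent=s)."""
    k = grid.values.size
    prior = np.exp(grid.log_prior())
    T = grid.stay_prob * np.eye(k) + grid.theta * np.tile(prior, (k, 1))
    return np.log(T)


def tree_posteriors(
    tree: PhenoTree,
    summaries: Mapping[str, NodeSummary],
    grid: CoefficientGrid,
    leaves_only: bool = True,
) -> dict[str, TreewasResult]:
    """Exact per-node marginal posteriors of the coefficient state.

    The Gaussian working likelihood attaches at leaf nodes only (internal
    case sets are unions of their descendants; attaching evidence there
    would count persons twice).  Upward (collect) and downward
    (distribute) sum-product passes run in log space.

    ``pp_nonzero`` is 1 − P(state = 0 | data); ``map_estimate`` is the
    posterior mode over the nonzero states (the effect-size estimate,
    conditional on association — the zero state's evidence is already
    summarized by ``pp_nonzero``); the credible interval is the central
    95% of the renormalized nonzero posterior mass.
    """
    g = tree.graph
    if not nx.is_arborescence(g):
        raise ValueError("input is not a rooted tree")
    k = grid.values.size
    log_prior = grid.log_prior()
    logT = _log_transition(grid)

    attach = (set(n for n in g.nodes if g.out_degree(n) == 0)
              if leaves_only else set(g.nodes))
    log_lik: dict[str, np.ndarray] = {}
    for node in g.nodes:
        s = summaries.get(node)
        if node in attach and s is not None and s.informative:
            log_lik[node] = norm.logpdf(s.b_hat, loc=grid.values, scale=s.se_hat)
        else:
            log_lik[node] = np.zeros(k)

    order = list(nx.topological_sort(g))
    # upward pass: U_v(s) = L_v(s) · Π_c Σ_{s'} T(s'|s) U_c(s')
    log_up: dict[str, np.ndarray] = {}
    log_msg_up: dict[str, np.ndarray] = {}  # child -> message to its parent
    for node in reversed(order):
        u = log_lik[node].copy()
        for child in g.successors(node):
            u = u + log_msg_up[child]
        u -= u.max()
        log_up[node] = u
        log_msg_up[node] = logsumexp(logT + u[None, :], axis=1)

    # downward pass: D_root = prior; D_c(s') = Σ_s T(s'|s)·D_v(s)·U_v(s)/M_c(s)
    root = order[0]
    log_down: dict[str, np.ndarray] = {root: log_prior}
    results: dict[str, TreewasResult] = {}
    for node in order:
        post = log_down[node] + log_up[node]
        post -= logsumexp(post)
        results[node] = _summarize(node, np.exp(post), grid,
                                   summaries.get(node))
        for child in g.successors(node):
            w = log_down[node] + log_up[node] - log_msg_up[child]
            log_down[child] = logsumexp(logT + w[:, None], axis=0)
            log_down[child] -= log_down[child].max()
    return results


def _summarize(
    node: str, post: np.ndarray, grid: CoefficientGrid,
    summary: Optional[NodeSummary],
) -> TreewasResult:
    z = grid.zero_index
    pp = float(1.0 - post[z])
    nonzero = np.delete(post, z)
    values = np.delete(grid.values, z)
    mass = nonzero / max(nonzero.sum(), 1e-300)
    cum = np.cumsum(mass)
    lo = float(values[np.searchsorted(cum, 0.025)])
    hi = float(values[np.searchsorted(cum, 0.975)])
    map_est = float(values[int(np.argmax(mass))])
    return TreewasResult(
        node=node, pp_nonzero=pp, map_estimate=map_est,
        ci_low=lo, ci_high=hi,
        n_cases=summary.n_cases if summary is not None else 0,
    )


def report_associated(
    tree: PhenoTree,
    results: Mapping[str, TreewasResult],
    pp_threshold: float = 0.95,
) -> list[TreewasResult]:
    """Nodes with posterior probability of association ≥ the threshold,
    in depth-first tree order."""
    order = list(nx.dfs_preorder_nodes(tree.graph, tree.root))
    return [results[n] for n in order if n in results
            and results[n].pp_nonzero >= pp_threshold]


def results_frame(results: Mapping[str, TreewasResult]) -> pd.DataFrame:
    rows = [
        {"node": r.node, "n_cases": r.n_cases, "pp_nonzero": r.pp_nonzero,
         "map_estimate": r.map_estimate, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in results.values()
    ]
    return pd.DataFrame(rows)
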