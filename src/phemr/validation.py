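"""Calibration experiments and independent brute-force validators.

These routines re-derive the package's statistical guarantees from
scratch: exhaustive-enumeration tree marginals (checking the sum-product
implementation), the meta-analytic IVW identity, estimator type-I error
and coverage under simulation, the family-wise discovery rate of the FDR
step under a permutation null, and the pleiotropy-dissection recovery
rates on the packaged synthetic cohort.  The brute-force validators
deliberately share no code with the implementations they check.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np

from . import grs as grs_mod
from . import mr as mr_mod
from . import phenome as phenome_mod
from . import phewas as phewas_mod
from . import pleiotropy as pleio_mod
from . import synthetic
from . import treewas as treewas_mod

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def enumerate_tree_marginals(graph, summaries, grid):
    """Exact per-node state marginals by summing every joint assignment.

    Vectorized over the full state product; only usable for small trees
    (the intended role: validating the message-passing marginals).
    """
    from scipy.stats import norm

    nodes = list(nx.topological_sort(graph))
    idx = {n: i for i, n in enumerate(nodes)}
    k = grid.values.size
    log_prior = grid.log_prior()
    prior = np.exp(log_prior)
    T = grid.stay_prob * np.eye(k) + (1.0 - grid.stay_prob) * np.tile(prior, (k, 1))
    logT = np.log(T)
    states = np.indices((k,) * len(nodes)).reshape(len(nodes), -1)
    logp = log_prior[states[0]]
    for parent, child in graph.edges:
        logp = logp + logT[states[idx[parent]], states[idx[child]]]
    for n in nodes:
        if graph.out_degree(n) == 0:
            s = summaries.get(n)
            if s is not None and s.informative:
                loglik = norm.logpdf(s.b_hat, loc=grid.values, scale=s.se_hat)
                logp = logp + loglik[states[idx[n]]]
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return {n: np.bincount(states[idx[n]], weights=p, minlength=k) for n in nodes}


def meta_analysis_of_ratios(beta_exposure, beta_outcome, se_outcome):
    """Inverse-variance meta-analysis of per-variant Wald ratios
    (weights β_X²/se_Y²) — the classical IVW identity."""
    bx = np.asarray(beta_exposure, float)
    by = np.asarray(beta_outcome, float)
    sy = np.asarray(se_outcome, float)
    ratios = by / bx
    w = bx**2 / sy**2
    return float(np.sum(w * ratios) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def random_tree(rng: np.random.Generator, n_nodes: int) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_node("n0")
    for i in range(1, n_nodes):
        g.add_edge(f"n{rng.integers(0, i)}", f"n{i}")
    return g


def random_grid(rng: np.random.Generator, max_states: int = 7):
    k = int(rng.integers(3, max_states + 1))
    values = np.sort(rng.normal(0.0, 1.0, k - 1))
    values = np.sort(np.append(values, 0.0))
    if np.unique(values).size < k:
        return random_grid(rng, max_states)
    return treewas_mod.CoefficientGrid(
        values,
        prior_nonzero=float(rng.uniform(0.01, 0.5)),
        stay_prob=float(rng.uniform(0.2, 0.95)),
    )


def treewas_enumeration_max_error(n_cases: int = 200, seed: int = 0,
                                  max_nodes: int = 6, max_states: int = 7) -> float:
    """Worst absolute deviation between message-passing and enumerated
    marginals over fuzzed random trees."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        g = random_tree(rng, int(rng.integers(2, max_nodes + 1)))
        tree = phenome_mod.PhenoTree(graph=g, root="n0")
        grid = random_grid(rng, max_states)
        summaries = {}
        for n in g.nodes:
            if g.out_degree(n) == 0 and rng.random() < 0.8:
                summaries[n] = treewas_mod.NodeSummary(
                    n, 100, float(rng.normal(0, 1)),
                    float(rng.uniform(0.05, 1.0)), True,
                )
        res = treewas_mod.tree_posteriors(tree, summaries, grid)
        oracle = enumerate_tree_marginals(g, summaries, grid)
        for n in g.nodes:
            err = abs(res[n].pp_nonzero - (1.0 - oracle[n][grid.zero_index]))
            worst = max(worst, float(err))
    return worst


def ivw_meta_identity_max_error(n_cases: int = 50, seed: int = 0) -> float:
    """Worst deviation between the IVW estimator and the meta-analytic
    combination of Wald ratios on fuzzed summary sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        m = int(rng.integers(2, 25))
        bx = rng.uniform(0.05, 0.4, m)
        sy = rng.uniform(0.01, 0.1, m)
        by = 0.2 * bx + rng.normal(0, sy)
        s = mr_mod.MRSummarySet([f"rs{i}" for i in range(m)], bx,
                                np.full(m, 0.01), by, sy)
        res = mr_mod.ivw(s)
        beta, se = meta_analysis_of_ratios(bx, by, sy)
        worst = max(worst, abs(res.beta - beta), abs(res.se - se))
    return float(worst)


# ---------------------------------------------------------------------------
# simulation calibrations (packaged study conditions)
# ---------------------------------------------------------------------------


def ivw_recovery(seed: int = 0, tau: float = 0.3, n_outcome: int = 50_000):
    """IVW estimate and SE for a simulated causal effect on the packaged
    31-variant instrument."""
    cfg = synthetic.default_config(1_000, seed=seed)
    s = synthetic.simulate_summary_stats(cfg, n_outcome, causal_effect=tau,
                                         seed=seed)
    res = mr_mod.ivw(s)
    return res.beta, res.se


def egger_type1_rate(n_reps: int = 1_000, seed: int = 0, tau: float = 0.0,
                     n_outcome: int = 50_000) -> float:
    """Rejection rate of the Egger intercept test with no simulated
    pleiotropy and no causal effect (nominal level 0.05; with tau = 0 the
    weighted t-test is exactly calibrated)."""
    cfg = synthetic.default_config(1_000, seed=seed)
    rejections = 0
    for r in range(n_reps):
        s = synthetic.simulate_summary_stats(cfg, n_outcome, causal_effect=tau,
                                             seed=seed * n_reps + r + 1)
        res = mr_mod.egger(s)
        rejections += res.p_pleiotropy < 0.05
    return rejections / n_reps


def bh_permutation_fwer(n_reps: int = 500, seed: int = 0, q: float = 0.05,
                        cohort_seed: int = 0, n: int = 50_000) -> float:
    """Fraction of permutation replicates with at least one FDR discovery.

    The cohort is simulated once under the packaged conditions; each
    replicate permutes the risk score across persons (a global null) and
    reruns the full PheWAS + BH step.
    """
    cfg = synthetic.default_config(n, seed=cohort_seed)
    cohort = synthetic.simulate_cohort(cfg)
    weights = synthetic.instrument_weights(cfg)
    score = grs_mod.compute_grs(
        cohort.genotypes, grs_mod.harmonize(weights, cohort.genotypes.variant_metadata())
    )
    selected = grs_mod.screen_covariates(
        score,
        cohort.traits[["sex", "age", "bmi", "center", "pc1", "pc2", "pc3", "pc4", "pc5"]],
        categorical=["center"],
    )
    covariates = cohort.traits[selected] if selected else None
    pmap = phenome_mod.packaged_map()
    assignments = phenome_mod.map_to_phecodes(cohort.diagnoses, pmap)
    phenome, _ = phenome_mod.build_all_case_controls(
        assignments, pmap, cohort.genotypes.person_ids, 20
    )
    positions = phewas_mod.phenome_positions(phenome, score.person_ids)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for _ in range(n_reps):
        perm = grs_mod.GRSVector(score.person_ids, rng.permutation(score.score), 1)
        rep = phewas_mod.run_phewas(phenome, perm, covariates, q,
                                    positions=positions)
        hits += bool(rep.discoveries)
    return hits / n_reps


GOUT_PHECODES = {"274", "274.1", "274.11"}
MEDIATED_PHECODE = {"obesity": "278.1", "bp": "401.1",
                    "lipid": "272.11", "glucose": "250.2"}


def dissection_recovery(n_reps: int = 50, seed: int = 0,
                        n: int = 50_000) -> dict[str, float]:
    """Replicate-level recovery rates of the pleiotropy-dissection logic.

    For each replicate cohort: the exposure-specific score must discover
    the gout-like phecode and nothing outside the gout rollup; each
    category score must discover its mediated disease phecode; each
    leave-category-out score must lose that discovery.
    """
    pmap = phenome_mod.packaged_map()
    counts: dict[str, int] = {}

    def bump(key, ok):
        counts[key] = counts.get(key, 0) + bool(ok)

    for r in range(n_reps):
        cfg = synthetic.default_config(n, seed=seed * n_reps + r + 1)
        cohort = synthetic.simulate_cohort(cfg)
        weights = synthetic.instrument_weights(cfg)
        score = grs_mod.compute_grs(
            cohort.genotypes,
            grs_mod.harmonize(weights, cohort.genotypes.variant_metadata()),
        )
        selected = grs_mod.screen_covariates(
            score,
            cohort.traits[["sex", "age", "bmi", "center",
                           "pc1", "pc2", "pc3", "pc4", "pc5"]],
            categorical=["center"],
        )
        covariates = cohort.traits[selected] if selected else None
        assignments = phenome_mod.map_to_phecodes(cohort.diagnoses, pmap)
        phenome, _ = phenome_mod.build_all_case_controls(
            assignments, pmap, cohort.genotypes.person_ids, 20
        )
        pvalues = synthetic.simulate_pleiotropy_pvalues(cfg)
        table = pleio_mod.classify_loci(
            pvalues, synthetic.TRAIT_GROUPS,
            pleio_mod.bonferroni_threshold(0.05, len(weights)),
            renal=cfg.renal_rsids,
        )
        grs_set = pleio_mod.build_stratified_grs(table, weights, cohort.genotypes)
        wanted = (["exposure_specific"] + list(MEDIATED_PHECODE)
                  + [f"without_{c}" for c in MEDIATED_PHECODE])
        subset = {k: grs_set[k] for k in wanted}
        reports, _ = pleio_mod.run_sensitivity(subset, phenome, covariates)
        spec_disc = set(reports["exposure_specific"].discoveries)
        bump("specific_only_gout",
             "274.1" in spec_disc and spec_disc <= GOUT_PHECODES)
        for cat, phecode in MEDIATED_PHECODE.items():
            bump(f"{cat}_hits_disease", phecode in reports[cat].discoveries)
            bump(f"without_{cat}_loses_disease",
                 phecode not in reports[f"without_{cat}"].discoveries)
    return {k: v / n_reps for k, v in counts.items()}
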