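import networkx as nx
import numpy as np
import pytest

from phemr.grs import GRSVector
from phemr.phenome import (
    PhenoTree,
    build_icd_tree,
    packaged_hierarchy,
    propagate_cases,
)
from phemr.phewas import fit_logistic
from phemr.phenome import CaseControlSet
from phemr.treewas import (
    CoefficientGrid,
    NodeSummary,
    TreewasResult,
    default_grid,
    node_summaries,
    report_associated,
    tree_posteriors,
)

from .oracles import enumerate_tree_marginals, random_grid, random_tree


def _grid(values=(-1.0, -0.5, 0.0, 0.5, 1.0), pi=0.1, stay=0.7):
    return CoefficientGrid(np.array(values), prior_nonzero=pi, stay_prob=stay)


def _chain(n):
    g = nx.DiGraph()
    for i in range(n - 1):
        g.add_edge(f"n{i}", f"n{i+1}")
    return PhenoTree(graph=g, root="n0")


def _star(leaves):
    g = nx.DiGraph()
    for name in leaves:
        g.add_edge("root", name)
    return PhenoTree(graph=g, root="root")


class TestGrid:
    def test_requires_single_zero_and_order(self):
        with pytest.raises(ValueError):
            CoefficientGrid(np.array([-1.0, 0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            CoefficientGrid(np.array([1.0, 0.0, -1.0]))

    def test_default_grid_width_formula(self):
        summaries = {f"l{i}": NodeSummary(f"l{i}", 100, 0.0, 0.2, True)
                     for i in range(4)}
        grid = default_grid(summaries, list(summaries), n_nonzero=20)
        assert grid.values.size == 21
        assert grid.values.max() == pytest.approx(4 * 0.2 * 2.0)  # 4·median SE·√4
        assert np.count_nonzero(grid.values == 0) == 1


class TestPosteriors:
    def test_flat_likelihoods_reproduce_prior_everywhere(self):
        # stationarity of the Markov prior: pp equals pi at every depth
        tree = _chain(5)
        grid = _grid(pi=0.07, stay=0.4)
        res = tree_posteriors(tree, {}, grid)
        for r in res.values():
            assert r.pp_nonzero == pytest.approx(0.07, abs=1e-12)

    def test_theta_to_zero_shares_one_state(self):
        # stay_prob -> 1: all nodes carry the pooled single-coefficient posterior
        tree = _star(["a", "b", "c"])
        grid = _grid(pi=0.2, stay=1 - 1e-12)
        summaries = {
            "a": NodeSummary("a", 50, 0.45, 0.2, True),
            "b": NodeSummary("b", 50, 0.55, 0.25, True),
            "c": NodeSummary("c", 50, 0.5, 0.3, True),
        }
        res = tree_posteriors(tree, summaries, grid)
        from scipy.stats import norm

        log_post = grid.log_prior().copy()
        for s in summaries.values():
            log_post += norm.logpdf(s.b_hat, grid.values, s.se_hat)
        pooled = np.exp(log_post - log_post.max())
        pooled /= pooled.sum()
        expected_pp = 1 - pooled[grid.zero_index]
        for r in res.values():
            assert r.pp_nonzero == pytest.approx(expected_pp, abs=1e-6)

    def test_theta_to_one_decouples_leaves(self):
        tree = _star(["a", "b", "c"])
        grid = _grid(pi=0.3, stay=1e-12)
        summaries = {
            "a": NodeSummary("a", 50, 0.9, 0.2, True),
            "b": NodeSummary("b", 50, -0.4, 0.3, True),
            "c": NodeSummary("c", 50, 0.0, 0.5, True),
        }
        res = tree_posteriors(tree, summaries, grid)
        from scipy.stats import norm

        for name, s in summaries.items():
            log_post = grid.log_prior() + norm.logpdf(s.b_hat, grid.values, s.se_hat)
            post = np.exp(log_post - log_post.max())
            post /= post.sum()
            assert res[name].pp_nonzero == pytest.approx(
                1 - post[grid.zero_index], abs=1e-6
            )

    def test_marginals_match_enumeration_on_random_trees(self, rng):
        for _ in range(40):
            g = random_tree(rng, int(rng.integers(2, 7)))
            tree = PhenoTree(graph=g, root="n0")
            grid = random_grid(rng)
            summaries = {}
            for n in g.nodes:
                if g.out_degree(n) == 0 and rng.random() < 0.8:
                    summaries[n] = NodeSummary(
                        n, 100, float(rng.normal(0, 1)),
                        float(rng.uniform(0.05, 1.0)), True,
                    )
            res = tree_posteriors(tree, summaries, grid)
            oracle = enumerate_tree_marginals(g, summaries, grid)
            for n in g.nodes:
                assert res[n].pp_nonzero == pytest.approx(
                    1 - oracle[n][grid.zero_index], abs=1e-10
                )

    def test_stronger_leaf_signal_never_lowers_its_pp(self):
        tree = _star(["a", "b"])
        grid = _grid(pi=0.05, stay=0.6)
        base = {"b": NodeSummary("b", 50, 0.1, 0.3, True)}
        previous = -1.0
        for b_hat in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            summaries = dict(base, a=NodeSummary("a", 50, b_hat, 0.25, True))
            pp = tree_posteriors(tree, summaries, grid)["a"].pp_nonzero
            assert pp >= previous - 1e-12
            previous = pp

    def test_cycle_is_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            tree_posteriors(PhenoTree(graph=g, root="a"), {}, _grid())

    def test_map_estimate_inside_credible_interval(self, rng):
        for _ in range(10):
            g = random_tree(rng, 5)
            tree = PhenoTree(graph=g, root="n0")
            grid = random_grid(rng)
            summaries = {
                n: NodeSummary(n, 100, float(rng.normal()), 0.3, True)
                for n in g.nodes if g.out_degree(n) == 0
            }
            for r in tree_posteriors(tree, summaries, grid).values():
                assert r.ci_low <= r.map_estimate <= r.ci_high


class TestNodeSummaries:
    def test_summary_matches_standalone_logistic_fit(self, default_cohort,
                                                     default_grs,
                                                     screened_covariates):
        _, cohort = default_cohort
        persons = cohort.genotypes.person_ids
        tree = build_icd_tree({d.code for d in cohort.diagnoses},
                              packaged_hierarchy())
        propagate_cases(tree, cohort.diagnoses, persons)
        summaries = node_summaries(tree, default_grs, screened_covariates)
        node = "M10.0"
        mask = tree.indicators[node]
        ccs = CaseControlSet(
            node,
            [p for p, m in zip(persons, mask) if m],
            [p for p, m in zip(persons, mask) if not m],
        )
        ref = fit_logistic(ccs, default_grs, screened_covariates)
        assert summaries[node].b_hat == pytest.approx(ref.beta, abs=1e-8)
        assert summaries[node].se_hat == pytest.approx(ref.se, abs=1e-8)

    def test_sparse_node_gets_flat_likelihood(self):
        g = nx.DiGraph([("root", "leaf")])
        tree = PhenoTree(graph=g, root="root", person_ids=["p0", "p1", "p2"],
                         indicators={"root": np.array([True, False, False]),
                                     "leaf": np.array([True, False, False])})
        grs = GRSVector(["p0", "p1", "p2"], np.array([0.1, 0.2, 0.3]), 1)
        summaries = node_summaries(tree, grs, min_cases=20)
        assert not summaries["leaf"].informative


class TestReporting:
    def test_threshold_filters_and_orders(self):
        tree = _star(["a", "b"])
        results = {
            "root": TreewasResult("root", 0.99, 0.3, 0.1, 0.5),
            "a": TreewasResult("a", 0.5, 0.3, 0.1, 0.5),
            "b": TreewasResult("b", 0.97, 0.3, 0.1, 0.5),
        }
        reported = report_associated(tree, results, 0.95)
        assert [r.node for r in reported] == ["root", "b"]
        assert report_associated(tree, results, 0.0) and len(
            report_associated(tree, results, 0.0)
        ) == 3
        none_pass = {k: TreewasResult(k, 0.5, 0, 0, 0) for k in results}
        assert report_associated(tree, none_pass, 0.95) == []

    def test_disease_branches_reported_in_default_cohort(self, default_cohort,
                                                         default_grs,
                                                         screened_covariates):
        _, cohort = default_cohort
        tree = build_icd_tree({d.code for d in cohort.diagnoses},
                              packaged_hierarchy())
        propagate_cases(tree, cohort.diagnoses, cohort.genotypes.person_ids)
        summaries = node_summaries(tree, default_grs, screened_covariates)
        grid = default_grid(summaries, tree.leaves())
        res = tree_posteriors(tree, summaries, grid)
        reported = {r.node for r in report_associated(tree, res, 0.95)}
        assert "M10.0" in reported            # exposure-driven disease leaf
        assert {"I10", "I10-I15"} <= reported  # mediated hypertension branch
        for null_node in ["J45.9", "K21.9", "N39.0", "J40-J47"]:
            assert null_node not in reported
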