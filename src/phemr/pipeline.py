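"""End-to-end orchestration of the analysis stages.

``run_all`` executes score construction → phenome building → PheWAS →
tree scan → two-sample MR replication → pleiotropy dissection on a
cohort (simulated by default), writing one TSV per stage plus a summary
document and a manifest.  A single global seed is fanned out to named
per-stage substreams, so reruns are byte-identical and stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import grs as grs_mod
from . import mr as mr_mod
from . import phenome as phenome_mod
from . import phewas as phewas_mod
from . import pleiotropy as pleio_mod
from . import synthetic
from . import treewas as treewas_mod
from .io_formats import write_diagnoses, write_genotypes, write_variant_weights

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    out_dir: Path
    n_individuals: int = 50_000
    q: float = 0.05
    min_cases: int = 20
    pp_threshold: float = 0.95
    alpha_pleiotropy: float = 0.05
    causal_effect: float = 0.3  # simulated causal effect for the MR stage
    n_outcome_cohort: int = 50_000
    seed: int = 0
    write_inputs: bool = True
    simulation: Optional[synthetic.SimulationConfig] = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("q", "pp_threshold", "alpha_pleiotropy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")


@dataclass
class ReportBundle:
    phewas: phewas_mod.PhewasReport
    treewas: dict[str, treewas_mod.TreewasResult]
    treewas_reported: list[treewas_mod.TreewasResult]
    mr: dict[str, list[mr_mod.MRResult]]
    sensitivity_matrix: pd.DataFrame
    covariates_selected: list[str]
    manifest: dict


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return str(path)


def run_all(config: PipelineConfig) -> ReportBundle:
    """Execute every stage; returns the in-memory reports.

    Any stage failure raises :class:`StageError` naming the stage;
    outputs written so far remain on disk and are listed in the manifest.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "outputs": [], "dropped": {}}
    stage = "simulate"
    try:
        sim = config.simulation or synthetic.default_config(
            config.n_individuals, seed=config.seed
        )
        cohort = synthetic.simulate_cohort(sim)
        weights = synthetic.instrument_weights(sim)
        if config.write_inputs:
            write_genotypes(cohort.genotypes, out / "genotypes.tsv")
            write_variant_weights(weights, out / "weights.tsv")
            write_diagnoses(cohort.diagnoses, out / "diagnoses.tsv")
            cohort.traits.reset_index().to_csv(
                out / "traits.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
            )
            manifest["outputs"] += ["genotypes.tsv", "weights.tsv",
                                    "diagnoses.tsv", "traits.tsv"]

        stage = "grs"
        aligned = grs_mod.harmonize(weights, cohort.genotypes.variant_metadata())
        score = grs_mod.compute_grs(cohort.genotypes, aligned)
        manifest["dropped"]["grs_variants"] = score.variants_dropped
        candidates = cohort.traits[
            ["sex", "age", "bmi", "center", "pc1", "pc2", "pc3", "pc4", "pc5"]
        ]
        selected = grs_mod.screen_covariates(score, candidates, categorical=["center"])
        covariates = cohort.traits[selected] if selected else None
        manifest["outputs"].append(_write(score.to_frame(), out / "grs.tsv"))

        stage = "phenome"
        pmap = phenome_mod.packaged_map()
        assignments = phenome_mod.map_to_phecodes(cohort.diagnoses, pmap)
        phenome, filtered = phenome_mod.build_all_case_controls(
            assignments, pmap, cohort.genotypes.person_ids, config.min_cases
        )
        manifest["dropped"]["phecodes_filtered"] = [
            (f.phecode, f.n_cases, f.reason) for f in filtered
        ]
        manifest["dropped"]["unmapped_codes"] = assignments.attrs.get(
            "unmapped_codes", []
        )
        tree = phenome_mod.build_icd_tree(
            {d.code for d in cohort.diagnoses}, phenome_mod.packaged_hierarchy()
        )
        phenome_mod.propagate_cases(tree, cohort.diagnoses, cohort.genotypes.person_ids)

        stage = "phewas"
        phewas_report = phewas_mod.run_phewas(phenome, score, covariates, config.q)
        manifest["outputs"].append(_write(phewas_report.to_frame(), out / "phewas.tsv"))

        stage = "treewas"
        summaries = treewas_mod.node_summaries(tree, score, covariates, config.min_cases)
        grid = treewas_mod.default_grid(summaries, tree.leaves())
        posteriors = treewas_mod.tree_posteriors(tree, summaries, grid)
        reported = treewas_mod.report_associated(tree, posteriors, config.pp_threshold)
        manifest["outputs"].append(
            _write(treewas_mod.results_frame(posteriors), out / "treewas.tsv")
        )

        stage = "mr"
        mr_results: dict[str, list[mr_mod.MRResult]] = {}
        for name, tau, loadings in [
            ("causal_outcome", config.causal_effect, None),
            ("pleiotropic_outcome", 0.0, {"bp": 0.25, "lipid": 0.25}),
        ]:
            sset = synthetic.simulate_summary_stats(
                sim, config.n_outcome_cohort, causal_effect=tau,
                mediator_loadings=loadings, outcome_name=name,
                seed=config.seed + (1 if loadings else 0),
            )
            mr_results[name] = [
                mr_mod.ivw(sset), mr_mod.egger(sset),
                mr_mod.weighted_median(sset, seed=config.seed),
                mr_mod.mode_based(sset, seed=config.seed),
                mr_mod.select_estimator(sset, config.alpha_pleiotropy, seed=config.seed),
            ]
        mr_frame = pd.concat(
            [mr_mod.results_frame(v).assign(outcome=k) for k, v in mr_results.items()],
            ignore_index=True,
        )
        manifest["outputs"].append(_write(mr_frame, out / "mr.tsv"))

        stage = "pleiotropy"
        threshold = pleio_mod.bonferroni_threshold(
            config.alpha_pleiotropy, len(weights)
        )
        pvalues = synthetic.simulate_pleiotropy_pvalues(sim)
        table = pleio_mod.classify_loci(
            pvalues, synthetic.TRAIT_GROUPS, threshold, renal=sim.renal_rsids
        )
        grs_set = pleio_mod.build_stratified_grs(table, weights, cohort.genotypes)
        reports, matrix = pleio_mod.run_sensitivity(
            grs_set, phenome, covariates, config.q
        )
        manifest["outputs"].append(
            _write(table.to_frame().reset_index(), out / "locus_categories.tsv")
        )
        manifest["outputs"].append(
            _write(matrix.reset_index(), out / "sensitivity_matrix.tsv")
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    _write_summary(out, score, selected, phewas_report, reported, mr_results, matrix)
    manifest["outputs"].append(str(out / "summary.md"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return ReportBundle(
        phewas=phewas_report, treewas=posteriors, treewas_reported=reported,
        mr=mr_results, sensitivity_matrix=matrix, covariates_selected=selected,
        manifest=manifest,
    )


def _write_summary(out, score, selected, phewas_report, treewas_reported,
                   mr_results, matrix) -> None:
    from .phewas import or_from_beta

    lines = ["# Phenome-wide MR summary", ""]
    lines.append(f"Mean weighted GRS: {np.mean(score.score):.3f} "
                 f"(SD {np.std(score.score):.3f}); "
                 f"{score.n_variants_used} variants used.")
    lines.append(f"Covariates adjusted: {', '.join(selected) or 'none'}.")
    lines.append("")
    lines.append("## PheWAS discoveries (FDR q < %g)" % phewas_report.fdr_q)
    lines.append(f"Significance threshold p <= {phewas_report.significance_threshold:.3g}")
    lines.append("")
    lines.append("phecode | n_cases | beta | SE | OR (95% CI) | p")
    lines.append("---|---|---|---|---|---")
    for r in phewas_report.results:
        if r.phenotype in phewas_report.discoveries:
            point, lo, hi = or_from_beta(r.beta, r.se)
            lines.append(
                f"{r.phenotype} | {r.n_cases} | {r.beta:.3f} | {r.se:.3f} | "
                f"{point:.2f} ({lo:.2f}-{hi:.2f}) | {r.p:.3g}"
            )
    lines.append("")
    lines.append("## Tree scan nodes at PP >= threshold")
    for r in treewas_reported:
        lines.append(f"- {r.node}: PP={r.pp_nonzero:.3f}, "
                     f"MAP={r.map_estimate:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})")
    lines.append("")
    lines.append("## Two-sample MR")
    for outcome, results in mr_results.items():
        chosen = results[-1]
        lines.append(f"- {outcome}: selected {chosen.method}, "
                     f"beta={chosen.beta:.3f} (SE {chosen.se:.3f}), "
                     f"p={chosen.p_effect:.3g} [{chosen.note}]")
    lines.append("")
    lines.append("## Sensitivity discovery matrix")
    lines.append(matrix.to_string())
    (out / "summary.md").write_text("\n".join(lines) + "\n")
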