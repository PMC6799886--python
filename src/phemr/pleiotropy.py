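"""Pleiotropy dissection of the instrument.

Classifies instrument loci by their cross-trait associations at a
Bonferroni threshold, builds category-stratified and leave-category-out
risk scores (plus the renal-handling subset and its complement), and
reruns the PheWAS under each score to separate exposure-specific from
mediator-driven disease associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grs import GRSVector, compute_grs, harmonize
from .io_formats import GenotypeMatrix, ValidationError, VariantWeight
from .phenome import CaseControlSet
from .phewas import PhewasReport, phenome_positions, run_phewas

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha/m — the per-test level over m instrument loci."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


@dataclass
class LocusCategoryTable:
    """Per-locus pleiotropy flags; categories may overlap.

    A locus is exposure-specific iff it carries no category flag.
    """

    flags: pd.DataFrame  # index rsid, boolean columns per category
    renal: set[str] = field(default_factory=set)

    @property
    def categories(self) -> list[str]:
        return list(self.flags.columns)

    def specific(self) -> list[str]:
        return list(self.flags.index[~self.flags.any(axis=1)])

    def flagged(self, category: str) -> list[str]:
        return list(self.flags.index[self.flags[category]])

    def to_frame(self) -> pd.DataFrame:
        out = self.flags.copy()
        out["exposure_specific"] = ~self.flags.any(axis=1)
        out["renal_handling"] = [r in self.renal for r in self.flags.index]
        return out


def classify_loci(
    pvalues: pd.DataFrame,
    trait_groups: Mapping[str, Sequence[str]],
    threshold: float,
    renal: Optional[Sequence[str]] = None,
) -> LocusCategoryTable:
    """Flag a locus for a category iff any trait in the category's group
    has p < threshold.

    ``pvalues`` is rsid × trait.  A missing trait p-value counts as
    non-significant (with a warning); an unknown trait name in
    ``trait_groups`` is an error.
    """
    known = set(pvalues.columns)
    flags = {}
    for category, traits in trait_groups.items():
        unknown = [t for t in traits if t not in known]
        if unknown:
            raise ValidationError(f"unknown trait name(s) {unknown} in group {category!r}")
        sub = pvalues[list(traits)]
        if sub.isna().any().any():
            logger.warning("missing p-values in group %s treated as non-significant",
                           category)
        flags[category] = (sub < threshold).any(axis=1)
    table = pd.DataFrame(flags, index=pvalues.index)
    return LocusCategoryTable(flags=table, renal=set(renal or []))


def build_stratified_grs(
    categories: LocusCategoryTable,
    weights: Sequence[VariantWeight],
    genotypes: GenotypeMatrix,
) -> dict[str, GRSVector]:
    """The named score set used by the sensitivity PheWAS.

    Emits: ``full`` (all loci), ``exposure_specific``, one score per
    pleiotropy category, ``without_<category>`` leave-category-out scores
    (a locus is removed if it carries the removed flag, regardless of
    other flags), and — when renal membership is supplied —
    ``renal_handling`` plus its complement ``non_renal``.  Empty subsets
    are omitted with a warning.
    """
    by_rsid = {w.rsid: w for w in weights}
    meta = genotypes.variant_metadata()
    subsets: dict[str, list[str]] = {
        "full": list(by_rsid),
        "exposure_specific": categories.specific(),
    }
    all_rsids = list(by_rsid)
    for cat in categories.categories:
        flagged = categories.flagged(cat)
        subsets[cat] = flagged
        subsets[f"without_{cat}"] = [r for r in all_rsids if r not in set(flagged)]
    if categories.renal:
        subsets["renal_handling"] = [r for r in all_rsids if r in categories.renal]
        subsets["non_renal"] = [r for r in all_rsids if r not in categories.renal]
    out: dict[str, GRSVector] = {}
    for name, rsids in subsets.items():
        if not rsids:
            logger.warning("stratified GRS %s is empty; omitted", name)
            continue
        sub_weights = [by_rsid[r] for r in rsids if r in by_rsid]
        aligned = harmonize(sub_weights, meta)
        out[name] = compute_grs(genotypes, aligned)
    return out


def run_sensitivity(
    grs_set: Mapping[str, GRSVector],
    phenome: Mapping[str, CaseControlSet],
    covariates: Optional[pd.DataFrame] = None,
    q: float = 0.05,
) -> tuple[dict[str, PhewasReport], pd.DataFrame]:
    """One PheWAS report per score, plus the phenotype × score discovery
    matrix (the network-plot analogue of the dissection)."""
    first = next(iter(grs_set.values()))
    positions = phenome_positions(phenome, first.person_ids)
    reports: dict[str, PhewasReport] = {}
    for name, grs in grs_set.items():
        if grs.person_ids != first.person_ids:
            positions_g = phenome_positions(phenome, grs.person_ids)
        else:
            positions_g = positions
        reports[name] = run_phewas(phenome, grs, covariates, q, positions=positions_g)
    matrix = pd.DataFrame(
        {name: {ph: ph in rep.discoveries for ph in phenome}
         for name, rep in reports.items()}
    )
    matrix.index.name = "phenotype"
    return reports, matrix
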