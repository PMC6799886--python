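"""Weighted genetic risk scores.

Aligns instrument weights to the alleles counted by a genotype matrix
(handling swapped, strand-flipped and palindromic variants), computes the
weighted allele-count score, and screens candidate covariates for
correlation with the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, ValidationError, VariantWeight

logger = logging.getLogger(__name__)

#: palindromic variants are frequency-aligned only when both sides are at
#: least this far from 0.5
PALINDROMIC_EAF_MARGIN = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class AlignedWeight:
    """A weight aligned to the genotype matrix's counted allele.

    ``flip`` means the counted allele is the instrument's *other* allele,
    so the dosage contributes as ``2 - d`` (equivalently the effect of
    the counted allele is ``-beta``).
    """

    rsid: str
    beta: float
    eaf: float  # frequency of the counted allele implied by the weights
    flip: bool


@dataclass
class GRSVector:
    """Per-person weighted risk score, in exposure units (mg/dL-equivalent)."""

    person_ids: list[str]
    score: np.ndarray
    n_variants_used: int
    variants_dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not np.all(np.isfinite(self.score)):
            raise ValidationError("GRS contains non-finite scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"person_id": self.person_ids, "score": self.score})

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=pd.Index(self.person_ids, name="person_id"),
                         name="score")


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    weights: Sequence[VariantWeight],
    genotype_variants: Sequence[tuple[str, str, str, float]],
) -> list[AlignedWeight]:
    """Align instrument weights to the alleles the genotype matrix counts.

    For each variant: a direct allele match keeps the weight; swapped
    alleles flip the dosage contribution to ``2 - d``; strand-flipped
    (complemented) alleles are matched after complementing; palindromic
    variants are aligned by allele frequency when both frequencies are
    more than ``PALINDROMIC_EAF_MARGIN`` from 0.5, otherwise dropped as
    "palindromic-ambiguous".  Unmatched or incompatible variants are
    dropped with a machine-readable reason, never silently.

    Returns the aligned list; drop reasons are attached to the list via
    the ``dropped`` attribute (list of (rsid, reason)).
    """
    by_rsid = {g[0]: g for g in genotype_variants}
    if len(by_rsid) != len(genotype_variants):
        raise ValidationError("duplicate rsids among genotype variants")
    aligned: list[AlignedWeight] = []
    dropped: list[tuple[str, str]] = []
    for w in weights:
        g = by_rsid.get(w.rsid)
        if g is None:
            dropped.append((w.rsid, "not-in-genotypes"))
            continue
        _, counted, other, observed_af = g
        if _is_palindromic(w.effect_allele, w.other_allele):
            if {counted, other} != {w.effect_allele, w.other_allele}:
                dropped.append((w.rsid, "allele-mismatch"))
                continue
            if abs(w.eaf - 0.5) <= PALINDROMIC_EAF_MARGIN or (
                observed_af is not None
                and np.isfinite(observed_af)
                and abs(observed_af - 0.5) <= PALINDROMIC_EAF_MARGIN
            ):
                dropped.append((w.rsid, "palindromic-ambiguous"))
                continue
            # frequencies on the same side of 0.5 -> counted allele is the
            # effect allele; opposite sides -> it is the other allele
            same_side = (w.eaf - 0.5) * (observed_af - 0.5) > 0
            flip = not same_side
        elif (counted, other) == (w.effect_allele, w.other_allele):
            flip = False
        elif (counted, other) == (w.other_allele, w.effect_allele):
            flip = True
        else:
            comp = (_COMPLEMENT.get(counted, "?"), _COMPLEMENT.get(other, "?"))
            if comp == (w.effect_allele, w.other_allele):
                flip = False
            elif comp == (w.other_allele, w.effect_allele):
                flip = True
            else:
                dropped.append((w.rsid, "allele-mismatch"))
                continue
        counted_eaf = 1.0 - w.eaf if flip else w.eaf
        aligned.append(AlignedWeight(w.rsid, w.beta, counted_eaf, flip))
    for rsid, reason in dropped:
        logger.info("harmonize: dropped %s (%s)", rsid, reason)
    return _AlignedList(aligned, dropped)


class _AlignedList(list):
    """List of AlignedWeight carrying the harmonization drop log."""

    def __init__(self, items, dropped):
        super().__init__(items)
        self.dropped: list[tuple[str, str]] = dropped


def compute_grs(
    genotypes: GenotypeMatrix, aligned: Sequence[AlignedWeight]
) -> GRSVector:
    """score_i = Σ_j beta_j · dosage_ij on the harmonized orientation.

    Flipped variants contribute ``beta·(2 - d)``; missing dosages are
    imputed by the expected dosage ``2·eaf`` of the counted allele (so a
    flipped variant's imputed contribution uses its flipped frequency).
    """
    dropped = list(getattr(aligned, "dropped", []))
    if len(aligned) == 0:
        raise ValidationError("no variants left after harmonization")
    col = {v: j for j, v in enumerate(genotypes.variant_ids)}
    score = np.zeros(genotypes.n_individuals)
    used = 0
    for w in aligned:
        j = col.get(w.rsid)
        if j is None:
            dropped.append((w.rsid, "not-in-genotypes"))
            continue
        d = genotypes.dosage[:, j]
        d = np.where(np.isnan(d), 2.0 * w.eaf if not w.flip else 2.0 * (1.0 - w.eaf), d)
        if w.flip:
            d = 2.0 - d
        score += w.beta * d
        used += 1
    if used == 0:
        raise ValidationError("no variants left after harmonization")
    return GRSVector(
        person_ids=list(genotypes.person_ids),
        score=score,
        n_variants_used=used,
        variants_dropped=dropped,
    )


def screen_covariates(
    grs: GRSVector,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    categorical: Optional[Sequence[str]] = None,
) -> list[str]:
    """Names of candidate covariates correlated with the score at p < alpha.

    Continuous candidates are tested by the Pearson correlation test;
    categorical candidates (declared via ``categorical``, or inferred for
    non-numeric / integer-coded columns with few levels) by one-way
    analysis of variance of the score across levels.  Constant columns
    are skipped with a warning.
    """
    y = grs.as_series().loc[candidates.index].to_numpy()
    categorical = set(categorical or [])
    selected = []
    for name in candidates.columns:
        x = candidates[name]
        if x.nunique(dropna=True) < 2:
            logger.warning("screen_covariates: %s is constant, skipped", name)
            continue
        is_cat = (
            name in categorical
            or not pd.api.types.is_numeric_dtype(x)
            or (pd.api.types.is_integer_dtype(x) and x.nunique() <= 10)
        )
        if is_cat:
            groups = [y[(x == level).to_numpy()] for level in x.unique()]
            _, p = stats.f_oneway(*groups)
        else:
            _, p = stats.pearsonr(x.to_numpy(dtype=float), y)
        if p < alpha:
            selected.append(name)
    return selected
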