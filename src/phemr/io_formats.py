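"""Typed readers and writers for every external table the pipeline touches.

All downstream modules consume only the record types defined here.  Files
are UTF-8; genotype/weight/diagnosis/summary-stat tables are
tab-separated, the phecode map is comma-separated.  No dialect sniffing
is performed, so a written file reads back bit-identically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")
_ICD9_RE = re.compile(r"^(?:[0-9]{3,5}|V[0-9]{2,4}|E[0-9]{3,4})$")
_PHECODE_RE = re.compile(r"^[0-9]+(?:\.[0-9]{1,2})?$")


class FormatError(ValueError):
    """The file cannot be parsed as the declared format."""


class ValidationError(ValueError):
    """The file parses but one or more rows violate a type invariant."""


def normalize_code(code: str) -> str:
    """Normalize a diagnosis code: trim, uppercase, strip dots."""
    return code.strip().upper().replace(".", "")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantWeight:
    """One exposure-associated variant of the instrument set.

    ``beta`` is the per-effect-allele effect on the exposure (mg/dL for
    the urate instrument), ``se`` its standard error and ``eaf`` the
    effect-allele frequency in the discovery population.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValidationError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValidationError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError("effect and other allele identical")
        if not np.isfinite(self.beta):
            raise ValidationError("beta not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError("se must be a positive real")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"eaf {self.eaf} outside (0,1)")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class DiagnosisRecord:
    """A single diagnosis episode from hospital, cancer or death records."""

    person_id: str
    system: str  # "ICD9" | "ICD10"
    code: str  # normalized: uppercase, no dot
    source: str  # "hospital" | "cancer" | "death"

    def validate(self) -> None:
        if self.system not in ("ICD9", "ICD10"):
            raise ValidationError(f"unknown code system {self.system!r}")
        if self.source not in ("hospital", "cancer", "death"):
            raise ValidationError(f"unknown record source {self.source!r}")
        pattern = _ICD10_RE if self.system == "ICD10" else _ICD9_RE
        if not pattern.match(self.code):
            raise ValidationError(f"code {self.code!r} invalid for {self.system}")


@dataclass(frozen=True)
class PhecodeMapEntry:
    """One row of the ICD→phecode map.

    ``code_pattern`` is a normalized ICD code or prefix; a diagnosis
    matches by longest normalized prefix.  ``exclusion_range`` gives the
    phecode interval whose members are removed from the control pool of
    this phecode (empty = no exclusion).
    """

    phecode: str
    system: str
    code_pattern: str
    exclusion_range: Optional[tuple[float, float]] = None

    def validate(self) -> None:
        if not _PHECODE_RE.match(self.phecode):
            raise ValidationError(f"phecode {self.phecode!r} is not hierarchical numeric")
        if self.system not in ("ICD9", "ICD10"):
            raise ValidationError(f"unknown code system {self.system!r}")
        if self.exclusion_range is not None:
            lo, hi = self.exclusion_range
            if not lo <= hi:
                raise ValidationError(f"exclusion bounds out of order: {lo} > {hi}")


@dataclass(frozen=True)
class SummaryStatRecord:
    """Per-variant GWAS summary statistic for one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    trait: str
    eaf: Optional[float] = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValidationError("alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError("effect and other allele identical")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError("se must be a positive real")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"eaf {self.eaf} outside (0,1)")


@dataclass
class GenotypeMatrix:
    """Individuals × variants dosage table.

    Dosages lie in [0, 2]; missing genotypes are encoded as ``nan``
    (never 0, which is a valid dosage).  ``counted_alleles`` /
    ``other_alleles`` record which allele each dosage column counts, when
    known, so weights can be harmonized against the matrix.
    """

    person_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    counted_alleles: Optional[list[str]] = None
    other_alleles: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.person_ids) or m != len(self.variant_ids):
            raise ValidationError("dosage dimensions inconsistent with id lists")
        if len(set(self.person_ids)) != len(self.person_ids):
            raise ValidationError("person_ids not unique")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages outside [0, 2]")
        for alleles in (self.counted_alleles, self.other_alleles):
            if alleles is not None and len(alleles) != m:
                raise ValidationError("allele annotation length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.person_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def observed_af(self) -> np.ndarray:
        """Counted-allele frequency per variant, ignoring missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def variant_metadata(self) -> list[tuple[str, str, str, float]]:
        """(rsid, counted_allele, other_allele, observed_af) per variant."""
        if self.counted_alleles is None or self.other_alleles is None:
            raise ValidationError("genotype matrix carries no allele annotation")
        afs = self.observed_af()
        return list(zip(self.variant_ids, self.counted_alleles, self.other_alleles, afs))


# ---------------------------------------------------------------------------
# variant weights
# ---------------------------------------------------------------------------

_WEIGHT_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se", "eaf"]


def read_variant_weights(path) -> list[VariantWeight]:
    """Read an instrument-weight TSV; reject invalid rows with their number."""
    df = _read_table(path, sep="\t", required=_WEIGHT_COLUMNS)
    records: list[VariantWeight] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = VariantWeight(
            rsid=str(row.rsid),
            effect_allele=str(row.effect_allele).strip().upper(),
            other_allele=str(row.other_allele).strip().upper(),
            beta=float(row.beta),
            se=float(row.se),
            eaf=float(row.eaf),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        if rec.rsid in seen:
            raise ValidationError(
                f"{path}, row {i}: duplicate rsid {rec.rsid!r} (first at row {seen[rec.rsid]})"
            )
        seen[rec.rsid] = i
        records.append(rec)
    return records


def write_variant_weights(records: Sequence[VariantWeight], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_WEIGHT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# diagnoses
# ---------------------------------------------------------------------------

_DIAG_COLUMNS = ["person_id", "system", "code", "source"]


def read_diagnoses(path) -> list[DiagnosisRecord]:
    """Read a long diagnosis TSV; codes are normalized, duplicates kept.

    Duplicate rows represent separate episodes and are retained.
    """
    df = _read_table(path, sep="\t", required=_DIAG_COLUMNS, allow_empty=True)
    if df.empty:
        logger.warning("diagnosis file %s is empty", path)
        return []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = DiagnosisRecord(
            person_id=str(row.person_id),
            system=str(row.system).strip().upper(),
            code=normalize_code(str(row.code)),
            source=str(row.source).strip().lower(),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise FormatError(f"{path}, row {i}: {exc}") from None
        records.append(rec)
    return records


def write_diagnoses(records: Sequence[DiagnosisRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_DIAG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phecode map
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["phecode", "icd", "system", "exclude_low", "exclude_high"]


def read_phecode_map(path) -> list[PhecodeMapEntry]:
    """Read the phecode↔ICD map (CSV dialect of the public map)."""
    df = _read_table(path, sep=",", required=_MAP_COLUMNS)
    entries: list[PhecodeMapEntry] = []
    seen: dict[tuple[str, str], tuple[str, int]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        lo, hi = row.exclude_low, row.exclude_high
        if pd.isna(lo) or str(lo).strip() == "":
            exclusion = None
        else:
            try:
                exclusion = (float(lo), float(hi))
            except (TypeError, ValueError):
                raise ValidationError(f"{path}, row {i}: malformed exclusion bounds") from None
        entry = PhecodeMapEntry(
            phecode=str(row.phecode).strip(),
            system=str(row.system).strip().upper(),
            code_pattern=normalize_code(str(row.icd)),
            exclusion_range=exclusion,
        )
        try:
            entry.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        key = (entry.system, entry.code_pattern)
        if key in seen:
            prev_phecode, prev_row = seen[key]
            if prev_phecode != entry.phecode:
                raise ValidationError(
                    f"{path}: conflicting phecodes for {key}: "
                    f"{prev_phecode!r} (row {prev_row}) vs {entry.phecode!r} (row {i})"
                )
        seen[key] = (entry.phecode, i)
        entries.append(entry)
    return entries


def write_phecode_map(entries: Sequence[PhecodeMapEntry], path) -> None:
    rows = []
    for e in entries:
        lo, hi = e.exclusion_range if e.exclusion_range is not None else ("", "")
        rows.append(
            {"phecode": e.phecode, "icd": e.code_pattern, "system": e.system,
             "exclude_low": lo, "exclude_high": hi}
        )
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_SUMSTAT_COLUMNS = ["rsid", "effect_allele", "other_allele", "beta", "se", "eaf", "trait"]


def read_summary_stats(path) -> list[SummaryStatRecord]:
    df = _read_table(path, sep="\t", required=_SUMSTAT_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        rec = SummaryStatRecord(
            rsid=str(row.rsid),
            effect_allele=str(row.effect_allele).strip().upper(),
            other_allele=str(row.other_allele).strip().upper(),
            beta=float(row.beta),
            se=float(row.se),
            eaf=eaf,
            trait=str(row.trait),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        records.append(rec)
    return records


def write_summary_stats(records: Sequence[SummaryStatRecord], path) -> None:
    rows = [
        {"rsid": r.rsid, "effect_allele": r.effect_allele, "other_allele": r.other_allele,
         "beta": r.beta, "se": r.se, "eaf": "" if r.eaf is None else r.eaf, "trait": r.trait}
        for r in records
    ]
    pd.DataFrame(rows, columns=_SUMSTAT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path) -> GenotypeMatrix:
    """Read a wide dosage TSV.

    First column ``person_id``; each remaining column is one variant,
    named ``rsid:counted_allele:other_allele``.  Missing dosages are the
    literal ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"], keep_default_na=False)
    if df.columns[0] != "person_id":
        raise FormatError(f"{path}: first column must be person_id")
    variant_ids, counted, other = [], [], []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 3:
            raise FormatError(f"{path}: variant column {col!r} not rsid:counted:other")
        variant_ids.append(parts[0])
        counted.append(parts[1].upper())
        other.append(parts[2].upper())
    dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(
        person_ids=[str(p) for p in df["person_id"]],
        variant_ids=variant_ids,
        dosage=dosage,
        counted_alleles=counted,
        other_alleles=other,
    )


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    if gm.counted_alleles is None or gm.other_alleles is None:
        raise ValidationError("cannot write genotypes without allele annotation")
    cols = [f"{v}:{c}:{o}" for v, c, o in zip(gm.variant_ids, gm.counted_alleles, gm.other_alleles)]
    df = pd.DataFrame(gm.dosage, columns=cols)
    df.insert(0, "person_id", gm.person_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read dosages from a minimal VCF (GT field only; ALT allele counted)."""
    import pysam  # deferred: only needed for VCF input

    vcf = pysam.VariantFile(str(path))
    person_ids = list(vcf.header.samples)
    variant_ids, counted, other, rows = [], [], [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(f"{path}: variant {rec.id} is not biallelic")
        variant_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        counted.append(str(rec.alts[0]).upper())
        other.append(str(rec.ref).upper())
        row = []
        for sample in person_ids:
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                row.append(np.nan)
            else:
                row.append(float(sum(1 for a in gt if a != 0)))
        rows.append(row)
    return GenotypeMatrix(
        person_ids=person_ids,
        variant_ids=variant_ids,
        dosage=np.array(rows, dtype=float).T if rows else np.empty((len(person_ids), 0)),
        counted_alleles=counted,
        other_alleles=other,
    )


# ---------------------------------------------------------------------------
# ICD-10 hierarchy edge list
# ---------------------------------------------------------------------------


def read_hierarchy(path) -> list[tuple[str, str]]:
    """Read the ICD-10 hierarchy as (parent, child) edges (TSV)."""
    df = _read_table(path, sep="\t", required=["parent", "child"])
    return [(str(p), str(c)) for p, c in zip(df["parent"], df["child"])]


def write_hierarchy(edges: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["parent", "child"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_table(path, sep: str, required: list[str], allow_empty: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty and not allow_empty:
        logger.warning("table %s has a header but no rows", path)
    return df
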