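"""Synthetic biobank generator.

Produces cohorts with the statistical structure the analysis pipeline
assumes: independent biallelic variants, a continuous exposure (urate-like,
mg/dL scale) with a configurable fraction of variance explained by the
variants, mediator traits (obesity / blood-pressure / lipid / glucose-like)
receiving pleiotropic effects from subsets of the variants, and binary
diseases generated under a liability-threshold model that emit 4-character
ICD-10 codes.  A separate routine draws two-sample GWAS summary statistics
from independent exposure- and outcome-cohort sampling distributions for
the MR replication stage.

The default configuration emulates the urate instrument: 31 loci explaining
about 7% of exposure variance, of which 14 are exposure-specific (7 of
those tagged as renal-handling loci) and 17 are pleiotropic on the four
mediators with category sizes 10 (obesity), 10 (BP), 6 (lipid) and
3 (glucose), overlapping as those counts require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import logging

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    DiagnosisRecord,
    GenotypeMatrix,
    VariantWeight,
    normalize_code,
)

logger = logging.getLogger(__name__)

# named substreams fanned out from the global seed, so each stage is
# individually reproducible
_STAGES = {
    "genotypes": 11,
    "traits": 12,
    "diagnoses": 13,
    "summary_exposure": 14,
    "summary_outcome": 15,
    "pvalues": 16,
}

MEDIATOR_NAMES = ("obesity", "bp", "lipid", "glucose")

#: metabolic traits scanned for pleiotropy, grouped by category
TRAIT_GROUPS: dict[str, tuple[str, ...]] = {
    "obesity": ("BMI", "WHR"),
    "bp": ("SBP", "DBP"),
    "lipid": ("TC", "LDL-c", "HDL-c"),
    "glucose": ("fasting_glucose", "2h_glucose", "glycoproteins"),
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), _STAGES[stage]]))


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class VariantSpec:
    rsid: str
    eaf: float
    beta_urate: float
    effect_allele: str = "A"
    other_allele: str = "G"


@dataclass(frozen=True)
class DiseaseSpec:
    """Liability-threshold disease emitting one 4-character ICD-10 code.

    ``w_exposure`` weights the standardized exposure in the liability;
    ``mediator_weights`` weight the standardized mediators.  Prevalence
    fixes the liability threshold.
    """

    icd10_code: str
    prevalence: float
    w_exposure: float = 0.0
    mediator_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_individuals: int
    variants: list[VariantSpec]
    target_r2: float = 0.07
    pleiotropy_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    mediators: list[tuple[str, float]] = field(default_factory=list)
    diseases: list[DiseaseSpec] = field(default_factory=list)
    renal_rsids: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if not (0.0 < self.target_r2 < 1.0):
            raise ConfigError("target_r2 must lie in (0,1)")
        for v in self.variants:
            if not (0.0 < v.eaf < 1.0):
                raise ConfigError(f"{v.rsid}: eaf outside (0,1)")
        rsids = {v.rsid for v in self.variants}
        mediator_names = {name for name, _ in self.mediators}
        for rsid, effects in self.pleiotropy_map.items():
            if rsid not in rsids:
                raise ConfigError(f"pleiotropy_map rsid {rsid} not among variants")
            for mediator, _ in effects:
                if mediator not in mediator_names:
                    raise ConfigError(f"unknown mediator {mediator!r} for {rsid}")
        for d in self.diseases:
            if not (0.0 < d.prevalence < 1.0):
                raise ConfigError(f"{d.icd10_code}: prevalence outside (0,1)")
            for m in d.mediator_weights:
                if m not in mediator_names:
                    raise ConfigError(f"{d.icd10_code}: unknown mediator {m!r}")

    # -- (de)serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_individuals": self.n_individuals,
            "target_r2": self.target_r2,
            "seed": self.seed,
            "variants": [
                {"rsid": v.rsid, "eaf": v.eaf, "beta_urate": v.beta_urate,
                 "effect_allele": v.effect_allele, "other_allele": v.other_allele}
                for v in self.variants
            ],
            "pleiotropy_map": {
                rsid: [[m, float(g)] for m, g in effects]
                for rsid, effects in self.pleiotropy_map.items()
            },
            "mediators": [[name, float(sd)] for name, sd in self.mediators],
            "diseases": [
                {"icd10_code": d.icd10_code, "prevalence": d.prevalence,
                 "w_exposure": d.w_exposure, "mediator_weights": dict(d.mediator_weights)}
                for d in self.diseases
            ],
            "renal_rsids": list(self.renal_rsids),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        cfg = cls(
            n_individuals=int(doc["n_individuals"]),
            variants=[VariantSpec(**v) for v in doc["variants"]],
            target_r2=float(doc.get("target_r2", 0.07)),
            pleiotropy_map={
                rsid: [(m, float(g)) for m, g in effects]
                for rsid, effects in doc.get("pleiotropy_map", {}).items()
            },
            mediators=[(name, float(sd)) for name, sd in doc.get("mediators", [])],
            diseases=[DiseaseSpec(**d) for d in doc.get("diseases", [])],
            renal_rsids=list(doc.get("renal_rsids", [])),
            seed=int(doc.get("seed", 0)),
        )
        cfg.validate()
        return cfg


@dataclass
class CohortData:
    """One simulated cohort: genotypes, trait table and diagnosis list."""

    genotypes: GenotypeMatrix
    traits: pd.DataFrame  # indexed by person_id
    diagnoses: list[DiagnosisRecord]


# ---------------------------------------------------------------------------
# default configuration (the packaged study conditions)
# ---------------------------------------------------------------------------

# EAFs: fixed spread over (0.08, 0.9); betas: two large renal-transporter-like
# loci and 29 smaller loci, calibrated only in aggregate (target_r2)
_DEFAULT_EAFS = [
    0.25, 0.25, 0.12, 0.68, 0.45, 0.33, 0.55, 0.78, 0.20, 0.42,
    0.61, 0.30, 0.85, 0.50, 0.38, 0.22, 0.73, 0.48, 0.15, 0.58,
    0.35, 0.66, 0.27, 0.52, 0.40, 0.18, 0.62, 0.44, 0.31, 0.70,
    0.26,
]
_DEFAULT_BETAS = [
    0.373, 0.217, 0.059, 0.047, 0.042, 0.050, 0.044, 0.039, 0.055, 0.046,
    0.041, 0.049, 0.061, 0.043, 0.048, 0.052, 0.040, 0.045, 0.057, 0.044,
    0.050, 0.042, 0.047, 0.053, 0.046, 0.058, 0.041, 0.049, 0.051, 0.043,
    0.054,
]
# pleiotropy category membership by variant index (0-based); indices 0-13
# are exposure-specific, 0-6 renal-handling
_CATEGORY_INDICES = {
    "obesity": list(range(14, 24)),
    "bp": [20, 21, 22, 23, 24, 25, 26, 27, 29, 30],
    "lipid": [24, 25, 26, 27, 28, 30],
    "glucose": [28, 29, 30],
}
_GAMMA = 0.20  # per-allele pleiotropic effect on each flagged mediator

_ALLELE_CYCLE = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

_DEFAULT_DISEASES = [
    DiseaseSpec("M10.0", 0.015, w_exposure=1.2),                      # gout-like
    DiseaseSpec("I10", 0.15, mediator_weights={"bp": 0.5}),           # hypertension
    DiseaseSpec("I21.0", 0.03, mediator_weights={"bp": 0.3, "lipid": 0.3}),
    DiseaseSpec("I25.1", 0.05, mediator_weights={"bp": 0.2, "lipid": 0.4}),
    DiseaseSpec("I50.1", 0.02, mediator_weights={"bp": 0.4}),         # heart failure
    DiseaseSpec("E78.0", 0.10, mediator_weights={"lipid": 0.5}),      # hypercholesterolemia
    DiseaseSpec("E11.9", 0.05, mediator_weights={"glucose": 0.5}),    # type-2-diabetes-like
    DiseaseSpec("E66.0", 0.08, mediator_weights={"obesity": 0.5}),
    DiseaseSpec("J45.9", 0.08),                                       # null diseases
    DiseaseSpec("K21.9", 0.06),
    DiseaseSpec("N39.0", 0.04),
]


def default_config(n_individuals: int = 50_000, seed: int = 0) -> SimulationConfig:
    """The packaged default: 31 loci, R²=0.07, four mediators, 11 diseases."""
    variants = []
    for i, (eaf, beta) in enumerate(zip(_DEFAULT_EAFS, _DEFAULT_BETAS)):
        ea, oa = _ALLELE_CYCLE[i % len(_ALLELE_CYCLE)]
        if i in (2, 12):  # two palindromic loci, far from eaf 0.5 so alignable
            ea, oa = ("A", "T") if i == 2 else ("C", "G")
        variants.append(VariantSpec(f"rs{1001 + i}", eaf, beta, ea, oa))
    pleiotropy_map: dict[str, list[tuple[str, float]]] = {}
    for category, indices in _CATEGORY_INDICES.items():
        for i in indices:
            pleiotropy_map.setdefault(variants[i].rsid, []).append((category, _GAMMA))
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        variants=variants,
        target_r2=0.07,
        pleiotropy_map=pleiotropy_map,
        mediators=[(name, 1.0) for name in MEDIATOR_NAMES],
        diseases=list(_DEFAULT_DISEASES),
        renal_rsids=[variants[i].rsid for i in range(7)],
        seed=seed,
    )
    cfg.validate()
    return cfg


def true_categories(config: SimulationConfig) -> dict[str, set[str]]:
    """Ground-truth pleiotropy category membership implied by the config."""
    cats: dict[str, set[str]] = {name: set() for name, _ in config.mediators}
    for rsid, effects in config.pleiotropy_map.items():
        for mediator, gamma in effects:
            if gamma != 0.0:
                cats[mediator].add(rsid)
    return cats


def instrument_weights(
    config: SimulationConfig, n_discovery: int = 110_000
) -> list[VariantWeight]:
    """Instrument-weight records implied by the config.

    SEs follow the usual GWAS scaling 1/sqrt(2p(1-p)·n) for a unit-variance
    trait, with ``n_discovery`` emulating the discovery meta-analysis size.
    """
    out = []
    for v in config.variants:
        se = 1.0 / np.sqrt(2.0 * v.eaf * (1.0 - v.eaf) * n_discovery)
        out.append(
            VariantWeight(v.rsid, v.effect_allele, v.other_allele, v.beta_urate, se, v.eaf)
        )
    return out


# ---------------------------------------------------------------------------
# simulation stages
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypeMatrix:
    """Draw dosages ~ Binomial(2, eaf), independent across variants."""
    config.validate()
    rng = rng if rng is not None else stage_rng(config.seed, "genotypes")
    n, m = config.n_individuals, len(config.variants)
    eafs = np.array([v.eaf for v in config.variants])
    dosage = rng.binomial(2, eafs, size=(n, m)).astype(float)
    return GenotypeMatrix(
        person_ids=[f"P{i:07d}" for i in range(n)],
        variant_ids=[v.rsid for v in config.variants],
        dosage=dosage,
        counted_alleles=[v.effect_allele for v in config.variants],
        other_alleles=[v.other_allele for v in config.variants],
    )


def simulate_traits(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Exposure, mediators and covariates for each individual.

    The exposure is ``G·beta + eps`` with the noise variance set so that
    the genetic score explains ``target_r2`` of the exposure variance
    (computed against the realized score variance).  Mediators receive
    only their pleiotropy-map variants.  Assessment center and the first
    principal-component score are given small correlations with the true
    score, so covariate screening has signal; sex, age, BMI and PC2-PC5
    are independent of genotype.
    """
    rng = rng if rng is not None else stage_rng(config.seed, "traits")
    n = genotypes.n_individuals
    betas = np.array([v.beta_urate for v in config.variants])
    G = genotypes.dosage
    true_score = G @ betas
    var_g = float(np.var(true_score))
    if var_g <= 0:
        # degenerate null: no genetic signal, exposure is pure unit noise
        logger.warning("genetic score has zero variance; exposure is pure noise")
        eps_sd = 1.0
    else:
        eps_sd = np.sqrt(var_g * (1.0 - config.target_r2) / config.target_r2)
    exposure = true_score + rng.normal(0.0, eps_sd, n)

    rsid_index = {r: j for j, r in enumerate(genotypes.variant_ids)}
    traits = pd.DataFrame(index=pd.Index(genotypes.person_ids, name="person_id"))
    traits["urate"] = exposure
    for name, noise_sd in config.mediators:
        genetic = np.zeros(n)
        for rsid, effects in config.pleiotropy_map.items():
            for mediator, gamma in effects:
                if mediator == name:
                    genetic += gamma * G[:, rsid_index[rsid]]
        traits[name] = genetic + rng.normal(0.0, noise_sd, n)

    z_score = (true_score - true_score.mean()) / max(true_score.std(), 1e-12)
    traits["sex"] = rng.binomial(1, 0.54, n)
    traits["age"] = rng.normal(56.9, 8.0, n)
    traits["bmi"] = rng.normal(27.4, 4.76, n)
    center_latent = 0.05 * z_score + rng.normal(0.0, 1.0, n)
    traits["center"] = np.digitize(center_latent, [-0.43, 0.43])
    traits["pc1"] = 0.03 * z_score + rng.normal(0.0, 1.0, n)
    for k in range(2, 6):
        traits[f"pc{k}"] = rng.normal(0.0, 1.0, n)
    return traits


def simulate_diagnoses(
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    known_codes: Optional[set[str]] = None,
) -> list[DiagnosisRecord]:
    """Liability-threshold diseases; one hospital ICD-10 record per case.

    liability = w·z(traits) + N(0,1); the case threshold is the normal
    quantile of the configured prevalence on the realized liability scale.
    ``known_codes`` (normalized) restricts emissions to codes present in
    the packaged hierarchy; a disease outside it is a config error.
    """
    from scipy.stats import norm

    rng = rng if rng is not None else stage_rng(config.seed, "diagnoses")
    if known_codes is None:
        known_codes = _packaged_code_closure()
    records: list[DiagnosisRecord] = []
    n = len(traits)
    z = {}
    for col in ["urate"] + [name for name, _ in config.mediators]:
        x = traits[col].to_numpy()
        z[col] = (x - x.mean()) / max(x.std(), 1e-12)
    for disease in config.diseases:
        code = normalize_code(disease.icd10_code)
        if code[:3] not in known_codes:
            raise ConfigError(f"disease code {disease.icd10_code} absent from ICD-10 tree")
        core = disease.w_exposure * z["urate"]
        for mediator, w in disease.mediator_weights.items():
            core = core + w * z[mediator]
        liability = core + rng.normal(0.0, 1.0, n)
        scale = np.sqrt(float(np.var(core)) + 1.0)
        threshold = norm.ppf(1.0 - disease.prevalence) * scale
        for pid in traits.index[liability > threshold]:
            records.append(DiagnosisRecord(str(pid), "ICD10", code, "hospital"))
    return records


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Run the three stages with per-stage substreams of ``config.seed``."""
    genotypes = simulate_genotypes(config)
    traits = simulate_traits(genotypes, config)
    diagnoses = simulate_diagnoses(traits, config)
    return CohortData(genotypes, traits, diagnoses)


def simulate_summary_stats(
    config: SimulationConfig,
    n_outcome_cohort: int,
    causal_effect: float = 0.0,
    mediator_loadings: Optional[dict[str, float]] = None,
    outcome_name: str = "outcome",
    n_exposure_cohort: int = 110_000,
    seed: Optional[int] = None,
):
    """Two-sample summary statistics from independent cohorts.

    The per-allele outcome effect of variant j is
    ``causal_effect·beta_j + Σ_m loading_m·gamma_jm`` (pleiotropic paths
    through the mediators); exposure- and outcome-side estimates are
    drawn around the truth with SEs scaling as 1/sqrt(2p(1-p)·n).
    Returns an :class:`~phemr.mr.MRSummarySet` already harmonized to the
    exposure-increasing allele.
    """
    from .mr import MRSummarySet

    seed = config.seed if seed is None else seed
    rng_x = stage_rng(seed, "summary_exposure")
    rng_y = stage_rng(seed, "summary_outcome")
    loadings = mediator_loadings or {}
    gamma = {
        rsid: dict(effects) for rsid, effects in config.pleiotropy_map.items()
    }
    rsids, bx, sx, by, sy = [], [], [], [], []
    for v in config.variants:
        het = 2.0 * v.eaf * (1.0 - v.eaf)
        se_x = 1.0 / np.sqrt(het * n_exposure_cohort)
        se_y = 1.0 / np.sqrt(het * n_outcome_cohort)
        pleio = sum(
            loadings.get(m, 0.0) * g for m, g in gamma.get(v.rsid, {}).items()
        )
        truth_y = causal_effect * v.beta_urate + pleio
        rsids.append(v.rsid)
        bx.append(rng_x.normal(v.beta_urate, se_x))
        sx.append(se_x)
        by.append(rng_y.normal(truth_y, se_y))
        sy.append(se_y)
    return MRSummarySet(
        rsids=rsids,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        exposure="urate",
        outcome=outcome_name,
    )


def simulate_pleiotropy_pvalues(
    config: SimulationConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Cross-trait p-value table (rsid × metabolic trait) with known truth.

    Variants flagged for a category receive genome-wide-significant
    p-values on the traits of that category's group; unflagged pairs draw
    from (0.05, 1), clear of any sensible pleiotropy threshold, so the
    configured truth table is recoverable exactly.
    """
    seed = config.seed if seed is None else seed
    rng = stage_rng(seed, "pvalues")
    cats = true_categories(config)
    traits = [t for group in TRAIT_GROUPS.values() for t in group]
    rows = {}
    for v in config.variants:
        row = {}
        for category, group in TRAIT_GROUPS.items():
            flagged = v.rsid in cats.get(category, set())
            for trait in group:
                if flagged:
                    row[trait] = 10.0 ** rng.uniform(-12.0, -4.0)
                else:
                    row[trait] = rng.uniform(0.05, 1.0)
        rows[v.rsid] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=traits).rename_axis("rsid")


def _packaged_code_closure() -> set[str]:
    """3-character ICD-10 codes present in the packaged hierarchy."""
    from .phenome import packaged_hierarchy

    return {
        node for edge in packaged_hierarchy() for node in edge
        if len(node) == 3 and node[0].isalpha() and node[1:].isdigit()
    }
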