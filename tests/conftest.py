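import numpy as np
import pytest

from phemr import grs as grs_mod
from phemr import phenome as phenome_mod
from phemr import synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged study conditions: n=50,000, seed 0."""
    cfg = synthetic.default_config(50_000, seed=0)
    return cfg, synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_grs(default_cohort):
    cfg, cohort = default_cohort
    weights = synthetic.instrument_weights(cfg)
    aligned = grs_mod.harmonize(weights, cohort.genotypes.variant_metadata())
    return grs_mod.compute_grs(cohort.genotypes, aligned)


@pytest.fixture(scope="session")
def default_phenome(default_cohort):
    cfg, cohort = default_cohort
    pmap = phenome_mod.packaged_map()
    assignments = phenome_mod.map_to_phecodes(cohort.diagnoses, pmap)
    kept, _ = phenome_mod.build_all_case_controls(
        assignments, pmap, cohort.genotypes.person_ids, min_cases=20
    )
    return kept


@pytest.fixture(scope="session")
def screened_covariates(default_cohort, default_grs):
    _, cohort = default_cohort
    candidates = cohort.traits[
        ["sex", "age", "bmi", "center", "pc1", "pc2", "pc3", "pc4", "pc5"]
    ]
    selected = grs_mod.screen_covariates(default_grs, candidates, categorical=["center"])
    return cohort.traits[selected]


@pytest.fixture()
def small_config():
    return synthetic.default_config(2_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
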