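import numpy as np
import pytest

from rareqtl.io import CovariateTable
from rareqtl.simdata import (
    CovariateEffects,
    GeneSpec,
    SimulationConfig,
    simulate_covariates,
    simulate_genotypes,
    simulate_traits,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Small mixed study: 2 risk genes + nulls, 120 subjects, 2 populations."""
    return SimulationConfig(
        gene_specs=[
            GeneSpec(
                gene="RISK1", n_rare=6, n_causal_rare=3, n_common=3,
                n_causal_common=1, rare_maf_range=(0.01, 0.04),
                common_maf_range=(0.1, 0.3), beta_rare=0.8, beta_common=0.5,
                ld_rho=0.2,
            ),
            GeneSpec(
                gene="RISK2", n_rare=5, n_causal_rare=2, n_common=0,
                rare_maf_range=(0.01, 0.04), beta_rare=0.8, ld_rho=0.0,
            ),
        ],
        n_null_genes=3,
        null_gene_template=GeneSpec(
            gene="NULL", n_rare=6, n_common=3,
            rare_maf_range=(0.01, 0.04), common_maf_range=(0.1, 0.3),
        ),
        n_subjects=120,
        n_populations=2,
        covariate_effects=CovariateEffects(sex=0.5, age=0.01, smoking=0.3),
        n_replicates=5,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    sim = simulate_genotypes(tiny_config)
    cov = simulate_covariates(tiny_config)
    q1, q4 = simulate_traits(sim, cov, tiny_config)
    return {"sim": sim, "cov": cov, "q1": q1, "q4": q4, "config": tiny_config}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_covariates(rng):
    """Raw covariate design matrix for n=200 (sex, age, smoking)."""
    n = 200
    return np.column_stack([
        rng.binomial(1, 0.5, n).astype(float),
        rng.normal(50, 10, n),
        rng.binomial(1, 0.3, n).astype(float),
    ])


def make_covariate_table(n, rng, n_pop=2):
    return CovariateTable(
        subject_ids=[f"S{i + 1:04d}" for i in range(n)],
        sex=rng.binomial(1, 0.5, n),
        age=rng.normal(50, 10, n),
        smoking=rng.binomial(1, 0.3, n),
        population=np.array([f"P{p + 1}" for p in rng.integers(0, n_pop, n)]),
    )
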