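import numpy as np
import pytest

import eqtlnet as eq


def make_planted_dataset(
    n_samples: int,
    seed: int,
    n_snps: int = 200,
    n_genes: int = 50,
    n_cis: int = 40,
    n_trans: int = 10,
    beta_cis: float = 1.0,
    beta_trans: float = 0.5,
    noise_sd: float = 1.0,
    n_covariates: int = 3,
):
    """Genotypes, expression with planted eQTL architecture, covariates."""
    G = eq.simulate_genotypes(n_samples, n_snps, seed=seed)
    genes = eq.simulate_genes(n_genes, seed=seed + 1)
    X = eq.simulate_covariates(n_samples, n_covariates, seed=seed + 2)
    arch = eq.random_architecture(
        G, genes, n_cis, n_trans, beta_cis, beta_trans, noise_sd=noise_sd,
        covariate_effect_sd=0.3, n_covariates=n_covariates, seed=seed + 3)
    E = eq.simulate_expression(G, genes, arch, X, seed=seed + 4)
    return G, genes, X, arch, E


def make_null_dataset(n_samples: int, seed: int, n_snps: int = 200,
                      n_genes: int = 50, n_covariates: int = 3):
    """Expression independent of genotype (no planted effects)."""
    G = eq.simulate_genotypes(n_samples, n_snps, seed=seed)
    genes = eq.simulate_genes(n_genes, seed=seed + 1)
    X = eq.simulate_covariates(n_samples, n_covariates, seed=seed + 2)
    arch = eq.PlantedArchitecture([], noise_sd=1.0)
    E = eq.simulate_expression(G, genes, arch, None, seed=seed + 4)
    return G, genes, X, arch, E


@pytest.fixture(scope="session")
def planted_400():
    return make_planted_dataset(400, seed=11)


@pytest.fixture(scope="session")
def mapped_400(planted_400):
    G, genes, X, arch, E = planted_400
    return eq.map_eqtls(G, E, X)
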