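import numpy as np
import pytest

from wgrvar import (MCMCConfig, SimSpec, build_covariate_matrix,
                    center_genotypes, prepare_cohort, simulate_dataset)


@pytest.fixture(scope="session")
def small_spec():
    """A compact synthetic study: 200 subjects, 400 variants, 4 genes."""
    return SimSpec(n_subjects=200, n_variants=400, n_genes=4,
                   gene_length_bp=10_000, flank_bp=50_000,
                   chrom_length_bp=1_000_000, n_causal=80, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_sim, small_spec):
    """Analysis-ready (y, Z, Xc) aligned across phenotypes and genotypes."""
    cohort, transform = prepare_cohort(small_sim["phenotypes"])
    order = {f"S{i + 1:05d}": i for i in range(small_spec.n_subjects)}
    rows = [order[s] for s in cohort["subject_id"]]
    Xc, freq = center_genotypes(small_sim["X"][rows])
    y = cohort["y"].to_numpy()
    Z, names = build_covariate_matrix(cohort)
    return {"cohort": cohort, "y": y, "Z": Z, "Xc": Xc,
            "transform": transform}


@pytest.fixture()
def short_mcmc():
    return MCMCConfig(n_iter=1_500, burn_in=300, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
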