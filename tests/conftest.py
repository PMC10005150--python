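"""Shared fixtures: one moderately sized simulated population reused across
module test suites (session-scoped to keep the run fast)."""

import numpy as np
import pytest

from lupinqg import geno_qc, simpop


@pytest.fixture(scope="session")
def sim_config():
    return simpop.SimConfig(n_markers=1200, n_chromosomes=12,
                            pool_differentiation=0.4, seed=42)


@pytest.fixture(scope="session")
def population(sim_config):
    return simpop.simulate_population(sim_config)


@pytest.fixture(scope="session")
def gm_complete(population):
    """Filtered, fully observed genotype matrix (no masking applied)."""
    gm = geno_qc.genotype_matrix_from_population(population)
    gm, _ = geno_qc.filter_genotypes(gm)
    return gm


@pytest.fixture(scope="session")
def cross_labels(gm_complete):
    return np.array([s.split("_")[0] for s in gm_complete.samples])


@pytest.fixture(scope="session")
def trial(population, sim_config):
    arch = simpop.default_architectures()
    return simpop.simulate_trial(population, arch, sim_config,
                                 rng=np.random.default_rng(7))
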