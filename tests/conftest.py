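"""Shared fixtures: small synthetic designs reused across test modules."""

import numpy as np
import pytest

from plastivec import synthdata


@pytest.fixture(scope="session")
def small_design() -> synthdata.SimulationDesign:
    """A fast 2-species x 4-site design with modest replication."""
    return synthdata.SimulationDesign(
        n_genotypes_per_species=8,
        n_blocks_per_site=2,
        n_clones_per_genotype_block=2,
        n_genes=200,
        n_genotypes_expression=6,
        n_clones_expression=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_traits(small_design):
    return synthdata.simulate_traits(small_design)


@pytest.fixture(scope="session")
def small_survival(small_design):
    return synthdata.simulate_survival(small_design)


@pytest.fixture(scope="session")
def small_counts(small_design):
    return synthdata.simulate_counts(small_design)


def constant_mean_design(**kwargs) -> synthdata.SimulationDesign:
    """Design with flat cell means (value 5) for one trait; no structure."""
    defaults = dict(
        n_genotypes_per_species=4,
        n_blocks_per_site=2,
        n_clones_per_genotype_block=2,
        trait_fixed_effects={"t1": np.full((2, 4), 5.0)},
        var_genotype_by_site=0.0,
        var_block=0.0,
        var_residual=0.0,
        seed=7,
    )
    defaults.update(kwargs)
    return synthdata.SimulationDesign(**defaults)
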