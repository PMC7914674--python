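"""Shared fixtures: small grids, catalogs and datasets built at test time."""

import numpy as np
import pytest

from nirgan import (
    RunConfig,
    WavenumberGrid,
    ClassCatalog,
    reference_catalog,
    sample_archetypes,
    derive_manufacturer_profiles,
    generate_dataset,
    stratified_split,
)


@pytest.fixture(scope="session")
def small_grid():
    return WavenumberGrid(4000.0, 11995.0, 64)


@pytest.fixture(scope="session")
def tiny_catalog():
    # 6 manufacturers over 2 drugs, class sizes big enough to split
    return ClassCatalog(tuple([
        (1, 1, 12), (2, 1, 8), (3, 1, 20),
        (4, 2, 10), (5, 2, 6), (6, 2, 15),
    ]))


@pytest.fixture(scope="session")
def tiny_dataset(small_grid, tiny_catalog):
    arch = sample_archetypes(2, small_grid, rng_seed=7)
    profiles = derive_manufacturer_profiles(arch, tiny_catalog, 0.05, rng_seed=8)
    return generate_dataset(profiles, tiny_catalog, noise_sd=0.01, grid=small_grid,
                            rng_seed=9, scatter_sd=0.05)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return stratified_split(tiny_dataset, 0.7, rng_seed=11)


@pytest.fixture(scope="session")
def table_catalog():
    return reference_catalog()
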