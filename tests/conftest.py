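from __future__ import annotations

import numpy as np
import pytest

from pedassoc.pedigree import build_a_matrix
from pedassoc.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size daughter-design dataset (506 daughters, 8 sires)."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def default_A(default_dataset):
    return build_a_matrix(default_dataset.pedigree)


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    write_dataset(default_dataset, out, vcf=True)
    return out


@pytest.fixture(scope="session")
def unrelated_config():
    """Independent individuals: one daughter per sire kills family structure."""
    def make(n: int, seed: int, missing_rate: float = 0.0) -> SimulationConfig:
        return SimulationConfig(
            n_sires=n, n_daughters=n, missing_rate=missing_rate, seed=seed
        )
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
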