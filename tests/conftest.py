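from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from flexms import (
    FeatureTable,
    ScenarioConfig,
    simulate_dataset,
    tiny_config,
)
from flexms.io_formats import read_newick
from flexms.synthetic_data import _random_topology

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def tiny_bundle():
    """Pinned 8-sample / 12-taxa scenario (same seed as the committed fixture)."""
    return simulate_dataset(tiny_config())


@pytest.fixture(scope="session")
def default_bundle():
    """One realization of the default 100-sample scenario."""
    return simulate_dataset(ScenarioConfig(seed=7))


@pytest.fixture
def tiny_fixture_dir() -> Path:
    return DATA / "tiny"


def random_tree(rng: np.random.Generator, n_leaves: int, prefix: str = "L"):
    """Random rooted binary phylogeny with branch lengths in [0.05, 0.3]."""
    leaves = [f"{prefix}{i}" for i in range(n_leaves)]
    return read_newick(_random_topology(list(leaves), rng, 1.0)), leaves


def random_table(rng: np.random.Generator, leaves, n_samples: int,
                 sparsity: float = 0.3) -> FeatureTable:
    """Random sparse positive relative-abundance table over the leaves."""
    vals = rng.gamma(0.7, 1.0, size=(len(leaves), n_samples))
    vals[rng.random(vals.shape) < sparsity] = 0.0
    vals[0] += 1e-3  # keep every sample non-empty
    return FeatureTable(
        pd.DataFrame(vals, index=list(leaves),
                     columns=[f"S{i}" for i in range(n_samples)])
    )
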