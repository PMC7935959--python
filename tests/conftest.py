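"""Shared fixtures: small synthetic datasets with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import consica as ci
from consica.decomposition import MixingMatrix
from consica.io import GeneSetCollection
from consica.simulate import planted_collection


@pytest.fixture(scope="session")
def planted_fixture():
    """Small planted-source dataset: 120 genes x 300 samples, 6 sources."""
    X, truth = ci.generate_expression(
        n_genes=120, n_samples=300, k=6, set_size=12, noise_sd=0.05, seed=2024
    )
    return X, truth


@pytest.fixture(scope="session")
def decomposed(planted_fixture):
    """Whitened basis, consensus sources and gene-space mixing matrix."""
    X, truth = planted_fixture
    basis = ci.whiten(X)
    mm_w, sources, report = ci.run_consensus_ica(basis, seed=77)
    MM = ci.recompute_mixing(X, sources, mm_w)
    return basis, sources, MM, report


@pytest.fixture(scope="session")
def planted_sets(planted_fixture):
    X, truth = planted_fixture
    return planted_collection(truth, X.gene_ids)


@pytest.fixture(scope="session")
def random_mixing():
    """Structure-free Gaussian mixing matrix, 80 genes x 5 components."""
    rng = np.random.default_rng(7)
    W = rng.normal(size=(80, 5))
    return MixingMatrix(
        gene_ids=[f"G{i + 1}" for i in range(80)],
        component_ids=[f"TC{j + 1}" for j in range(5)],
        weights=W,
        credibility=np.ones(5),
    )


@pytest.fixture
def toy_collection():
    """Universe of 100 genes; one gene (G1) in a 10-set and a 20-set."""
    universe = [f"G{i + 1}" for i in range(100)]
    return GeneSetCollection(
        name="toy",
        universe=frozenset(universe),
        sets={
            "TEN": tuple(universe[:10]),        # G1..G10
            "TWENTY": tuple([universe[0]] + universe[10:29]),  # G1 + 19 others
        },
        size_bounds=(10, 500),
    )
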