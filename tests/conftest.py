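"""Shared fixtures: toy similarity structures and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pytest

from ibsmatch import Phenotype, SimilarityMatrix, pack_genotypes
from ibsmatch.popsim import sample_h0_study, scaled_design


def block_similarity(sizes, within, between, diag=1.0):
    """Block-constant similarity matrix for the given block sizes."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    s = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(s, diag)
    return SimilarityMatrix(scores=s, n_pairwise_loci=np.full((n, n), 100)), labels


@pytest.fixture
def two_block_sim():
    """10 + 10 individuals, within-block 0.9, between 0.1."""
    sim, labels = block_similarity((10, 10), 0.9, 0.1)
    return sim, labels


@pytest.fixture
def random_genotypes():
    rng = np.random.default_rng(42)
    codes = rng.integers(0, 3, size=(30, 120)).astype(np.uint8)
    miss = rng.random(codes.shape) < 0.05
    codes[miss] = 3
    return pack_genotypes(codes), codes


@pytest.fixture(scope="session")
def small_study():
    """A small stratified null study shared by slower integration tests."""
    return sample_h0_study(scaled_design(n_snps=500), 123)


@pytest.fixture
def balanced_phenotype():
    return Phenotype(np.array([0, 0, 1, 1], dtype=np.int8))
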