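"""Shared fixtures: tiny hand-built matrices and the default synthetic screen."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import mescreen as ms


@pytest.fixture()
def tiny_matrix() -> ms.ExpressionMatrix:
    """3 genes x 2 samples, hand-checkable."""
    df = pd.DataFrame(
        [[0.0, 1.0], [3.0, 2.0], [1.0, 0.0]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["S1", "S2"],
    )
    return ms.ExpressionMatrix(df)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 600 samples, 8 phenotypes, 2000 genes, seed 1."""
    spec = ms.GeneratorSpec()
    matrix, truth = ms.generate(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Full hub-source screen on the default synthetic study (shared, read-only)."""
    matrix, truth = default_dataset
    ranks = ms.compute_rank_matrix(matrix)
    profile = ms.gene_plasticity(ranks)
    sorting = ms.virtual_sort(ranks, truth.hub_gene)
    cosines = ms.cosine_to_source(matrix, truth.hub_gene)
    candidates = ms.screen_me(sorting, cosines, plasticity=profile)
    return SimpleNamespace(
        matrix=matrix,
        truth=truth,
        ranks=ranks,
        profile=profile,
        sorting=sorting,
        cosines=cosines,
        candidates=candidates,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
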