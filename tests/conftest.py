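"""Shared fixtures: the default planted dataset and its fitted pipeline.

Session scope keeps the one moderately expensive end-to-end fit reusable
across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methplier as mp

DEFAULT_SEED = 17


@pytest.fixture(scope="session")
def default_manifest() -> pd.DataFrame:
    return mp.simulate_manifest(120, 1, 6, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_manifest):
    beta, sets, truth = mp.simulate_plier_dataset(default_manifest, seed=DEFAULT_SEED)
    return beta, sets, truth


@pytest.fixture(scope="session")
def default_compression(default_manifest, default_dataset):
    beta, _, _ = default_dataset
    probe_map = mp.select_region_probes(default_manifest)
    gene_map = (
        default_manifest.drop_duplicates("transcript_id")
        .set_index("transcript_id")["gene"]
    )
    model, scores = mp.fit_compression(beta, probe_map, transcript_gene_map=gene_map)
    return model, scores


@pytest.fixture(scope="session")
def default_fit(default_dataset, default_compression):
    """Knowledge matrix, aligned data and fitted factorization (k=6, seed 17)."""
    _, sets, _ = default_dataset
    _, scores = default_compression
    K = mp.build_feature_knowledge(sets, scores.feature_gene, min_genes=10)
    D = mp.align_to_knowledge(scores, K)
    model = mp.fit(D, K, mp.PlierConfig(k=6, seed=DEFAULT_SEED))
    return K, D, model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
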