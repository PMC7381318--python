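import numpy as np
import pytest

from coreselect import (
    DistanceMatrix,
    GenotypeMatrix,
    SyntheticConfig,
    generate_structured_population,
    mrd_matrix,
)


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """Two collections x 30 accessions, 200 complete markers."""
    cfg = SyntheticConfig(
        collection_sizes=(30, 30), n_markers=200, divergence=0.15, seed=42
    )
    return generate_structured_population(cfg)


@pytest.fixture(scope="session")
def small_mrd(small_panel) -> DistanceMatrix:
    return mrd_matrix(small_panel)


@pytest.fixture(scope="session")
def tiny_panel() -> GenotypeMatrix:
    """Eight accessions for exhaustive-subset oracles."""
    cfg = SyntheticConfig(
        collection_sizes=(4, 4), n_markers=30, divergence=0.2, seed=7
    )
    return generate_structured_population(cfg)


def make_matrix(calls, prefix_a="acc", prefix_m="m") -> GenotypeMatrix:
    """GenotypeMatrix from a plain accessions-by-markers list/array."""
    calls = np.asarray(calls, dtype=float)
    return GenotypeMatrix(
        accession_ids=[f"{prefix_a}{i+1}" for i in range(calls.shape[0])],
        marker_ids=[f"{prefix_m}{j+1}" for j in range(calls.shape[1])],
        calls=calls,
    )


def make_distance(values, metric="other") -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        accession_ids=[f"acc{i+1}" for i in range(values.shape[0])],
        values=values,
        metric=metric,
    )
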