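import numpy as np
import pytest

from tmedeconv import (
    ExpressionMatrix,
    MarkerSet,
    generate_mixture,
    generate_signatures,
)
from tmedeconv.containers import SampleMetadata
from tmedeconv.markers import build_labeling_matrix


@pytest.fixture(scope="session")
def five_type_mixture():
    """Noiseless 5-type mixture with disjoint markers (the identity case)."""
    S, marker_sets = generate_signatures(
        200, [f"type{k + 1}" for k in range(5)], markers_per_type=5,
        marker_fold=10.0, seed=11,
    )
    X, truth = generate_mixture(
        S, 60, [1.0] * 5, noise_sd=0.0, seed=11, marker_sets=marker_sets
    )
    labeling = build_labeling_matrix(marker_sets, X.gene_ids)
    return X, truth, labeling, marker_sets


@pytest.fixture(scope="session")
def exclusive_marker_mixture():
    """4-type mixture whose markers are expressed in one type only."""
    rng = np.random.default_rng(7)
    n_types, mpt = 4, 6
    S = np.zeros((n_types * mpt + 60, n_types))
    marker_sets = []
    g = 0
    for k in range(n_types):
        genes = []
        for _ in range(mpt):
            S[g, k] = rng.uniform(50, 150)
            genes.append(f"MK{k}_{g}")
            g += 1
        marker_sets.append(MarkerSet(f"type{k + 1}", tuple(genes)))
    S[g:, :] = rng.uniform(20, 60, size=(60, 1))
    X, truth = generate_mixture(
        S, 100, [5.0] * 4, noise_sd=0.05, seed=2, marker_sets=marker_sets
    )
    labeling = build_labeling_matrix(marker_sets, X.gene_ids)
    return X, truth, labeling, marker_sets


@pytest.fixture()
def tiny_matrix():
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture()
def two_group_metadata():
    return SampleMetadata(
        [f"S{j + 1:04d}" for j in range(20)],
        ["primary"] * 10 + ["metastasis"] * 10,
    )
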