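import numpy as np
import pandas as pd
import pytest

from enteroassembly.io import AsvTable


@pytest.fixture
def tiny_table() -> AsvTable:
    """3 samples x 4 taxa with easy totals."""
    return AsvTable(
        pd.DataFrame(
            [[3, 0, 1, 2], [1, 2, 0, 3], [0, 4, 4, 0]],
            index=["s1", "s2", "s3"],
            columns=["a", "b", "c", "d"],
        )
    )


@pytest.fixture
def two_blob_distance():
    """Distance matrix of two tight, well-separated blobs (6 + 6 samples)."""
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    rng = np.random.default_rng(5)
    pts = np.vstack([rng.normal(0, 0.05, (6, 2)), rng.normal(5, 0.05, (6, 2))])
    ids = [f"s{i}" for i in range(12)]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids), np.array([0] * 6 + [1] * 6)


@pytest.fixture
def newick_three_taxa() -> str:
    return "((A:1,B:1):1,C:2);"
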