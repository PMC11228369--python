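import logging

import numpy as np
import pandas as pd
import pytest

from scexemplar.io import ExpressionMatrix
from scexemplar.percluster import RankCentroid

logging.getLogger("scexemplar").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_counts():
    """3 genes x 2 cells dense count matrix."""
    df = pd.DataFrame(
        [[1, 0], [2, 2], [0, 5]],
        index=["g1", "g2", "g3"], columns=["c1", "c2"],
    )
    return ExpressionMatrix(df, unit="counts", dataset_id="toy")


def make_centroid(values, uid="u0", dataset="ds0", genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return RankCentroid(uid, pd.Series(values, index=genes, dtype=float),
                        n_cells=10, dataset_id=dataset)


@pytest.fixture()
def blob_dataset(rng):
    """Two well-separated expression blobs of 40 cells each over 100 genes."""
    base = rng.lognormal(1, 1, 100)
    a = base.copy()
    a[:10] *= 50
    b = base.copy()
    b[50:60] *= 50
    cells = []
    for i in range(40):
        cells.append(rng.poisson(a))
    for i in range(40):
        cells.append(rng.poisson(b))
    df = pd.DataFrame(
        np.array(cells).T,
        index=[f"g{i}" for i in range(100)],
        columns=[f"c{i}" for i in range(80)],
    )
    truth = np.array([0] * 40 + [1] * 40)
    return ExpressionMatrix(df, unit="counts", dataset_id="blobs"), truth
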