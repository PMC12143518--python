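import numpy as np
import pytest
import scipy.sparse as sp

from wmc.preprocessing import RawCountMatrix


@pytest.fixture
def fixture_counts():
    """5-gene x 4-cell matrix with hand-checkable QC metrics.

             c1 c2 c3 c4
    g1        3  0  1  0
    g2        2  1  0  0
    g3        0  4  2  0
    g4        0  0  1  0
    MT-1      0  5  1  0

    depth        5 10  5  0
    n_genes      2  3  4  0
    mito_frac    0 .5 .2  0
    """
    counts = np.array(
        [
            [3, 0, 1, 0],
            [2, 1, 0, 0],
            [0, 4, 2, 0],
            [0, 0, 1, 0],
            [0, 5, 1, 0],
        ]
    )
    return RawCountMatrix(
        sp.csr_matrix(counts),
        gene_ids=np.array(["g1", "g2", "g3", "g4", "MT-1"], dtype=object),
        barcodes=np.array(["c1", "c2", "c3", "c4"], dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
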