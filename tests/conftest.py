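import numpy as np
import pytest

from resetlib import CellTypeAnnotation, MethylationMatrix


def make_matrix(J, groups, seed=0, loc=0.0, scale=1.0):
    """Random matrix + annotation; ``groups`` maps cell type -> n samples."""
    rng = np.random.default_rng(seed)
    sample_ids, labels = [], []
    for t, n in groups.items():
        sample_ids += [f"{t}_s{i}" for i in range(n)]
        labels += [t] * n
    N = len(sample_ids)
    values = rng.normal(loc, scale, size=(J, N))
    m = MethylationMatrix(
        np.array([f"cg{j:04d}" for j in range(J)], object),
        np.array(sample_ids, object),
        values,
    )
    return m, CellTypeAnnotation(np.array(sample_ids, object), np.array(labels, object))


@pytest.fixture
def small_matrix():
    """Two cell types, two CpGs: A at (0,0),(0,2); B at (4,0),(4,2).

    Centroids (0,1) and (4,1): Db* = [4], Dw* = [1,1], MDSC = 4.
    """
    values = np.array([[0.0, 0.0, 4.0, 4.0], [0.0, 2.0, 0.0, 2.0]])
    sample_ids = np.array(["a1", "a2", "b1", "b2"], object)
    m = MethylationMatrix(np.array(["cg1", "cg2"], object), sample_ids, values)
    ann = CellTypeAnnotation(sample_ids, np.array(["A", "A", "B", "B"], object))
    return m, ann
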