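import numpy as np
import pytest
from skbio import DistanceMatrix

from enteropipe import CountTable


@pytest.fixture
def small_table():
    return CountTable(
        ["s1", "s2", "s3"],
        ["gA", "gB", "gC"],
        np.array([[5, 0, 3], [1, 2, 5], [4, 4, 0]]),
    )


@pytest.fixture
def four_point_dm():
    """1-D points {0, 1, 10, 11} under Euclidean distance."""
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    return DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=list("abcd"))


def euclid_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    if ids is None:
        ids = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(d, ids=ids)
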