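import numpy as np
import pytest

from fcreliab import DistanceMatrix, FCMatrix
from fcreliab.synthetic import VarianceSpec, generate_fc_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_fc_set(X, scale="z"):
    """Wrap an (n_subjects, n_scans, V, P) array as a condition FC set."""
    n, k = X.shape[:2]
    return {
        (f"sub-{i + 1:03d}", j + 1): FCMatrix(
            values=X[i, j],
            subject_id=f"sub-{i + 1:03d}",
            condition="movie",
            scan_index=j + 1,
            scale=scale,
        )
        for i in range(n)
        for j in range(k)
    }


def random_distance_matrix(rng, n_subjects, n_scans=2, quantize=None):
    """Random valid Euclidean-style distance matrix over (subject, scan)."""
    M = n_subjects * n_scans
    points = rng.normal(size=(M, 6))
    if quantize:
        points = np.round(points * quantize) / quantize
    D = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    index = [
        (f"sub-{i + 1:03d}", j + 1) for i in range(n_subjects) for j in range(n_scans)
    ]
    return DistanceMatrix(values=D, index=index)


@pytest.fixture
def balanced_direct_dataset():
    """Small two-condition dataset with equal variance components."""
    spec = VarianceSpec(
        n_subjects=8,
        n_vertices=6,
        n_parcels=5,
        sigma2_between=1.0,
        sigma2_within=1.0,
        seed=7,
    )
    return generate_fc_dataset(spec)
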