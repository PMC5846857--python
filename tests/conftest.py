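import itertools

import numpy as np
import pytest

from binfing import BinaryFingerprintMatrix, SyntheticSpec, generate


@pytest.fixture
def tiny_binary():
    """Four samples, four metabolites, with two identical samples."""
    return BinaryFingerprintMatrix(
        ["s1", "s2", "s3", "s4"],
        ["m1", "m2", "m3", "m4"],
        np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]]),
    )


@pytest.fixture
def synthetic_pair():
    """A three-group synthetic dataset with paired quantitative layer."""
    return generate(SyntheticSpec(n_groups=3, samples_per_group=6, seed=7))


def all_bit_vectors(length: int) -> np.ndarray:
    return np.array(list(itertools.product([0, 1], repeat=length)), dtype=float)


def pairwise_count_arrays(X: np.ndarray, Y: np.ndarray):
    a = X @ Y.T
    b = X.sum(axis=1)[:, None] - a
    c = Y.sum(axis=1)[None, :] - a
    d = X.shape[1] - a - b - c
    return a, b, c, d


@pytest.fixture
def binary_csv(tmp_path, tiny_binary):
    path = tmp_path / "binary.csv"
    tiny_binary.to_frame().to_csv(path)
    return path
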