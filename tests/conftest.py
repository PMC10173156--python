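import numpy as np
import pytest

from polycore.geno_io import MISSING, DosageMatrix


@pytest.fixture
def small_matrix() -> DosageMatrix:
    """3 samples x 4 markers, no missing data."""
    calls = np.array(
        [
            [0, 1, 2, 4],
            [4, 3, 2, 0],
            [2, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    return DosageMatrix(["s1", "s2", "s3"], ["m1", "m2", "m3", "m4"], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dosage_matrix(
    rng: np.random.Generator, n_samples: int, n_markers: int, missing_rate: float = 0.0
) -> DosageMatrix:
    calls = rng.integers(0, 5, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return DosageMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"m{j}" for j in range(n_markers)],
        calls,
    )
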