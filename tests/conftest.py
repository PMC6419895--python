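import numpy as np
import pytest

from sparcor import OtuTable


@pytest.fixture
def tiny_table() -> OtuTable:
    return OtuTable(
        ("A", "B"), ("S1", "S2", "S3"), np.array([[1, 2, 3], [4, 5, 6]])
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_table(rng: np.random.Generator, d: int, n: int, lam: float = 20.0) -> OtuTable:
    counts = rng.poisson(lam, size=(d, n)).astype(np.int64)
    return OtuTable(
        tuple(f"O{i}" for i in range(d)),
        tuple(f"S{j}" for j in range(n)),
        counts,
    )
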