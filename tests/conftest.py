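import numpy as np
import pytest

from barcodekit.alignment import Alignment
from barcodekit.simulate import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic cryptic-species dataset shared across tests."""
    return simulate(SyntheticConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_alignment(n: int, length: int, rng, name: str = "rand") -> Alignment:
    """IID random gap-free alignment (no phylogenetic structure)."""
    bases = np.array(list("ACGT"))
    rows = ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]
    return Alignment(name, [f"s{i}" for i in range(n)], rows)
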