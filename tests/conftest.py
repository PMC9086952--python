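import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from aggtol.simulate import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-pair synthetic dataset shared by fast integration tests."""
    return simulate(
        SimConfig(n_pairs=30, n_differential=4, n_client=6, seed=123)
    )


def random_cds(rng, n_codons: int) -> str:
    """A valid CDS: ATG start, random sense codons, one stop."""
    from aggtol.io import codon_map

    sense = [c for c, aa in codon_map(1).items() if aa != "*"]
    stops = [c for c, aa in codon_map(1).items() if aa == "*"]
    body = [sense[rng.integers(len(sense))] for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + stops[rng.integers(len(stops))]
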