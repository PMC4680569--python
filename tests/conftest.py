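import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import methylrad as mr


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def small_catalog():
    """Deterministic ~200-site catalog with a control contig."""
    cfg = mr.SimConfig(seed=11, genome_length=8000, control_length=2000)
    contigs, catalog = mr.simulate_genome(cfg)
    return contigs, catalog


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
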