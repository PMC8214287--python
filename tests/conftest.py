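import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from svpipe import simulate as sim  # noqa: E402
from svpipe import svmerge as sv  # noqa: E402


@pytest.fixture(scope="session")
def toy_genome():
    return sim.toy_genome({"contig1": 100_000, "contig2": 100_000}, seed=42)


@pytest.fixture(scope="session")
def injected(toy_genome):
    spec = sim.SVSpec(
        counts={"DEL": 3, "INS": 2, "INV": 2, "DUP": 1, "TRA": 1}, seed=42
    )
    altered, truth = sim.inject_svs(toy_genome, spec)
    return altered, truth


@pytest.fixture
def simple_truth():
    """A tiny hand-built truth set on one contig."""
    return [
        sv.SVCall("DEL", "chr1", 1000, 1500, length=500, caller="truth"),
        sv.SVCall("INS", "chr1", 5000, 5000, length=300, caller="truth",
                  info={"SEQ": "A" * 300}),
        sv.SVCall("INV", "chr1", 9000, 9800, length=800, caller="truth"),
    ]
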