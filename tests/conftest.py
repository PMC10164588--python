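import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from ctcnt.types import MarkerMap, SimulationConfig


def make_map(
    positions, genome_length=None, circular=True, donor="G", recipient="C"
) -> MarkerMap:
    """Toy marker map with uniform alleles at explicit positions."""
    positions = np.asarray(positions, dtype=np.int64)
    if genome_length is None:
        genome_length = int(positions.max()) + 100
    n = positions.size
    return MarkerMap(
        genome_length=genome_length,
        circular=circular,
        positions=positions,
        donor_alleles=np.full(n, donor, dtype="U1"),
        recipient_alleles=np.full(n, recipient, dtype="U1"),
    )


@pytest.fixture
def toy_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=200_000,
        snp_spacing_mean=56,
        segments_per_clone_mean=4.0,
        segment_length_mean=10_000.0,
        n_clones=3,
        rng_seed=1,
    )
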