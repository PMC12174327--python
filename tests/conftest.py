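import numpy as np
import pytest
from hypothesis import settings

from cfmeth.formats import Block, CpGIndexMap
from cfmeth.simulate import ReferenceSimConfig, simulate_reference_set

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cpg_map() -> CpGIndexMap:
    """100 CpGs on chr1 every 10 bp (positions 101, 111, ...), 20 on chr2."""
    return CpGIndexMap.from_positions(
        {
            "chr1": (101 + 10 * np.arange(100)).tolist(),
            "chr2": (501 + 25 * np.arange(20)).tolist(),
        }
    )


@pytest.fixture
def simple_block(cpg_map) -> Block:
    """CpGs 5..12 on chr1 (8 sites)."""
    return Block("chr1", 140, 212, 5, 13)


@pytest.fixture(scope="session")
def small_reference():
    """A small four-cell-type reference set shared across tests."""
    cfg = ReferenceSimConfig(
        n_cell_types=4,
        samples_per_type=2,
        n_blocks=160,
        planted_markers_per_type=20,
        fragments_per_block=80,
        seed=1234,
    )
    return simulate_reference_set(cfg)
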