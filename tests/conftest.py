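import numpy as np
import pytest

from depthcline.io_formats import GenotypeTable
from depthcline.synthetic_data import SynthConfig, simulate_genotypes


@pytest.fixture
def hand_gt() -> GenotypeTable:
    """Six individuals, two loci, two groups of three (hand-checkable)."""
    calls = np.array(
        [
            [[1, 1], [1, 2]],
            [[1, 2], [2, 2]],
            [[1, 1], [1, 1]],
            [[2, 2], [2, 3]],
            [[1, 2], [3, 3]],
            [[2, 2], [2, 2]],
        ]
    )
    return GenotypeTable(
        [f"i{k}" for k in range(6)], ["L1", "L2"], calls
    )


@pytest.fixture
def hand_groups() -> list[str]:
    return ["A", "A", "A", "B", "B", "B"]


@pytest.fixture
def null_pair():
    """Two groups drawn from one shared frequency vector (no structure)."""
    cfg = SynthConfig(
        n_groups=2,
        group_sizes=(120, 120),
        n_loci=10,
        target_fst=0.0,
        depth_per_group=(40.0, 120.0),
        seed=11,
    )
    gt, frame = simulate_genotypes(cfg)
    return gt, frame["group"].to_numpy()
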