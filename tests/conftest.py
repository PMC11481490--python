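import numpy as np
import pytest

from phyloconflict.classify import LineageMap
from phyloconflict.simulate import MSCSimConfig, simulate_gene_trees


@pytest.fixture
def lm7():
    """Lineage map for the hand-written 7-leaf examples (2+2+2 ingroup + outgroup)."""
    return LineageMap(
        {
            "a1": "L1", "a2": "L1",
            "d1": "L2", "d2": "L2",
            "r1": "L3", "r2": "L3",
            "out": "OUT",
        },
        display_names={"L1": "Arthrobotrys", "L2": "Dactylellina", "L3": "Drechslerella"},
    )


@pytest.fixture
def lm4():
    """Lineage map for one-taxon-per-lineage simulations."""
    return LineageMap({"L1_1": "L1", "L2_1": "L2", "L3_1": "L3", "OUT": "OUT"})


def random_trees(n, seed, n1=3, n2=2, n3=1, internal_t=0.2, lineage_depth=0.4):
    """Diverse random trees on one leaf set, drawn from the coalescent simulator."""
    cfg = MSCSimConfig(
        n1=n1, n2=n2, n3=n3, n_genes=n,
        internal_t=internal_t, lineage_depth=lineage_depth, seed=seed,
    )
    trees, _ = simulate_gene_trees(cfg)
    return [t for _, t in trees]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
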