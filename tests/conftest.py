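import pytest

from grbcontext.homology import ScoringScheme
from grbcontext.synth import (
    SynthConfig, emit_alignments, generate_reference, hits_from_wgd,
    simulate_wgd,
)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_world():
    """A small winner-scenario synthetic bundle shared across tests."""
    cfg = SynthConfig(
        n_genes=3, ucnes_per_gene=4, seed=101,
        retention_scenario="winner", retention_prob=1.0,
        intergenic_fraction=0.25,
    )
    ref = generate_reference(cfg)
    dup = simulate_wgd(ref, cfg)
    return cfg, ref, dup


@pytest.fixture(scope="session")
def small_world_hits(small_world, scheme):
    _, ref, dup = small_world
    return hits_from_wgd(ref, dup, scheme)


@pytest.fixture(scope="session")
def small_world_blocks(small_world):
    _, ref, dup = small_world
    return emit_alignments(ref, dup)
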