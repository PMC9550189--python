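import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from syntevo.core import BlockGenome, DatedTree
from syntevo.simulate import SimulationConfig, make_orthology_maps, simulate_history

# Desk-scale demo tree: 6 tips, total span ~7.5 My.  The simulated block
# universe (~40-500 blocks) is a few percent of a real mammalian synteny
# map, so branch durations are scaled down comparably to keep the
# breakage probability per junction in a realistic regime.
DEMO_NEWICK = (
    "((((A:0.5,B:0.5)AB:0.5,(C:0.5,D:0.5)CD:0.5)ABCD:0.5,E:1.5)ABCDE:0.5,"
    "F:2.0)root;"
)

# Balanced 4-tip tree where an internal target node has its two tips at
# patristic distance 10 and the outgroup tips at 30.
BALANCED_NEWICK = "((A:10,B:10)T:10,(C:10,D:10)U:10)root;"


@pytest.fixture(scope="session")
def demo_tree() -> DatedTree:
    return DatedTree.from_newick(DEMO_NEWICK)


@pytest.fixture(scope="session")
def balanced_tree() -> DatedTree:
    return DatedTree.from_newick(BALANCED_NEWICK)


@pytest.fixture(scope="session")
def small_history(demo_tree):
    """One simulated history at coarse blocks, with orthology maps."""
    cfg = SimulationConfig(
        n_blocks=40,
        n_chromosomes=3,
        mean_block_length=1_000_000,
        min_block_length=200_000,
        seed=7,
    )
    genomes, log = simulate_history(demo_tree, cfg)
    maps = make_orthology_maps(genomes, "root")
    return demo_tree, genomes, log, maps


def random_genome(name: str, n: int, rng: random.Random, max_chroms: int = 3) -> BlockGenome:
    """A uniformly scrambled genome over blocks 1..n."""
    blocks = list(range(1, n + 1))
    rng.shuffle(blocks)
    k = rng.randint(1, min(max_chroms, n))
    cuts = sorted(rng.sample(range(1, n), k - 1)) if k > 1 else []
    chroms, prev = {}, 0
    for idx, c in enumerate(cuts + [n]):
        chroms[f"c{idx}"] = [b * rng.choice([1, -1]) for b in blocks[prev:c]]
        prev = c
    return BlockGenome(name, chroms, {b: 100 * b for b in range(1, n + 1)})
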