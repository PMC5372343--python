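import random

import pytest

from panscaf.permutation import SignedPermutation
from panscaf.pipeline import PipelineConfig, run_pipeline
from panscaf.simulate import apply_event_script, default_desk_config


def random_signed_permutation(n: int, rng: random.Random) -> SignedPermutation:
    vals = list(range(1, n + 1))
    rng.shuffle(vals)
    return SignedPermutation(tuple(v * rng.choice((1, -1)) for v in vals))


@pytest.fixture(scope="session")
def desk_dataset():
    """The default desk-scale synthetic study: 5 strains, 40 blocks,
    5 planted long IR inversions and 1 DR transposition, seed 0."""
    return apply_event_script(default_desk_config(seed=0))


@pytest.fixture(scope="session")
def desk_report(desk_dataset, tmp_path_factory):
    """Full pipeline report (with the repeat-flank stage) on the desk data."""
    outdir = tmp_path_factory.mktemp("desk")
    blockmap = outdir / "blockmap.tsv"
    blockmap.write_text(desk_dataset.block_map.to_tsv())
    return run_pipeline(PipelineConfig(
        blockmap=blockmap, genomes=desk_dataset.genomes))
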