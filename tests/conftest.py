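import numpy as np
import pytest

from crescreen import SimConfig, design, simulate


@pytest.fixture(scope="session")
def screen_setup():
    """A 20-region PAM-rich mini-genome with a designed tiling library and
    a -2 log2FC effect planted in the first region."""
    cfg = SimConfig(
        seed=0,
        n_regions=20,
        genome_length=20_000,
        planted_effects={"region_0000": -2.0},
    )
    genome, bed = simulate.make_genome(cfg)
    regions = design.prepare_target_regions(bed)
    library, reports = design.design_library(genome, regions)
    return {
        "config": cfg,
        "genome": genome,
        "bed": bed,
        "regions": regions,
        "library": library,
        "reports": reports,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
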