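import numpy as np
import pytest

from occudiff.synthetic_data import (
    Condition,
    GenomeSpec,
    OccupancyModel,
    RepeatFamily,
    Site,
    build_toy_genome,
)


@pytest.fixture(scope="session")
def toy_genome_genes():
    """One 200 kb chromosome, 50 mRNA genes, one 10-copy tRNA family."""
    return build_toy_genome(1, 200_000, 50, [10], seed=1)


@pytest.fixture()
def flat_genome():
    return GenomeSpec((("chr1", 100_000),))


@pytest.fixture()
def spread_repeat_genome():
    """A genome with ten identical, widely separated repeat copies."""
    copies = tuple(("chr1", 20_000 * i + 5_000, 20_000 * i + 5_100) for i in range(10))
    fam = RepeatFamily("tF1", "tRNA", copies)
    return GenomeSpec((("chr1", 220_000),), (fam,))


def single_site_model(chrom: str, pos: int, weight: float, width: int = 300,
                      background_rate: float = 1.0, **kw) -> OccupancyModel:
    return OccupancyModel(
        "factor", (Site(chrom, pos, width, weight),), background_rate, **kw
    )


@pytest.fixture()
def wt_condition():
    return Condition("factor", "WT", False)


def footprint_count(frags, chrom: str, lo: int, hi: int) -> int:
    """Fragments whose midpoint falls in [lo, hi) on the chromosome."""
    n = 0
    for f in frags:
        if f.chrom == chrom and lo <= (f.start + f.end) // 2 < hi:
            n += 1
    return n


@pytest.fixture(autouse=True)
def _seed_numpy_global():
    # some scipy internals consume global state; keep runs reproducible
    np.random.seed(0)
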