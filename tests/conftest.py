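import numpy as np
import pytest

from lincatlas.core import Transcript
from lincatlas.synthetic import simulate_dataset


def make_transcript(tid="t1", chrom="chr1", strand="+", exons=((0, 100),),
                    gene=None, biotype="unannotated"):
    return Transcript(
        transcript_id=tid,
        gene_id=gene or tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        biotype=biotype,
    )


def random_transcript(rng, chrom="chr1", max_exons=5, span=2000):
    n = int(rng.integers(1, max_exons + 1))
    bounds = np.sort(rng.choice(span, size=2 * n, replace=False))
    exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n))
    return Transcript(
        transcript_id=f"r{rng.integers(1e9)}",
        gene_id="g",
        chrom=chrom,
        strand="+" if rng.random() < 0.5 else "-",
        exons=exons,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 50 coding loci, 20 planted lincRNAs,
    6 tissues x 6 replicates, 10% assembly dropout."""
    return simulate_dataset(seed=7)
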