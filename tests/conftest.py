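import numpy as np
import pytest

from lrsplice.core import GenomicInterval, TranscriptModel, build_reference_index
from lrsplice.synth import FixtureSpec, make_fixture


def tx(tid, gene, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, gene, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted catalog: genome, reference, labeled queries, artifacts."""
    return make_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def ref_index(planted):
    return build_reference_index(planted.reference)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
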