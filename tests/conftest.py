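import numpy as np
import pytest

from allomap.datatypes import PAIR_PL, TraitPairData
from allomap.scan import PairDesign, ScanConfig
from allomap.simulate import make_paper_like_dataset


@pytest.fixture(scope="session")
def paper_like():
    """Study-scale dataset at desk SNP count: 150 SNPs x 84 progenies."""
    return make_paper_like_dataset(seed=11, snps_per_chrom=30)


@pytest.fixture(scope="session")
def pl_design(paper_like):
    _, traits, _ = paper_like
    return PairDesign(TraitPairData.from_traits(traits, PAIR_PL))


@pytest.fixture()
def fast_config():
    """Single-start optimizer config for runtime-sensitive scans."""
    return ScanConfig(n_perm=100, level=0.05, n_starts=1, fatol=1e-8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
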