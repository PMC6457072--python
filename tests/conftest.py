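import numpy as np
import pytest
from hypothesis import settings

from diffem import BinnedCountTrack, GenomeBins

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def bins3():
    """Three 200 bp bins on one chromosome."""
    return GenomeBins(chrom_names=("chr1",), chrom_n_bins=(3,), bin_size=200)


@pytest.fixture
def bins_two_chroms():
    """Two chromosomes of 40 bins each."""
    return GenomeBins(chrom_names=("chr1", "chr2"), chrom_n_bins=(40, 40), bin_size=200)


def make_track(counts, bins=None, mark="markA", cell_type="cellA"):
    counts = np.asarray(counts)
    if bins is None:
        bins = GenomeBins(chrom_names=("chr1",), chrom_n_bins=(len(counts),), bin_size=200)
    return BinnedCountTrack(mark=mark, cell_type=cell_type, bins=bins, counts=counts)


@pytest.fixture
def track_024(bins3):
    return make_track([0, 2, 4], bins=bins3)
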