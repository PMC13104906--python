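import numpy as np
import pytest

from archscreen.genome import CpGTrack, GenomeBins


@pytest.fixture
def toy_bins():
    """Two tiny chromosomes, 1-Mb bins (5 + 3 bins)."""
    return GenomeBins(("chr1", "chr2"), np.array([5_000_000, 2_500_000]), 1_000_000)


@pytest.fixture
def toy_cpg(toy_bins):
    return CpGTrack(toy_bins, np.linspace(0.010, 0.024, toy_bins.n_bins))


def make_contacts(bins, rows, **kwargs):
    """ContactSet from (chrom1, pos1, chrom2, pos2) tuples."""
    from archscreen.contacts import ContactSet

    rows = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
    return ContactSet(
        bins, rows[:, 0].astype(np.int32), rows[:, 1],
        rows[:, 2].astype(np.int32), rows[:, 3], **kwargs
    )
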