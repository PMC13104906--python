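"""Binned contact matrices and observed/expected normalization.

A :class:`BinnedMatrix` keeps the raw upper-triangular bin-pair assignments
of every contact (global bin indices) plus lazily built dense per-chromosome
views. Genomes handled here are desk-scale (a few thousand bins per
chromosome), so dense per-chromosome arrays are the fastest representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactSet
from .genome import GenomeBins

__all__ = ["BinnedMatrix", "bin_contacts", "observed_expected"]


@dataclass
class BinnedMatrix:
    """Sparse symmetric contact counts at a fixed bin size.

    ``b1 <= b2`` are global bin indices of each contact (upper triangle);
    duplicates in (b1, b2) represent counts. ``oe`` maps chromosome index to
    a dense observed/expected matrix once :func:`observed_expected` has run.
    """

    bins: GenomeBins
    b1: np.ndarray
    b2: np.ndarray
    oe: dict = field(default_factory=dict, repr=False)
    _cis_cache: dict = field(default_factory=dict, repr=False)

    @property
    def total(self) -> int:
        return self.b1.size

    def cis_dense(self, chrom) -> np.ndarray:
        """Dense symmetric cis count matrix of one chromosome (float64)."""
        ci = chrom if isinstance(chrom, (int, np.integer)) else self.bins.chrom_index[chrom]
        ci = int(ci)
        if ci in self._cis_cache:
            return self._cis_cache[ci]
        sl = self.bins.chrom_slice(ci)
        n = sl.stop - sl.start
        sel = (self.b1 >= sl.start) & (self.b1 < sl.stop) & \
              (self.b2 >= sl.start) & (self.b2 < sl.stop)
        i = self.b1[sel] - sl.start
        j = self.b2[sel] - sl.start
        m = np.bincount(i * n + j, minlength=n * n).astype(np.float64).reshape(n, n)
        diag = np.diag(m).copy()
        m = m + m.T  # only the upper triangle was populated
        np.fill_diagonal(m, diag)
        self._cis_cache[ci] = m
        return m

    def dense(self) -> np.ndarray:
        """Dense symmetric genome-wide matrix (use only at coarse bins)."""
        n = self.bins.n_bins
        m = np.bincount(self.b1 * n + self.b2, minlength=n * n)
        m = m.astype(np.float64).reshape(n, n)
        return m + np.triu(m, 1).T

    def marginals(self) -> np.ndarray:
        """Per-bin total contact counts (both mates)."""
        n = self.bins.n_bins
        return np.bincount(self.b1, minlength=n) + np.bincount(self.b2, minlength=n)

    def to_triplets(self, path):
        """Aggregate to (bin1, bin2, count) rows and write as TSV."""
        n = self.bins.n_bins
        keys, counts = np.unique(self.b1 * n + self.b2, return_counts=True)
        pd.DataFrame(
            {"bin1": keys // n, "bin2": keys % n, "count": counts}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_triplets(cls, path, bins: GenomeBins) -> "BinnedMatrix":
        tbl = pd.read_csv(path, sep="\t")
        b1 = np.repeat(tbl["bin1"].to_numpy(np.int64), tbl["count"])
        b2 = np.repeat(tbl["bin2"].to_numpy(np.int64), tbl["count"])
        return cls(bins, b1, b2)


def bin_contacts(cs: ContactSet, bins: GenomeBins) -> BinnedMatrix:
    """Assign every contact to exactly one bin pair; conserves total count."""
    if not cs.bins.same_assembly(bins):
        raise ValueError("contact set and bins are on different assemblies")
    b1 = bins.bin_of(cs.c1, cs.p1)
    b2 = bins.bin_of(cs.c2, cs.p2)
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    return BinnedMatrix(bins, lo, hi)


def expected_profile(dense: np.ndarray, log_bands: int | None = None) -> np.ndarray:
    """Mean count per diagonal offset of a dense symmetric cis matrix.

    With ``log_bands`` set, offsets >= 1 are pooled into that many
    geometric bands per octave before averaging — a smoothed expected that
    stabilizes O/E ratios at shallow sequencing depth.
    """
    n = dense.shape[0]
    i, j = np.triu_indices(n)
    offs = j - i
    sums = np.bincount(offs, weights=dense[i, j], minlength=n)
    counts = np.bincount(offs, minlength=n)
    if log_bands is not None and n > 1:
        band = np.floor(np.log2(np.maximum(np.arange(n), 1)) * log_bands).astype(int)
        bsums = np.bincount(band, weights=sums)
        bcounts = np.bincount(band, weights=counts)
        with np.errstate(invalid="ignore"):
            smoothed = (bsums / bcounts)[band]
        smoothed[0] = sums[0] / counts[0] if counts[0] else np.nan
        return smoothed
    with np.errstate(invalid="ignore"):
        return sums / counts


def observed_expected(
    m: BinnedMatrix, log_bands: int | None = None
) -> BinnedMatrix:
    """Attach per-chromosome O/E layers (cis entry over its distance mean).

    Expected is computed on the same matrix, so the layer is invariant to
    uniform count scaling. Chromosomes with no contacts are masked (absent
    from the layer). ``log_bands`` selects the smoothed expected.
    """
    for ci in range(m.bins.n_chroms):
        d = m.cis_dense(ci)
        if d.sum() == 0:
            continue
        exp = expected_profile(d, log_bands)
        n = d.shape[0]
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        e = exp[dist]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(e > 0, d / e, np.nan)
        m.oe[ci] = oe
    return m


def cpm_dense(m: BinnedMatrix) -> np.ndarray:
    """Genome-wide dense matrix in contacts-per-million units."""
    d = m.dense()
    if m.total == 0:
        return d
    return d * (1e6 / m.total)
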