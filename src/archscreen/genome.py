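"""Genome binning and per-bin annotation tracks.

Coordinate conventions: contact positions are 1-based base pairs (pairs-file
dialect); bins are 0-based half-open intervals ``[start, start + binsize)``.
The last bin of each chromosome may be short.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "CpGTrack", "read_chrom_sizes", "load_cpg_track"]


def _open_text(path):
    """Open a possibly gzip-compressed text file for reading."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


@dataclass(frozen=True)
class GenomeBins:
    """A fixed-width binning of a genome assembly.

    Bins are numbered globally: chromosome order is the order of ``chroms``,
    and within a chromosome bins run left to right.
    """

    chroms: tuple
    lengths: np.ndarray  # bp, int64, aligned with chroms
    binsize: int
    # derived
    n_bins_per_chrom: np.ndarray = field(init=False, repr=False)
    offsets: np.ndarray = field(init=False, repr=False)
    chrom_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.chroms) != len(lengths):
            raise ValueError("chroms and lengths must align")
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")
        if np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        nb = -(-lengths // self.binsize)  # ceil division
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "n_bins_per_chrom", nb)
        object.__setattr__(
            self, "offsets", np.concatenate([[0], np.cumsum(nb)])
        )
        object.__setattr__(
            self, "chrom_index", {c: i for i, c in enumerate(self.chroms)}
        )

    @property
    def n_bins(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_chroms(self) -> int:
        return len(self.chroms)

    def chrom_slice(self, chrom) -> slice:
        """Global-bin slice covering one chromosome (name or index)."""
        ci = chrom if isinstance(chrom, (int, np.integer)) else self.chrom_index[chrom]
        return slice(int(self.offsets[ci]), int(self.offsets[ci + 1]))

    def bin_of(self, chrom_idx, pos):
        """Global bin index for 1-based positions on given chromosome indices."""
        chrom_idx = np.asarray(chrom_idx)
        pos = np.asarray(pos, dtype=np.int64)
        return self.offsets[chrom_idx] + (pos - 1) // self.binsize

    def bin_table(self) -> pd.DataFrame:
        """BED-like table of all bins (chrom, start, end), 0-based half-open."""
        rows = []
        for ci, name in enumerate(self.chroms):
            n = int(self.n_bins_per_chrom[ci])
            starts = np.arange(n, dtype=np.int64) * self.binsize
            ends = np.minimum(starts + self.binsize, self.lengths[ci])
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_chrom_ids(self) -> np.ndarray:
        """Chromosome index of every global bin."""
        return np.repeat(
            np.arange(self.n_chroms), self.n_bins_per_chrom.astype(int)
        )

    def with_binsize(self, binsize: int) -> "GenomeBins":
        return GenomeBins(self.chroms, self.lengths, binsize)

    def same_assembly(self, other: "GenomeBins") -> bool:
        return self.chroms == other.chroms and np.array_equal(
            self.lengths, other.lengths
        )


def read_chrom_sizes(path, binsize: int) -> GenomeBins:
    """Build GenomeBins from a two-column ``chrom.sizes`` file."""
    chroms, lengths = [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed chrom.sizes line {lineno}: {line!r}")
            chroms.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeBins(tuple(chroms), np.array(lengths, dtype=np.int64), binsize)


@dataclass
class CpGTrack:
    """Per-bin CpG density (CpG dinucleotides per bp), aligned to a GenomeBins.

    Missing bins carry NaN and are treated as masked everywhere downstream.
    """

    bins: GenomeBins
    values: np.ndarray  # float64, NaN = masked

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.bins.n_bins,):
            raise ValueError("one CpG value per bin required")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 0.25):
            raise ValueError("CpG density must lie in [0, 0.25]")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_bedgraph(self, path):
        tbl = self.bins.bin_table()
        tbl["value"] = self.values
        tbl = tbl[np.isfinite(tbl["value"].to_numpy())]
        tbl.to_csv(path, sep="\t", header=False, index=False)


def load_cpg_track(path, bins: GenomeBins) -> CpGTrack:
    """Load a bedGraph into per-bin length-weighted mean values.

    Bins with no covering interval are masked (NaN). Malformed lines raise
    with their line number.
    """
    wsum = np.zeros(bins.n_bins)
    lsum = np.zeros(bins.n_bins)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                chrom, start, end, value = (
                    parts[0], int(parts[1]), int(parts[2]), float(parts[3]),
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"malformed bedGraph line {lineno}: {line.rstrip()!r}"
                ) from exc
            if chrom not in bins.chrom_index:
                raise ValueError(
                    f"unknown chromosome {chrom!r} at bedGraph line {lineno}"
                )
            ci = bins.chrom_index[chrom]
            if end <= start or end > bins.lengths[ci]:
                raise ValueError(
                    f"interval out of range at bedGraph line {lineno}"
                )
            off = bins.offsets[ci]
            b0 = start // bins.binsize
            b1 = (end - 1) // bins.binsize
            for b in range(b0, b1 + 1):
                lo = max(start, b * bins.binsize)
                hi = min(end, (b + 1) * bins.binsize)
                wsum[off + b] += value * (hi - lo)
                lsum[off + b] += hi - lo
    values = np.full(bins.n_bins, np.nan)
    covered = lsum > 0
    values[covered] = wsum[covered] / lsum[covered]
    return CpGTrack(bins, values)
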