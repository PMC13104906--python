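"""Contact-level I/O and bookkeeping.

A :class:`ContactSet` is a sample's (or single cell's) list of pairwise
genomic contacts, stored column-wise as numpy arrays in canonical order:
``chrom1 <= chrom2`` by genome order and ``pos1 <= pos2`` within a
chromosome. Positions are 1-based base pairs (4DN pairs dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import GenomeBins, _open_text

__all__ = [
    "ContactSet",
    "read_pairs",
    "write_pairs",
    "deduplicate",
    "downsample",
    "estimate_complexity",
]


@dataclass
class ContactSet:
    """Pairwise contacts of one sample/cell on a shared assembly."""

    bins: GenomeBins  # assembly reference (binsize irrelevant here)
    c1: np.ndarray  # chromosome index of first mate
    p1: np.ndarray  # 1-based bp
    c2: np.ndarray
    p2: np.ndarray
    sample_id: str = ""
    cell_id: str | None = None
    n_total: int | None = None  # read pairs before dedup; None = unknown
    n_duplicates: int = 0

    def __post_init__(self):
        self.c1 = np.asarray(self.c1, dtype=np.int32)
        self.c2 = np.asarray(self.c2, dtype=np.int32)
        self.p1 = np.asarray(self.p1, dtype=np.int64)
        self.p2 = np.asarray(self.p2, dtype=np.int64)
        self._canonicalize()

    def _canonicalize(self):
        swap = (self.c1 > self.c2) | ((self.c1 == self.c2) & (self.p1 > self.p2))
        if np.any(swap):
            c1, p1 = self.c1.copy(), self.p1.copy()
            self.c1[swap], self.p1[swap] = self.c2[swap], self.p2[swap]
            self.c2[swap], self.p2[swap] = c1[swap], p1[swap]

    def __len__(self) -> int:
        return self.c1.size

    @property
    def is_cis(self) -> np.ndarray:
        return self.c1 == self.c2

    @property
    def distances(self) -> np.ndarray:
        """Genomic separation of cis contacts (bp)."""
        cis = self.is_cis
        return (self.p2 - self.p1)[cis]

    def validate(self):
        """Raise if any position exceeds its chromosome length or is < 1."""
        for c, p in ((self.c1, self.p1), (self.c2, self.p2)):
            if np.any(p < 1) or np.any(p > self.bins.lengths[c]):
                bad = np.flatnonzero((p < 1) | (p > self.bins.lengths[c]))[0]
                raise ValueError(
                    f"position {p[bad]} out of range for chromosome "
                    f"{self.bins.chroms[c[bad]]}"
                )
        return self

    def as_frame(self) -> pd.DataFrame:
        chroms = np.asarray(self.bins.chroms)
        return pd.DataFrame(
            {
                "chrom1": chroms[self.c1],
                "pos1": self.p1,
                "chrom2": chroms[self.c2],
                "pos2": self.p2,
            }
        )

    def subset(self, idx) -> "ContactSet":
        return replace(
            self,
            c1=self.c1[idx], p1=self.p1[idx],
            c2=self.c2[idx], p2=self.p2[idx],
            n_total=None, n_duplicates=0,
        )

    def concat(self, *others: "ContactSet") -> "ContactSet":
        all_sets = (self, *others)
        return replace(
            self,
            c1=np.concatenate([s.c1 for s in all_sets]),
            p1=np.concatenate([s.p1 for s in all_sets]),
            c2=np.concatenate([s.c2 for s in all_sets]),
            p2=np.concatenate([s.p2 for s in all_sets]),
            n_total=None, n_duplicates=0,
        )


def read_pairs(path, bins: GenomeBins, sample_id: str = "") -> ContactSet:
    """Parse a pairs-like text file (optionally gzip) into a ContactSet.

    Expected columns: read id, chrom1, pos1, chrom2, pos2 (extra columns
    ignored). Header lines start with '#'. Unknown chromosomes and
    out-of-range positions raise, naming the offending line.
    """
    ids1, pos1, ids2, pos2 = [], [], [], []
    cindex = bins.chrom_index
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"malformed pairs line {lineno}: {line.rstrip()!r}")
            _, ch1, p1, ch2, p2 = parts[:5]
            try:
                i1, i2 = cindex[ch1], cindex[ch2]
            except KeyError as exc:
                raise ValueError(
                    f"unknown chromosome {exc.args[0]!r} at pairs line {lineno}"
                ) from None
            ids1.append(i1)
            ids2.append(i2)
            pos1.append(int(p1))
            pos2.append(int(p2))
    cs = ContactSet(
        bins,
        np.array(ids1, dtype=np.int32), np.array(pos1, dtype=np.int64),
        np.array(ids2, dtype=np.int32), np.array(pos2, dtype=np.int64),
        sample_id=sample_id, n_total=len(ids1),
    )
    return cs.validate()


def write_pairs(cs: ContactSet, path):
    """Write a ContactSet as pairs-like text; round-trips through read_pairs."""
    chroms = np.asarray(cs.bins.chroms)
    with open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2\n")
        for i in range(len(cs)):
            fh.write(
                f".\t{chroms[cs.c1[i]]}\t{cs.p1[i]}"
                f"\t{chroms[cs.c2[i]]}\t{cs.p2[i]}\n"
            )


def _contact_keys(cs: ContactSet) -> np.ndarray:
    """Encode each contact 4-tuple as one int64 key (collision-free)."""
    nb = int(cs.bins.lengths.max()) + 2
    k1 = cs.c1.astype(np.int64) * nb + cs.p1
    k2 = cs.c2.astype(np.int64) * nb + cs.p2
    # two-level lexicographic key via structured array
    keys = np.empty(len(cs), dtype=[("a", np.int64), ("b", np.int64)])
    keys["a"], keys["b"] = k1, k2
    return keys


def deduplicate(cs: ContactSet) -> ContactSet:
    """Collapse exact-duplicate 4-tuples; record total/duplicate counts."""
    if len(cs) == 0:
        return replace(cs, n_total=0, n_duplicates=0)
    keys = _contact_keys(cs)
    _, first = np.unique(keys, return_index=True)
    out = cs.subset(np.sort(first))
    out.n_total = len(cs)
    out.n_duplicates = len(cs) - len(out)
    return out


def downsample(cs: ContactSet, n: int, seed) -> ContactSet:
    """Uniform random subset of exactly ``n`` contacts, without replacement."""
    if n > len(cs):
        raise ValueError(f"cannot downsample {len(cs)} contacts to {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(cs), size=n, replace=False))
    return cs.subset(idx)


def estimate_complexity(n_total: int, n_unique: int) -> float:
    """Estimate distinct library molecules from read-pair duplication.

    Solves ``n_unique = C * (1 - exp(-n_total / C))`` for C (the saturation
    curve of sampling with replacement from C molecules) by bracketed
    root-finding. Returns ``inf`` when no duplicates were observed.
    """
    if n_unique <= 0:
        raise ValueError("n_unique must be positive")
    if n_unique > n_total:
        raise ValueError("n_unique cannot exceed n_total")
    if n_unique == n_total:
        return float("inf")

    def f(c):
        return c * -np.expm1(-n_total / c) - n_unique

    lo = float(n_unique)  # C >= n_unique always
    hi = max(2.0 * lo, 4.0)
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))
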