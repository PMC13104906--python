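"""Contact locality: distance distributions, insulation, boundaries, loops.

Insulation follows the sliding-diamond convention: for each bin the counts
in the ``w x w`` square flanking it off-diagonal are summed, log2-normalized
to the chromosome-wide median of that sum. Domain boundaries are local
minima below a threshold. When comparing samples, boundaries (and their
flanking reference maxima) are called once on a designated reference and
held fixed, so strength changes reflect depth at the same loci rather than
re-calling stochasticity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactSet
from .genome import GenomeBins
from .matrix import BinnedMatrix, observed_expected

__all__ = [
    "DistanceProfile",
    "InsulationTrack",
    "LoopStrength",
    "distance_profile",
    "intermingling",
    "insulation_profile",
    "call_boundaries",
    "boundary_strength",
    "apa_p2ll",
    "read_bedpe",
]

# summary band edges: short < 2 Mb <= long < 10 Mb <= very long
BAND_EDGES = (2_000_000, 10_000_000)
MIN_DISTANCE = 10_000
N_LOG_BINS = 20
BOUNDARY_THRESHOLD = -0.2
DEFAULT_WINDOW = 250_000


@dataclass
class DistanceProfile:
    """Distribution of contact distances of one sample.

    Curve fractions (log-spaced cis bands) plus the trans fraction sum to 1
    up to float tolerance; contacts closer than ``MIN_DISTANCE`` fall into
    the first band.
    """

    edges: np.ndarray          # log10-spaced distance bin edges (bp)
    fractions: np.ndarray      # per-band fraction of all contacts
    trans_fraction: float
    frac_short: float          # cis < 2 Mb, as fraction of all contacts
    frac_long: float           # cis 2-10 Mb
    frac_very_long: float      # cis > 10 Mb


@dataclass
class InsulationTrack:
    bins: GenomeBins
    window: int                # bp
    values: np.ndarray         # log2 score; NaN where window does not fit
    boundaries: np.ndarray     # global bin indices of called boundaries

    def to_bedgraph(self, path):
        from .compartments import write_track_bedgraph

        write_track_bedgraph(self.bins, self.values, path)


@dataclass
class LoopStrength:
    stack: np.ndarray          # mean O/E submatrix, odd x odd
    p2ll: float
    centers: np.ndarray        # per-loop center O/E values
    n_used: int
    n_skipped: int


def distance_profile(cs: ContactSet) -> DistanceProfile:
    """Band fractions of contact distances; fractions sum to 1 exactly."""
    n = len(cs)
    if n == 0:
        raise ValueError("empty contact set")
    dist = cs.distances.astype(float)
    trans_fraction = 1.0 - dist.size / n
    max_len = float(cs.bins.lengths.max())
    edges = np.logspace(
        np.log10(MIN_DISTANCE), np.log10(max_len), N_LOG_BINS + 1
    )
    edges[-1] = max_len + 1
    idx = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, N_LOG_BINS - 1)
    fractions = np.bincount(idx, minlength=N_LOG_BINS) / n
    frac_short = float(np.sum(dist < BAND_EDGES[0]) / n)
    frac_long = float(np.sum((dist >= BAND_EDGES[0]) & (dist < BAND_EDGES[1])) / n)
    frac_very_long = float(np.sum(dist >= BAND_EDGES[1]) / n)
    return DistanceProfile(
        edges=edges, fractions=fractions, trans_fraction=trans_fraction,
        frac_short=frac_short, frac_long=frac_long, frac_very_long=frac_very_long,
    )


def intermingling(cs: ContactSet) -> float:
    """Fraction of contacts that are interchromosomal."""
    if len(cs) == 0:
        raise ValueError("empty contact set")
    return float(np.mean(~cs.is_cis))


def _diamond_sums(dense: np.ndarray, w: int) -> np.ndarray:
    """Sum of the w x w square flanking each bin, via an integral image."""
    n = dense.shape[0]
    pad = np.zeros((n + 1, n + 1))
    pad[1:, 1:] = np.cumsum(np.cumsum(dense, axis=0), axis=1)
    out = np.full(n, np.nan)
    i = np.arange(w, n - w)
    if i.size == 0:
        return out
    r0, r1 = i - w, i            # rows [i-w, i-1]
    c0, c1 = i + 1, i + 1 + w    # cols [i+1, i+w]
    out[i] = pad[r1, c1] - pad[r0, c1] - pad[r1, c0] + pad[r0, c0]
    return out


def diamond_sums(m: BinnedMatrix, chrom, w: int) -> np.ndarray:
    """Per-bin w x w flanking-square sums of one chromosome, O(contacts).

    A contact (i, j), i < j, falls in the diamond of bin b exactly when
    b - w <= i < b < j <= b + w, i.e. for b in [max(i+1, j-w),
    min(i+w, j-1)] — a contiguous range, accumulated with a difference
    array. Integer counts keep the result exactly equal to naive summation.
    """
    ci = chrom if isinstance(chrom, (int, np.integer)) else m.bins.chrom_index[chrom]
    sl = m.bins.chrom_slice(int(ci))
    n = sl.stop - sl.start
    out = np.full(n, np.nan)
    if n <= 2 * w:
        return out
    sel = (m.b1 >= sl.start) & (m.b1 < sl.stop) & \
          (m.b2 >= sl.start) & (m.b2 < sl.stop)
    i = m.b1[sel] - sl.start
    j = m.b2[sel] - sl.start
    lo = np.maximum(i + 1, j - w)
    hi = np.minimum(i + w, j - 1)
    ok = hi >= lo
    diff = np.zeros(n + 1)
    np.add.at(diff, lo[ok], 1.0)
    np.add.at(diff, hi[ok] + 1, -1.0)
    sums = np.cumsum(diff[:-1])
    out[w : n - w] = sums[w : n - w]
    return out


def insulation_profile(
    m: BinnedMatrix, window: int = DEFAULT_WINDOW,
    threshold: float = BOUNDARY_THRESHOLD,
) -> InsulationTrack:
    """Per-bin diamond insulation score with boundary calls.

    The score is log2(diamond sum / chromosome-wide median diamond sum), so
    it is invariant to uniform depth scaling. Chromosomes smaller than the
    window are fully masked.
    """
    if window % m.bins.binsize:
        raise ValueError("window must be a multiple of the bin size")
    w = window // m.bins.binsize
    values = np.full(m.bins.n_bins, np.nan)
    for ci in range(m.bins.n_chroms):
        sl = m.bins.chrom_slice(ci)
        n = sl.stop - sl.start
        if n <= 2 * w:
            warnings.warn(
                f"chromosome {m.bins.chroms[ci]} smaller than insulation "
                "window; masked", stacklevel=2,
            )
            continue
        sums = diamond_sums(m, ci, w)
        med = np.nanmedian(sums)
        if not np.isfinite(med) or med <= 0:
            continue
        with np.errstate(divide="ignore"):
            values[sl] = np.log2(sums / med)
    track = InsulationTrack(m.bins, window, values, np.empty(0, dtype=int))
    track.boundaries = call_boundaries(track, threshold)
    return track


def call_boundaries(track: InsulationTrack, threshold: float = BOUNDARY_THRESHOLD) -> np.ndarray:
    """Local minima of the insulation score below ``threshold``."""
    v = track.values
    out = []
    for ci in range(track.bins.n_chroms):
        sl = track.bins.chrom_slice(ci)
        x = v[sl]
        for i in range(1, x.size - 1):
            # -inf (empty diamond) is a legitimate extreme dip; NaN is masked
            if np.isnan(x[i]) or x[i] >= threshold:
                continue
            left = x[i - 1] if not np.isnan(x[i - 1]) else np.inf
            right = x[i + 1] if not np.isnan(x[i + 1]) else np.inf
            if (x[i] <= left and x[i] < right) or (x[i] < left and x[i] <= right):
                out.append(sl.start + i)
    return np.asarray(out, dtype=int)


def reference_flanks(
    track: InsulationTrack, boundaries, search_bins: int | None = None
) -> list:
    """For each reference boundary, the flanking local-maximum bins of the
    reference track (nearest maxima within ``search_bins`` on each side).
    Held fixed when scoring other samples."""
    v = track.values
    w = track.window // track.bins.binsize
    search = search_bins if search_bins is not None else 2 * w
    chrom_of = track.bins.bin_chrom_ids()
    flanks = []
    for b in boundaries:
        sl = track.bins.chrom_slice(int(chrom_of[b]))
        pair = []
        for step in (-1, 1):
            best = None
            prev = v[b]
            for k in range(1, search + 1):
                j = b + step * k
                if j < sl.start or j >= sl.stop or not np.isfinite(v[j]):
                    break
                if v[j] >= prev:
                    best = j
                    prev = v[j]
                elif best is not None:
                    break
                else:
                    prev = v[j]
            if best is None:
                # monotone decrease away from the boundary: take the edge
                j = min(max(b + step * search, sl.start), sl.stop - 1)
                best = j
            pair.append(best)
        flanks.append(tuple(pair))
    return flanks


def boundary_strength(
    track: InsulationTrack,
    reference_boundaries,
    reference_flanks_list=None,
) -> float:
    """Mean prominence of the insulation dip at fixed reference boundaries.

    Per boundary: mean of the two flanking maxima minus the boundary score.
    Flank positions default to maxima of this track but should be supplied
    from the reference condition for cross-sample comparisons.
    """
    reference_boundaries = np.asarray(reference_boundaries, dtype=int)
    if reference_boundaries.size == 0:
        raise ValueError("no reference boundaries provided")
    if reference_flanks_list is None:
        reference_flanks_list = reference_flanks(track, reference_boundaries)
    v = track.values
    strengths = []
    for b, (lf, rf) in zip(reference_boundaries, reference_flanks_list):
        if not (np.isfinite(v[b]) and np.isfinite(v[lf]) and np.isfinite(v[rf])):
            continue
        strengths.append(0.5 * (v[lf] + v[rf]) - v[b])
    if not strengths:
        raise ValueError("no scorable reference boundaries")
    return float(np.mean(strengths))


def read_bedpe(path, bins: GenomeBins) -> np.ndarray:
    """Load a BEDPE loop list into (chrom_idx, mid1, mid2) rows (bp)."""
    tbl = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        usecols=range(6),
    )
    rows = []
    for _, r in tbl.iterrows():
        if r.chrom1 != r.chrom2:
            continue  # trans loops not supported
        if r.chrom1 not in bins.chrom_index:
            raise ValueError(f"unknown chromosome {r.chrom1!r} in loop list")
        ci = bins.chrom_index[r.chrom1]
        rows.append((ci, (r.start1 + r.end1) // 2, (r.start2 + r.end2) // 2))
    return np.asarray(rows, dtype=np.int64).reshape(-1, 3)


def apa_p2ll(
    m: BinnedMatrix, loops: np.ndarray, half_window: int = 5
) -> LoopStrength:
    """Aggregate peak analysis of a loop list on the O/E matrix.

    Stacks the ``(2*half_window+1)``-sized O/E submatrix centered on each
    loop pixel; P2LL is the center pixel of the mean stack over the mean of
    the lower-left corner box (``max(1, half_window // 2)`` square). Loops
    too near the diagonal or matrix edge are skipped with a warning.
    """
    loops = np.asarray(loops, dtype=np.int64).reshape(-1, 3)
    if not m.oe:
        observed_expected(m)
    hw = half_window
    size = 2 * hw + 1
    stack_sum = np.zeros((size, size))
    centers = []
    n_used = n_skipped = 0
    bs = m.bins.binsize
    for ci, pos1, pos2 in loops:
        ci = int(ci)
        if ci not in m.oe:
            n_skipped += 1
            continue
        oe = m.oe[ci]
        n = oe.shape[0]
        b1 = int((pos1 - 1) // bs) if pos1 > 0 else 0
        b2 = int((pos2 - 1) // bs) if pos2 > 0 else 0
        b1, b2 = min(b1, b2), max(b1, b2)
        if (
            b1 - hw < 0 or b2 + hw >= n
            or (b2 - hw) - (b1 + hw) < 1  # submatrix would cross the diagonal
        ):
            n_skipped += 1
            continue
        sub = oe[b1 - hw : b1 + hw + 1, b2 - hw : b2 + hw + 1]
        sub = np.where(np.isfinite(sub), sub, 1.0)
        stack_sum += sub
        centers.append(sub[hw, hw])
        n_used += 1
    if n_used == 0:
        raise ValueError("all loops skipped; no usable APA stack")
    if n_skipped:
        warnings.warn(f"{n_skipped} loops skipped near diagonal/edge", stacklevel=2)
    stack = stack_sum / n_used
    k = max(1, hw // 2)
    ll = stack[-k:, :k]  # lower-left corner box
    p2ll = float(stack[hw, hw] / ll.mean())
    return LoopStrength(
        stack=stack, p2ll=p2ll, centers=np.asarray(centers),
        n_used=n_used, n_skipped=n_skipped,
    )
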