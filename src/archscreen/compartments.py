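"""A/B compartment analysis: eigenvectors, scA/B profiles, saddle strengths.

The scA/B value of a locus is the contact-weighted mean CpG density of the
loci it touches — a contact-frequency surrogate for the spatial-neighborhood
definition used in single-cell work. Near-diagonal cis contacts (< 3 Mb by
default) are excluded from the weighting so the value reflects long-range
spatial environment rather than the linear neighborhood; trans contacts are
included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contacts import ContactSet
from .genome import CpGTrack, GenomeBins
from .matrix import BinnedMatrix, bin_contacts, observed_expected

__all__ = [
    "EigTrack",
    "ScABProfile",
    "CompartmentStrengths",
    "compartment_eigenvector",
    "scab_profile",
    "saddle_strengths",
]

MIN_EIG_BINS = 10
SCAB_MIN_SEPARATION = 3_000_000
SCAB_MIN_SUPPORT = 10
SADDLE_QUANTILE = 0.2


@dataclass
class EigTrack:
    """First eigenvector of the per-chromosome O/E correlation matrix,
    sign-oriented so that its correlation with CpG density is >= 0."""

    bins: GenomeBins
    values: np.ndarray        # NaN = masked
    flipped: np.ndarray       # per-chromosome orientation flag
    masked_fraction: float

    def to_bedgraph(self, path):
        write_track_bedgraph(self.bins, self.values, path)


def write_track_bedgraph(bins: GenomeBins, values, path):
    """Write a per-bin track as bedGraph, skipping masked bins."""
    tbl = bins.bin_table()
    tbl["value"] = np.asarray(values, dtype=float)
    tbl = tbl[np.isfinite(tbl["value"].to_numpy())]
    tbl.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ScABProfile:
    """Per-bin spatial CpG-based compartment value of one sample/cell."""

    bins: GenomeBins
    values: np.ndarray        # CpG-density units; NaN = masked
    support: np.ndarray       # contact count behind each bin's value
    sample_id: str = ""


@dataclass
class CompartmentStrengths:
    """Saddle-style compartment interaction strengths.

    ``comp = log2(AA * BB / AB**2)`` is the overall compartmentalization
    strength; ``ab_difference = log2(AA) - log2(BB)`` compares A against B.
    """

    aa: float
    bb: float
    ab: float

    @property
    def comp(self) -> float:
        return float(np.log2(self.aa * self.bb / self.ab**2))

    @property
    def ab_difference(self) -> float:
        return float(np.log2(self.aa) - np.log2(self.bb))


def compartment_eigenvector(
    m: BinnedMatrix,
    cpg: CpGTrack,
    min_marginal: int = 1,
) -> EigTrack:
    """Per-chromosome first eigenvector of the Pearson correlation of the
    cis O/E matrix, oriented by CpG density.

    Bins with marginal counts below ``min_marginal`` (or masked CpG at the
    whole-chromosome level) are excluded before decomposition. Chromosomes
    with fewer than ``MIN_EIG_BINS`` usable bins yield a masked track with
    a warning.
    """
    if not m.bins.same_assembly(cpg.bins) or m.bins.binsize != cpg.bins.binsize:
        raise ValueError("matrix and CpG track must share bins")
    if not m.oe:
        observed_expected(m)
    values = np.full(m.bins.n_bins, np.nan)
    flipped = np.zeros(m.bins.n_chroms, dtype=bool)
    marg = m.marginals()
    for ci in range(m.bins.n_chroms):
        sl = m.bins.chrom_slice(ci)
        if ci not in m.oe:
            continue
        # offsets with no counts chromosome-wide give 0/0; treat as neutral
        oe = np.where(np.isfinite(m.oe[ci]), m.oe[ci], 1.0)
        good = marg[sl] >= min_marginal
        if good.sum() < MIN_EIG_BINS:
            warnings.warn(
                f"chromosome {m.bins.chroms[ci]}: fewer than {MIN_EIG_BINS} "
                "usable bins; eigenvector masked",
                stacklevel=2,
            )
            continue
        sub = oe[np.ix_(good, good)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr[~np.isfinite(corr)] = 0.0
        evals, evecs = np.linalg.eigh(corr)
        vec = evecs[:, -1]
        cpg_sub = cpg.values[sl][good]
        ok = np.isfinite(cpg_sub)
        if ok.sum() >= 2:
            r = np.corrcoef(vec[ok], cpg_sub[ok])[0, 1]
            if np.isfinite(r) and r < 0:
                vec = -vec
                flipped[ci] = True
        chrom_vals = np.full(sl.stop - sl.start, np.nan)
        chrom_vals[good] = vec
        values[sl] = chrom_vals
    masked_fraction = float(np.mean(~np.isfinite(values)))
    return EigTrack(m.bins, values, flipped, masked_fraction)


def scab_profile(
    cs: ContactSet,
    cpg: CpGTrack,
    min_separation: int = SCAB_MIN_SEPARATION,
    min_support: int = SCAB_MIN_SUPPORT,
    sample_id: str | None = None,
) -> ScABProfile:
    """Contact-weighted mean CpG density of each bin's long-range partners.

    ``scab(i) = sum_j w_ij * cpg(j) / sum_j w_ij`` where ``w_ij`` counts
    contacts between bins i and j (cis beyond ``min_separation``, plus all
    trans; j != i). Bins with support below ``min_support``, and partners
    with masked CpG, are excluded.
    """
    bins = cpg.bins
    if not np.isfinite(cpg.values).any():
        raise ValueError("CpG track is fully masked")
    b1 = bins.bin_of(cs.c1, cs.p1)
    b2 = bins.bin_of(cs.c2, cs.p2)
    keep = (cs.c1 != cs.c2) | ((cs.p2 - cs.p1) >= min_separation)
    keep &= b1 != b2
    b1, b2 = b1[keep], b2[keep]

    n = bins.n_bins
    wsum = np.zeros(n)
    csum = np.zeros(n)
    cpg_ok = np.isfinite(cpg.values)
    # each contact contributes to both endpoint bins, weighted by the
    # partner's CpG value
    for src, dst in ((b1, b2), (b2, b1)):
        ok = cpg_ok[dst]
        np.add.at(wsum, src[ok], cpg.values[dst[ok]])
        np.add.at(csum, src[ok], 1.0)
    values = np.full(n, np.nan)
    good = csum >= min_support
    values[good] = wsum[good] / csum[good]
    values[~cpg_ok] = np.nan
    return ScABProfile(
        bins, values, csum,
        sample_id=cs.sample_id if sample_id is None else sample_id,
    )


def scab_sampling_sd(a: ScABProfile, b: ScABProfile, cpg: CpGTrack) -> np.ndarray:
    """Per-bin standard deviation of the scA/B difference between two
    profiles of the same genome, under the binomial/multinomial sampling
    noise model: the value is a mean of ~support i.i.d. partner CpG draws,
    so its s.d. is sd(CpG) / sqrt(support)."""
    spread = np.nanstd(cpg.values)
    with np.errstate(divide="ignore"):
        var = spread**2 / a.support + spread**2 / b.support
    return np.sqrt(var)


def saddle_strengths(
    m: BinnedMatrix,
    ranking: np.ndarray,
    quantile: float = SADDLE_QUANTILE,
    min_bins: int = 10,
) -> CompartmentStrengths:
    """Compartment interaction strengths from quantiles of a ranking track.

    Bins are ranked by ``ranking`` (an eigenvector or scA/B profile over
    the matrix bins); AA is the mean cis O/E among pairs of top-quantile
    bins, BB among bottom-quantile pairs, AB across. The diagonal is
    excluded. Uses the matrix's O/E layer, computing it if absent.
    """
    ranking = np.asarray(ranking, dtype=float)
    if ranking.shape != (m.bins.n_bins,):
        raise ValueError("ranking must cover the matrix bins")
    if not m.oe:
        observed_expected(m)
    finite = np.isfinite(ranking)
    if finite.sum() < min_bins:
        raise ValueError("too few unmasked bins for saddle analysis")
    lo_cut = np.nanquantile(ranking, quantile)
    hi_cut = np.nanquantile(ranking, 1.0 - quantile)
    is_a = finite & (ranking >= hi_cut)
    is_b = finite & (ranking <= lo_cut)

    sums = {"aa": 0.0, "bb": 0.0, "ab": 0.0}
    counts = {"aa": 0, "bb": 0, "ab": 0}
    for ci, oe in m.oe.items():
        sl = m.bins.chrom_slice(ci)
        a_loc = np.flatnonzero(is_a[sl])
        b_loc = np.flatnonzero(is_b[sl])
        valid = np.isfinite(oe)
        for key, rows, cols in (
            ("aa", a_loc, a_loc), ("bb", b_loc, b_loc), ("ab", a_loc, b_loc),
        ):
            if rows.size == 0 or cols.size == 0:
                continue
            sub = oe[np.ix_(rows, cols)]
            vm = valid[np.ix_(rows, cols)]
            if rows is cols or key != "ab":
                off_diag = rows[:, None] != cols[None, :]
                vm = vm & off_diag
            sums[key] += np.nansum(np.where(vm, sub, 0.0))
            counts[key] += int(vm.sum())
    if min(counts.values()) == 0:
        raise ValueError("empty saddle quantile; too few usable bins")
    aa, bb, ab = (sums[k] / counts[k] for k in ("aa", "bb", "ab"))
    return CompartmentStrengths(aa=aa, bb=bb, ab=ab)


def scab_from_contacts(
    cs: ContactSet, cpg: CpGTrack, **kwargs
) -> ScABProfile:
    """Convenience alias used by the pipeline."""
    return scab_profile(cs, cpg, **kwargs)
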