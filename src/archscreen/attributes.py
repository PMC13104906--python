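"""Per-sample computation of the 7 architectural attributes.

From coarse to fine scale: chromosome intermingling, the contact-distance
distribution (short / long / very-long band fractions), overall
compartmentalization strength (COMP, with its AA/BB/AB components), the
A-B difference, the per-locus scA/B profile, overall domain-boundary
strength, and overall loop strength (P2LL).

Attribute definitions are ratios or fractions wherever possible so they are
robust to sequencing depth; cross-sample comparisons can additionally
equalize depth by downsampling every sample to the minimum count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import saddle_strengths, scab_profile
from .contacts import ContactSet, downsample
from .genome import CpGTrack, GenomeBins
from .locality import (
    apa_p2ll,
    boundary_strength,
    call_boundaries,
    distance_profile,
    insulation_profile,
    intermingling,
    reference_flanks,
)
from .matrix import bin_contacts, observed_expected

__all__ = ["AttributeContext", "compute_attributes", "attribute_table", "SCALAR_ATTRIBUTES"]

SCALAR_ATTRIBUTES = (
    "intermingling",
    "frac_short",
    "frac_long",
    "frac_very_long",
    "aa",
    "bb",
    "ab",
    "comp_strength",
    "ab_difference",
    "boundary_strength",
    "p2ll",
)

MIN_CONTACTS_QC = 10_000


@dataclass
class AttributeContext:
    """Shared references needed to score every sample of a comparison.

    Reference boundaries (and their flanks) are called once — from a pooled
    vehicle or supplied ground truth — and held fixed across samples.
    """

    cpg: CpGTrack                       # at the scA/B resolution (1 Mb)
    loops: np.ndarray | None = None     # (chrom_idx, mid1, mid2) bp rows
    ref_boundaries: np.ndarray | None = None   # global bins at insulation res
    ref_flanks: list | None = None
    scab_binsize: int = 1_000_000
    insulation_binsize: int = 25_000
    insulation_window: int = 250_000
    apa_binsize: int = 50_000
    apa_half_window: int = 5
    oe_log_bands: int | None = 3  # smoothed expected for saddle strengths

    def bins(self, binsize: int) -> GenomeBins:
        return self.cpg.bins.with_binsize(binsize)

    def set_reference_from(self, cs: ContactSet, threshold: float = -0.2):
        """Call reference boundaries (with flanks) from a pooled sample."""
        m = bin_contacts(cs, self.bins(self.insulation_binsize))
        track = insulation_profile(m, self.insulation_window, threshold)
        self.ref_boundaries = track.boundaries
        self.ref_flanks = reference_flanks(track, track.boundaries)
        return self

    def set_reference_boundaries(self, positions_bp):
        """Fix reference boundaries from known (chrom_idx, pos) bp pairs;
        flank bins default to half an insulation window on each side."""
        bins = self.bins(self.insulation_binsize)
        w = self.insulation_window // self.insulation_binsize
        bnds, flanks = [], []
        for ci, pos in positions_bp:
            b = int(bins.offsets[ci] + (pos - 1) // self.insulation_binsize)
            sl = bins.chrom_slice(int(ci))
            if b - w < sl.start or b + w >= sl.stop:
                continue
            bnds.append(b)
            flanks.append((b - w, b + w))
        self.ref_boundaries = np.asarray(bnds, dtype=int)
        self.ref_flanks = flanks
        return self


def compute_attributes(cs: ContactSet, ctx: AttributeContext) -> dict:
    """All scalar attributes plus the scA/B profile of one sample."""
    out: dict = {"sample_id": cs.sample_id, "n_contacts": len(cs)}
    out["qc_pass"] = len(cs) >= MIN_CONTACTS_QC

    prof = distance_profile(cs)
    out["intermingling"] = intermingling(cs)
    out["frac_short"] = prof.frac_short
    out["frac_long"] = prof.frac_long
    out["frac_very_long"] = prof.frac_very_long
    out["distance_profile"] = prof

    scab = scab_profile(cs, ctx.cpg)
    out["scab"] = scab

    m1 = bin_contacts(cs, ctx.bins(ctx.scab_binsize))
    # smoothed expected keeps the saddle strengths depth-stable
    observed_expected(m1, log_bands=ctx.oe_log_bands)
    strengths = saddle_strengths(m1, scab.values)
    out["aa"], out["bb"], out["ab"] = strengths.aa, strengths.bb, strengths.ab
    out["comp_strength"] = strengths.comp
    out["ab_difference"] = strengths.ab_difference

    if ctx.ref_boundaries is not None and ctx.ref_boundaries.size:
        m25 = bin_contacts(cs, ctx.bins(ctx.insulation_binsize))
        track = insulation_profile(m25, ctx.insulation_window)
        out["boundary_strength"] = boundary_strength(
            track, ctx.ref_boundaries, ctx.ref_flanks
        )
    else:
        out["boundary_strength"] = np.nan

    if ctx.loops is not None and len(ctx.loops):
        m50 = bin_contacts(cs, ctx.bins(ctx.apa_binsize))
        loop = apa_p2ll(m50, ctx.loops, ctx.apa_half_window)
        out["p2ll"] = loop.p2ll
    else:
        out["p2ll"] = np.nan
    return out


def attribute_table(
    sets: dict,
    ctx: AttributeContext,
    sheet: pd.DataFrame | None = None,
    equalize_depth: bool = False,
    seed=0,
):
    """Attribute rows for a collection of samples.

    Returns ``(table, scab_matrix)``: one row of scalar attributes per
    sample joined with sample-sheet metadata, and the sample x 1-Mb-bin
    scA/B matrix. With ``equalize_depth`` every sample is first
    downsampled to the smallest per-sample contact count.
    """
    sets = dict(sets)
    if equalize_depth:
        n_min = min(len(cs) for cs in sets.values())
        sets = {
            sid: downsample(cs, n_min, np.random.SeedSequence([seed, i]))
            for i, (sid, cs) in enumerate(sorted(sets.items()))
        }
    rows, profiles = [], {}
    for sid in sets:
        res = compute_attributes(sets[sid], ctx)
        profiles[sid] = res.pop("scab").values
        res.pop("distance_profile")
        rows.append(res)
    tbl = pd.DataFrame(rows).set_index("sample_id")
    if sheet is not None:
        meta = sheet.set_index("sample_id")
        tbl = tbl.join(meta, how="left")
    scab_matrix = pd.DataFrame.from_dict(profiles, orient="index")
    scab_matrix = scab_matrix.loc[tbl.index]
    return tbl, scab_matrix
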