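"""Synthetic contact-map generator with known architectural ground truth.

Every downstream stage of the pipeline is testable by parameter recovery
against fixtures produced here. The generative model draws each contact
from a product of independent architectural factors:

* cis/trans split: a contact is interchromosomal with probability
  ``f_trans``; trans pairs are uniform over positions, reweighted by the
  compartment term.
* cis distance law: genomic separation ``s`` follows a truncated power law
  ``P(s) ~ s**-alpha`` on ``[min_cis_dist, L)``.
* compartmentalization: each ground-truth 1-Mb block carries a compartment
  value in CpG-density units; values map to an affinity ``a`` in
  ``[-a_clip, a_clip]`` (A positive, B negative) and a bin pair is weighted
  by ``c ** (a_i * a_j)`` — same-compartment pairs enriched up to ``c``,
  cross pairs depleted down to ``1/c``.
* domains: short-range pairs (< ``tad_max_dist``) that straddle a planted
  boundary are depleted by ``d`` in (0, 1].
* loops: pairs falling in a planted anchor pixel are enriched by
  ``loop_mult``.
* library complexity: reads sample with replacement from ``complexity``
  distinct molecules, producing exact-duplicate contacts; ``None`` means
  unbounded complexity (all reads unique).

Weights are applied by rejection sampling against the distance-law x
uniform-position proposal, so no full matrix is ever materialized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactSet, write_pairs
from .genome import CpGTrack, GenomeBins

__all__ = [
    "SyntheticGenomeSpec",
    "PerturbationDelta",
    "default_spec",
    "simulate_contacts",
    "perturb_spec",
    "make_screen_fixture",
    "standard_deltas",
    "make_profile_fixture",
]

_CHROM_NAMES = ("chr1", "chr2")


@dataclass(frozen=True)
class PerturbationDelta:
    """Multiplicative changes to generator parameters, plus optional additive
    shifts of the ground-truth compartment value at a chosen locus subset
    (a stand-in for a compound's effect)."""

    mult_c: float = 1.0
    mult_f_trans: float = 1.0
    mult_alpha: float = 1.0
    mult_d: float = 1.0
    mult_loop: float = 1.0
    shift_bins: tuple = ()        # global 1-Mb bin indices
    shift_value: float = 0.0      # CpG-density units
    name: str = "identity"

    def is_identity(self) -> bool:
        return (
            self.mult_c == self.mult_f_trans == self.mult_alpha
            == self.mult_d == self.mult_loop == 1.0
            and (not self.shift_bins or self.shift_value == 0.0)
        )


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome and its contact model."""

    chrom_lengths: tuple = (60_000_000, 60_000_000)
    block_binsize: int = 1_000_000
    comp_value: tuple = ()        # per global 1-Mb bin, CpG-density units
    alpha: float = 1.0            # cis decay exponent, P(s) ~ s**-alpha
    f_trans: float = 0.05         # trans contact fraction
    c: float = 1.5                # compartment contrast (>= 1)
    d: float = 1.0                # boundary depletion in (0, 1]; 1 = no TADs
    tad_boundaries: tuple = ()    # per-chrom tuples of bp positions
    loop_anchors: tuple = ()      # rows (chrom_idx, pos1, pos2), bp midpoints
    loop_mult: float = 1.0
    anchor_binsize: int = 50_000  # pixel size of planted loop anchors
    cpg_mean_a: float = 0.022
    cpg_mean_b: float = 0.012
    cpg_sd: float = 0.003
    complexity: float | None = None
    min_cis_dist: int = 10_000
    tad_max_dist: int = 2_000_000
    aff_mid: float = 0.017        # compartment value mapping to affinity 0
    aff_halfspan: float = 0.005   # value offset mapping to affinity +/-1
    aff_clip: float = 1.5
    applied_delta: PerturbationDelta | None = None

    def __post_init__(self):
        if not (0.0 <= self.f_trans <= 1.0):
            raise ValueError("f_trans must lie in [0, 1]")
        if self.c < 1.0:
            raise ValueError("compartment contrast c must be >= 1")
        if not (0.0 < self.d <= 1.0):
            raise ValueError("boundary depletion d must lie in (0, 1]")
        if self.loop_mult <= 0 or self.alpha <= 0:
            raise ValueError("multipliers and alpha must be positive")
        n_blocks = sum(
            -(-length // self.block_binsize) for length in self.chrom_lengths
        )
        if self.comp_value and len(self.comp_value) != n_blocks:
            raise ValueError("comp_value must cover every ground-truth block")

    # -- derived views ----------------------------------------------------
    def genome_bins(self, binsize: int | None = None) -> GenomeBins:
        return GenomeBins(
            _CHROM_NAMES[: len(self.chrom_lengths)],
            np.array(self.chrom_lengths, dtype=np.int64),
            binsize or self.block_binsize,
        )

    @property
    def block_bins(self) -> GenomeBins:
        return self.genome_bins(self.block_binsize)

    def comp_values(self) -> np.ndarray:
        if self.comp_value:
            return np.asarray(self.comp_value, dtype=float)
        # default checkerboard: alternating A/B in 5-block runs per chromosome
        vals = []
        for length in self.chrom_lengths:
            n = -(-length // self.block_binsize)
            pattern = (np.arange(n) // 5) % 2 == 0
            vals.append(np.where(pattern, self.cpg_mean_a, self.cpg_mean_b))
        return np.concatenate(vals)

    def labels(self) -> np.ndarray:
        """Ground-truth A (True) / B (False) label per 1-Mb block."""
        return self.comp_values() >= self.aff_mid

    def affinity(self) -> np.ndarray:
        a = (self.comp_values() - self.aff_mid) / self.aff_halfspan
        return np.clip(a, -self.aff_clip, self.aff_clip)

    def make_cpg_track(self, seed=0, binsize: int | None = None) -> CpGTrack:
        """CpG density per bin: Gaussian around the A/B means, truncated at 0.

        The track is a property of the genome, so it derives from the A/B
        labels and is unaffected by perturbations of the contact model.
        """
        rng = np.random.default_rng(seed)
        means = np.where(self.labels(), self.cpg_mean_a, self.cpg_mean_b)
        vals = np.clip(rng.normal(means, self.cpg_sd), 0.0, 0.25)
        if binsize is None or binsize == self.block_binsize:
            return CpGTrack(self.block_bins, vals)
        if self.block_binsize % binsize:
            raise ValueError("binsize must divide the ground-truth block size")
        bins = self.genome_bins(binsize)
        out = np.empty(bins.n_bins)
        blocks = self.block_bins
        for ci in range(bins.n_chroms):
            sl, bl = bins.chrom_slice(ci), blocks.chrom_slice(ci)
            starts = np.arange(sl.stop - sl.start) * binsize
            out[sl] = vals[bl][(starts // self.block_binsize)]
        return CpGTrack(bins, out)

    def loop_bedpe(self) -> pd.DataFrame:
        """Planted loop anchors as a BEDPE-style table."""
        chroms = np.asarray(_CHROM_NAMES[: len(self.chrom_lengths)])
        rows = np.asarray(self.loop_anchors, dtype=np.int64).reshape(-1, 3)
        half = self.anchor_binsize // 2
        return pd.DataFrame(
            {
                "chrom1": chroms[rows[:, 0]],
                "start1": rows[:, 1] - half,
                "end1": rows[:, 1] + half,
                "chrom2": chroms[rows[:, 0]],
                "start2": rows[:, 2] - half,
                "end2": rows[:, 2] + half,
            }
        )


def _default_boundaries(chrom_lengths, spacing=1_200_000):
    out = []
    for length in chrom_lengths:
        out.append(tuple(range(spacing, length - spacing // 2, spacing)))
    return tuple(out)


def _default_loops(chrom_lengths, spacing=1_300_000, base_dist=1_400_000):
    """Loop anchors along the diagonal, distances 1.4-1.6 Mb, spaced 1.3 Mb."""
    anchors = []
    for ci, length in enumerate(chrom_lengths):
        x = 1_000_000
        k = 0
        # keep a margin past the far anchor so APA windows fit the matrix
        while x + base_dist + 600_000 < length:
            dist = base_dist + (k % 5) * 50_000
            anchors.append((ci, x, x + dist))
            x += spacing
            k += 1
    return tuple(anchors)


def default_spec(**overrides) -> SyntheticGenomeSpec:
    """The default toy genome: 2 chromosomes x 60 Mb, 1-Mb ground-truth
    blocks alternating A/B in 5-block runs, planted boundaries every 1.2 Mb
    and loop anchors every 1.3 Mb at 1.4-1.6 Mb separations."""
    lengths = overrides.pop("chrom_lengths", (60_000_000, 60_000_000))
    kwargs = dict(
        chrom_lengths=lengths,
        tad_boundaries=_default_boundaries(lengths),
        loop_anchors=_default_loops(lengths),
    )
    kwargs.update(overrides)
    return SyntheticGenomeSpec(**kwargs)


# ---------------------------------------------------------------------------
# contact simulation
# ---------------------------------------------------------------------------


def _sample_power_law(rng, n, alpha, lo, hi):
    """Continuous truncated power law s**-alpha on [lo, hi] via inverse CDF."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return lo * np.exp(u * np.log(hi / lo))
    g = 1.0 - alpha
    return (lo**g + u * (hi**g - lo**g)) ** (1.0 / g)


class _Weigher:
    """Evaluate the architectural weight of proposed contacts."""

    def __init__(self, spec: SyntheticGenomeSpec):
        self.spec = spec
        self.aff = spec.affinity()
        self.blocks = spec.block_bins
        self.boundaries = [
            np.asarray(b, dtype=np.int64) for b in spec.tad_boundaries
        ]
        abins = spec.genome_bins(spec.anchor_binsize)
        keys = []
        for ci, p1, p2 in np.asarray(spec.loop_anchors, np.int64).reshape(-1, 3):
            b1 = abins.bin_of(np.array([ci]), np.array([p1]))[0]
            b2 = abins.bin_of(np.array([ci]), np.array([p2]))[0]
            keys.append(min(b1, b2) * abins.n_bins + max(b1, b2))
        self.abins = abins
        self.loop_keys = np.sort(np.asarray(keys, dtype=np.int64))
        amax = float(np.max(np.abs(self.aff))) if self.aff.size else 0.0
        self.w_comp_max = spec.c ** (amax * amax)

    def comp_weight(self, c1, p1, c2, p2):
        a1 = self.aff[self.blocks.bin_of(c1, p1)]
        a2 = self.aff[self.blocks.bin_of(c2, p2)]
        return self.spec.c ** (a1 * a2)

    def cis_weight(self, ci, p1, p2):
        """Weight of cis proposals on a single chromosome (p1 < p2)."""
        spec = self.spec
        w = self.comp_weight(
            np.full(p1.shape, ci, dtype=np.int32), p1,
            np.full(p1.shape, ci, dtype=np.int32), p2,
        )
        if spec.d < 1.0 and len(self.boundaries) > ci and self.boundaries[ci].size:
            b = self.boundaries[ci]
            crossing = np.searchsorted(b, p1) != np.searchsorted(b, p2)
            short = (p2 - p1) < spec.tad_max_dist
            w = np.where(crossing & short, w * spec.d, w)
        if spec.loop_mult != 1.0 and self.loop_keys.size:
            ab = self.abins
            off = ab.offsets[ci]
            k1 = off + (p1 - 1) // spec.anchor_binsize
            k2 = off + (p2 - 1) // spec.anchor_binsize
            keys = k1 * ab.n_bins + k2
            pos = np.searchsorted(self.loop_keys, keys)
            pos = np.minimum(pos, self.loop_keys.size - 1)
            hit = self.loop_keys[pos] == keys
            w = np.where(hit, w * spec.loop_mult, w)
        return w

    @property
    def cis_wmax(self):
        return self.w_comp_max * max(1.0, self.spec.loop_mult)


def _draw_cis(rng, spec, weigher, n):
    """Rejection-sample n cis contacts; returns (chrom, p1, p2) arrays."""
    lengths = np.asarray(spec.chrom_lengths, dtype=np.int64)
    p_chrom = lengths / lengths.sum()
    wmax = weigher.cis_wmax
    out_c, out_p1, out_p2 = [], [], []
    got, acc_est = 0, 0.5
    while got < n:
        m = int((n - got) / max(acc_est, 0.02) * 1.15) + 512
        m = min(m, 4_000_000)
        ci = rng.choice(lengths.size, size=m, p=p_chrom)
        L = lengths[ci]
        s = np.empty(m)
        for cc in range(lengths.size):
            mask = ci == cc
            if mask.any():
                s[mask] = _sample_power_law(
                    rng, int(mask.sum()), spec.alpha,
                    spec.min_cis_dist, lengths[cc] - 1,
                )
        s = np.minimum(s, L - 2).astype(np.int64)
        p1 = 1 + (rng.random(m) * (L - s - 1)).astype(np.int64)
        p2 = p1 + s
        w = np.empty(m)
        for cc in range(lengths.size):
            mask = ci == cc
            if mask.any():
                w[mask] = weigher.cis_weight(cc, p1[mask], p2[mask])
        keep = rng.random(m) * wmax < w
        acc_est = max(keep.mean(), 0.02)
        out_c.append(ci[keep])
        out_p1.append(p1[keep])
        out_p2.append(p2[keep])
        got += int(keep.sum())
    c = np.concatenate(out_c)[:n].astype(np.int32)
    return c, np.concatenate(out_p1)[:n], np.concatenate(out_p2)[:n]


def _draw_trans(rng, spec, weigher, n):
    lengths = np.asarray(spec.chrom_lengths, dtype=np.int64)
    nc = lengths.size
    pairs = [(i, j) for i in range(nc) for j in range(i + 1, nc)]
    pw = np.array([lengths[i] * lengths[j] for i, j in pairs], dtype=float)
    pw /= pw.sum()
    wmax = weigher.w_comp_max
    out = [[], [], [], []]
    got, acc_est = 0, 0.5
    while got < n:
        m = int((n - got) / max(acc_est, 0.05) * 1.15) + 256
        pi = rng.choice(len(pairs), size=m, p=pw)
        c1 = np.array([pairs[k][0] for k in range(len(pairs))], np.int32)[pi]
        c2 = np.array([pairs[k][1] for k in range(len(pairs))], np.int32)[pi]
        p1 = 1 + (rng.random(m) * (lengths[c1] - 1)).astype(np.int64)
        p2 = 1 + (rng.random(m) * (lengths[c2] - 1)).astype(np.int64)
        w = weigher.comp_weight(c1, p1, c2, p2)
        keep = rng.random(m) * wmax < w
        acc_est = max(keep.mean(), 0.05)
        for arr, vals in zip(out, (c1, p1, c2, p2)):
            arr.append(vals[keep])
        got += int(keep.sum())
    c1, p1, c2, p2 = (np.concatenate(a)[:n] for a in out)
    return c1.astype(np.int32), p1, c2.astype(np.int32), p2


def simulate_contacts(
    spec: SyntheticGenomeSpec, depth: int, seed, sample_id: str = ""
) -> ContactSet:
    """Draw ``depth`` read-pair contacts from the spec's product model.

    Deterministic given ``seed``. With finite ``complexity`` the returned
    set contains exact duplicates (reads resampling the same molecule);
    otherwise every read is a distinct molecule.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    weigher = _Weigher(spec)

    if spec.complexity is not None:
        mol_ids = rng.integers(0, int(spec.complexity), size=depth)
        uniq, inverse = np.unique(mol_ids, return_inverse=True)
        n_mol = uniq.size
    else:
        inverse = None
        n_mol = depth

    n_trans = rng.binomial(n_mol, spec.f_trans)
    n_cis = n_mol - n_trans
    cc, cp1, cp2 = _draw_cis(rng, spec, weigher, n_cis) if n_cis else (
        np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int64))
    tc1, tp1, tc2, tp2 = _draw_trans(rng, spec, weigher, n_trans) if n_trans else (
        np.empty(0, np.int32), np.empty(0, np.int64),
        np.empty(0, np.int32), np.empty(0, np.int64))

    c1 = np.concatenate([cc, tc1])
    p1 = np.concatenate([cp1, tp1])
    c2 = np.concatenate([cc, tc2])
    p2 = np.concatenate([cp2, tp2])
    if inverse is not None:
        c1, p1, c2, p2 = c1[inverse], p1[inverse], c2[inverse], p2[inverse]
    cs = ContactSet(
        spec.genome_bins(), c1, p1, c2, p2,
        sample_id=sample_id, n_total=depth,
    )
    return cs.validate()


# ---------------------------------------------------------------------------
# perturbations and screen fixtures
# ---------------------------------------------------------------------------


def perturb_spec(
    spec: SyntheticGenomeSpec, delta: PerturbationDelta
) -> SyntheticGenomeSpec:
    """Apply a delta, returning a new spec; the input is unchanged and the
    applied delta is recorded on the result for recovery tests."""
    comp = spec.comp_values().copy()
    if delta.shift_bins:
        idx = np.asarray(delta.shift_bins, dtype=int)
        comp[idx] += delta.shift_value
    return dataclasses.replace(
        spec,
        c=spec.c * delta.mult_c,
        f_trans=spec.f_trans * delta.mult_f_trans,
        alpha=spec.alpha * delta.mult_alpha,
        d=spec.d * delta.mult_d,
        loop_mult=spec.loop_mult * delta.mult_loop,
        comp_value=tuple(comp),
        applied_delta=delta,
    )


def standard_deltas() -> dict:
    """The canonical perturbation set used across recovery tests: one delta
    per architectural axis, each with a known expected attribute response."""
    shift_rng = np.random.default_rng(12345)
    shift_bins = tuple(sorted(shift_rng.choice(120, size=50, replace=False)))
    return {
        "trans_up": PerturbationDelta(mult_f_trans=2.0, name="trans_up"),
        "comp_up": PerturbationDelta(mult_c=1.5, name="comp_up"),
        "tad_strengthen": PerturbationDelta(mult_d=0.2, name="tad_strengthen"),
        "loop_up": PerturbationDelta(mult_loop=3.0, name="loop_up"),
        "scab_shift": PerturbationDelta(
            shift_bins=shift_bins, shift_value=0.004, name="scab_shift"
        ),
    }


def expected_directions(delta: PerturbationDelta) -> dict:
    """Ground-truth sign (+1/-1/0) of each attribute response to a delta."""
    sign = lambda x: int(np.sign(x))
    return {
        "intermingling": sign(delta.mult_f_trans - 1),
        "frac_very_long": sign(1 - delta.mult_alpha),
        "comp_strength": sign(delta.mult_c - 1),
        "ab_difference": 0,
        "boundary_strength": sign(1 - delta.mult_d),
        "p2ll": sign(delta.mult_loop - 1),
        "scab": sign(delta.shift_value) if delta.shift_bins else 0,
    }


def make_screen_fixture(
    n_conditions: int,
    n_replicates: int,
    depth: int,
    seed,
    deltas: list | None = None,
    base_spec: SyntheticGenomeSpec | None = None,
):
    """Build a toy perturbation screen: vehicle plus perturbed conditions.

    Returns ``(sheet, contact_sets, truth)`` where ``sheet`` is a sample
    sheet DataFrame, ``contact_sets`` maps sample id to ContactSet, and
    ``truth`` maps condition name to its delta and expected attribute
    directions. Deterministic (byte-identical) given ``seed``.
    """
    if n_conditions < 1 or n_replicates < 1:
        raise ValueError("counts must be >= 1")
    spec = base_spec if base_spec is not None else default_spec()
    if deltas is None:
        pool = list(standard_deltas().values())
        deltas = [pool[i % len(pool)] for i in range(n_conditions)]
    if len(deltas) != n_conditions:
        raise ValueError("need one delta per condition")

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.spawn((n_conditions + 1) * n_replicates))
    rows, sets, truth = [], {}, {}

    def add_condition(name, cond_spec, is_vehicle):
        for rep in range(n_replicates):
            sid = f"{name}_rep{rep + 1}"
            sets[sid] = simulate_contacts(
                cond_spec, depth, next(child_seeds), sample_id=sid
            )
            rows.append(
                {
                    "path": "", "sample_id": sid, "condition": name,
                    "compound": name if not is_vehicle else "vehicle",
                    "dose": 0.0 if is_vehicle else 1.0, "time": 24.0,
                    "cell_type": "synthetic", "replicate": rep + 1,
                    "is_vehicle": is_vehicle, "batch": "b1",
                }
            )

    add_condition("vehicle", spec, True)
    for delta in deltas:
        cond_spec = perturb_spec(spec, delta)
        add_condition(delta.name, cond_spec, False)
        truth[delta.name] = {
            "delta": delta,
            "directions": expected_directions(delta),
        }
    return pd.DataFrame(rows), sets, truth


def write_fixture(sheet, sets, truth, spec, outdir):
    """Write a fixture to disk: pairs files, sample sheet CSV, truth JSON."""
    import os

    os.makedirs(outdir, exist_ok=True)
    sheet = sheet.copy()
    paths = []
    for sid in sheet["sample_id"]:
        path = os.path.join(outdir, f"{sid}.pairs")
        write_pairs(sets[sid], path)
        paths.append(path)
    sheet["path"] = paths
    sheet.to_csv(os.path.join(outdir, "samples.csv"), index=False)
    serializable = {
        name: {
            "delta": dataclasses.asdict(info["delta"]),
            "directions": info["directions"],
        }
        for name, info in truth.items()
    }
    with open(os.path.join(outdir, "truth.json"), "wt") as fh:
        json.dump(serializable, fh, indent=1)
    with open(os.path.join(outdir, "chrom.sizes"), "wt") as fh:
        bins = spec.genome_bins()
        for name, length in zip(bins.chroms, bins.lengths):
            fh.write(f"{name}\t{length}\n")
    spec.make_cpg_track().to_bedgraph(os.path.join(outdir, "cpg.bedgraph"))
    bins = spec.genome_bins()
    with open(os.path.join(outdir, "boundaries.bed"), "wt") as fh:
        for ci, positions in enumerate(spec.tad_boundaries):
            for p in positions:
                fh.write(f"{bins.chroms[ci]}\t{p - 1}\t{p}\n")
    return sheet


def make_profile_fixture(
    n_loci: int,
    n_per_group: int,
    shift_bins,
    shift_value: float,
    noise_sd: float,
    seed,
    baseline: float = 0.017,
):
    """Replicate-level scA/B profile matrices under a planted locus shift.

    Emulates the per-locus differential setting directly at the profile
    level: replicate profiles are the ground truth plus i.i.d. Gaussian
    noise, with ``shift_bins`` moved by ``shift_value`` in the treated
    group. Returns (vehicle, treated) arrays of shape (n_per_group, n_loci).
    """
    rng = np.random.default_rng(seed)
    truth = np.full(n_loci, baseline)
    veh = truth + rng.normal(0, noise_sd, size=(n_per_group, n_loci))
    shifted = truth.copy()
    shifted[np.asarray(shift_bins, dtype=int)] += shift_value
    trt = shifted + rng.normal(0, noise_sd, size=(n_per_group, n_loci))
    return veh, trt
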