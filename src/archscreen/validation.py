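"""Validation studies: the package's own end-to-end quality checks.

Each function runs a self-contained study on synthetic data with known
ground truth and returns plain numbers. The test suite asserts on them;
``scripts/acceptance.py`` reports them. Study sizes are chosen so the full
battery runs in minutes on one core while keeping statistical margins wide;
the methods note records the sizes used.

Oracle helpers here are deliberately naive re-implementations (explicit
loops, closed forms, textbook bisection) kept independent of the optimized
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attributes import AttributeContext, attribute_table, SCALAR_ATTRIBUTES
from .compartments import scab_profile, scab_sampling_sd
from .differential import bh_adjust, differential_scab, screen_differential, ttest_equal_var
from .matrix import bin_contacts, observed_expected
from .simulate import (
    PerturbationDelta,
    default_spec,
    make_profile_fixture,
    make_screen_fixture,
    simulate_contacts,
    standard_deltas,
)

RECOVERY_KEY_ATTRIBUTE = {
    "trans_up": "intermingling",
    "comp_up": "comp_strength",
    "tad_strengthen": "boundary_strength",
    "loop_up": "p2ll",
}

CALIBRATION_ATTRIBUTES = (
    "intermingling", "frac_short", "frac_very_long",
    "comp_strength", "ab_difference", "boundary_strength", "p2ll",
)


def _context_for(spec, cpg_seed=0) -> AttributeContext:
    ctx = AttributeContext(
        cpg=spec.make_cpg_track(cpg_seed),
        loops=np.asarray(spec.loop_anchors, dtype=np.int64).reshape(-1, 3),
    )
    ctx.set_reference_boundaries(
        [(ci, p) for ci, bs in enumerate(spec.tad_boundaries) for p in bs]
    )
    return ctx


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


def brute_force_insulation(dense: np.ndarray, w: int) -> np.ndarray:
    """O(n * w^2) sliding-diamond sums by explicit loops (oracle)."""
    n = dense.shape[0]
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        s = 0.0
        for r in range(i - w, i):
            for c in range(i + 1, i + w + 1):
                s += dense[r, c]
        out[i] = s
    return out


def bh_step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Naive O(n^2) Benjamini-Hochberg step-up (oracle)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = min(running, 1.0)
    return adj


def bisection_complexity_oracle(n_total, n_unique, rel_tol=1e-9) -> float:
    """Textbook bisection on C*(1 - exp(-n/C)) = u (oracle)."""
    lo, hi = float(n_unique), float(n_unique)
    while hi * (1.0 - np.exp(-n_total / hi)) < n_unique:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * (1.0 - np.exp(-n_total / mid)) < n_unique:
            lo = mid
        else:
            hi = mid
        if (hi - lo) / hi < rel_tol:
            break
    return 0.5 * (lo + hi)


def oracle_equivalence(seed: int = 0) -> dict:
    """Compare core primitives against their independent oracles."""
    from scipy.stats import ttest_ind

    from .compartments import compartment_eigenvector
    from .contacts import estimate_complexity
    from .genome import CpGTrack
    from .locality import diamond_sums, insulation_profile

    rng = np.random.default_rng(seed)
    out = {}

    # eigenvector vs dense decomposition on a small checkerboard genome
    spec = default_spec(chrom_lengths=(40_000_000, 40_000_000), c=2.0)
    cs = simulate_contacts(spec, 300_000, rng.integers(2**31), "eig")
    m = bin_contacts(cs, spec.genome_bins(1_000_000))
    observed_expected(m)
    cpg = spec.make_cpg_track(0)
    track = compartment_eigenvector(m, cpg)
    errs = []
    for ci in range(m.bins.n_chroms):
        sl = m.bins.chrom_slice(ci)
        oe = np.where(np.isfinite(m.oe[ci]), m.oe[ci], 1.0)
        n = oe.shape[0]
        # manual Pearson correlation + eigendecomposition (oracle)
        z = oe - oe.mean(axis=1, keepdims=True)
        z /= np.sqrt((z**2).sum(axis=1, keepdims=True))
        corr = z @ z.T
        w, v = np.linalg.eig(corr)
        lead = np.real(v[:, np.argmax(np.real(w))])
        lead /= np.linalg.norm(lead)
        got = track.values[sl]
        got = got / np.linalg.norm(got)
        errs.append(min(np.max(np.abs(got - lead)), np.max(np.abs(got + lead))))
    out["eig_oracle_max_abs_err"] = float(max(errs))

    # insulation vs brute-force diamond, exact
    small = default_spec(chrom_lengths=(7_500_000, 7_500_000))
    cs2 = simulate_contacts(small, 100_000, rng.integers(2**31), "ins")
    m25 = bin_contacts(cs2, small.genome_bins(25_000))
    insulation_profile(m25, 250_000)  # exercises the full track path
    w = 250_000 // 25_000
    diffs = []
    for ci in range(2):
        oracle = brute_force_insulation(m25.cis_dense(ci), w)
        got = diamond_sums(m25, ci, w)
        ok = np.isfinite(oracle)
        diffs.append(np.max(np.abs(got[ok] - oracle[ok])))
    out["insulation_oracle_max_abs_err"] = float(max(diffs))

    # BH vs naive step-up on 1,000 random p-vectors
    bh_err = 0.0
    for _ in range(1000):
        p = rng.random(rng.integers(1, 60))
        bh_err = max(bh_err, float(np.max(np.abs(bh_adjust(p) - bh_step_up_oracle(p)))))
    out["bh_oracle_max_abs_err"] = bh_err

    # pooled t-test vs scipy
    t_err = 0.0
    for _ in range(200):
        x = rng.normal(size=rng.integers(2, 12))
        y = rng.normal(size=rng.integers(2, 12))
        t, df, p = ttest_equal_var(x, y)
        ref = ttest_ind(x, y, equal_var=True)
        t_err = max(t_err, abs(t - ref.statistic), abs(p - ref.pvalue))
    out["ttest_oracle_max_abs_err"] = t_err

    # complexity estimator vs bisection oracle + saturation round trip
    c_err = rt_err = 0.0
    for n_total in (100, 1_000, 50_000, 1_000_000):
        for frac in (0.5, 0.8, 0.95, 0.99):
            n_unique = int(n_total * frac)
            est = estimate_complexity(n_total, n_unique)
            ref = bisection_complexity_oracle(n_total, n_unique)
            c_err = max(c_err, abs(est - ref) / ref)
            back = est * (1.0 - np.exp(-n_total / est))
            rt_err = max(rt_err, abs(back - n_unique) / n_unique)
    out["complexity_oracle_max_rel_err"] = c_err
    out["complexity_roundtrip_max_rel_err"] = rt_err
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def parameter_recovery(
    n_seeds: int = 20,
    depth: int = 500_000,
    n_replicates: int = 4,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of each planted perturbation across fixture seeds.

    A perturbation counts as detected when its key attribute is significant
    (BH-adjusted, screen-wide family) with the ground-truth sign.
    """
    deltas = [standard_deltas()[k] for k in RECOVERY_KEY_ATTRIBUTE]
    spec = default_spec()
    ctx = _context_for(spec)
    hits = {name: 0 for name in RECOVERY_KEY_ATTRIBUTE}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        fixture_seed = int(child.generate_state(1)[0] % (2**31))
        sheet, sets, _ = make_screen_fixture(
            len(deltas), n_replicates, depth, fixture_seed,
            deltas=deltas, base_spec=spec,
        )
        tbl, _ = attribute_table(sets, ctx, sheet=sheet)
        diff = screen_differential(tbl)
        for name, attr in RECOVERY_KEY_ATTRIBUTE.items():
            row = diff[(diff.condition == name) & (diff.unit == attr)].iloc[0]
            if row.p_adj < alpha and row.effect > 0:
                hits[name] += 1
    return {
        f"detect_{name}": hits[name] / n_seeds for name in RECOVERY_KEY_ATTRIBUTE
    }


def scab_shift_recovery(
    n_seeds: int = 20,
    n_loci: int = 240,
    n_shifted: int = 50,
    shift: float = 0.004,
    noise_sd: float = 0.001,
    n_per_group: int = 4,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity and FDR of the per-locus scA/B volcano on planted shifts."""
    rng = np.random.default_rng(seed)
    sens, fdrs = [], []
    for _ in range(n_seeds):
        shifted = rng.choice(n_loci, size=n_shifted, replace=False)
        veh, trt = make_profile_fixture(
            n_loci, n_per_group, shifted, shift, noise_sd,
            rng.integers(2**31),
        )
        res = differential_scab(
            np.vstack([trt, veh]),
            treated_ids=np.arange(n_per_group),
            vehicle_ids=np.arange(n_per_group, 2 * n_per_group),
        )
        hit = res["p_adj"].to_numpy() < alpha
        is_true = np.isin(res["locus"].to_numpy(), shifted)
        sens.append(hit[is_true].mean())
        n_disc = hit.sum()
        fdrs.append((hit & ~is_true).sum() / n_disc if n_disc else 0.0)
    return {
        "scab_shift_sensitivity": float(np.mean(sens)),
        "scab_shift_fdr": float(np.mean(fdrs)),
    }


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def null_calibration(
    n_fixtures: int = 60,
    depth: int = 50_000,
    n_replicates: int = 4,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Per-test type-I error of the attribute framework on null fixtures.

    Vehicle vs an identity-delta condition: every rejection is false. Uses
    a smaller genome (2 x 30 Mb) since calibration concerns the test, not
    the map scale.
    """
    spec = default_spec(chrom_lengths=(30_000_000, 30_000_000))
    ctx = _context_for(spec)
    null_delta = [PerturbationDelta(name="null")]
    pvals = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_fixtures):
        fixture_seed = int(child.generate_state(1)[0] % (2**31))
        sheet, sets, _ = make_screen_fixture(
            1, n_replicates, depth, fixture_seed,
            deltas=null_delta, base_spec=spec,
        )
        tbl, _ = attribute_table(sets, ctx, sheet=sheet)
        diff = screen_differential(tbl, attributes=CALIBRATION_ATTRIBUTES)
        pvals.extend(diff["p"].tolist())
    pvals = np.asarray(pvals)
    return {
        "null_n_tests": int(pvals.size),
        "null_type_i_error": float(np.mean(pvals < alpha)),
    }


def volcano_permutation_uniformity(
    n_loci: int = 240, n_samples: int = 8, noise_sd: float = 0.001, seed: int = 0
) -> dict:
    """KS test of volcano p-values against uniform under label permutation."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    profiles = 0.017 + rng.normal(0, noise_sd, size=(n_samples, n_loci))
    perm = rng.permutation(n_samples)
    res = differential_scab(
        profiles,
        treated_ids=perm[: n_samples // 2],
        vehicle_ids=perm[n_samples // 2 :],
    )
    stat, p = kstest(res["p"].to_numpy(), "uniform")
    return {"volcano_ks_statistic": float(stat), "volcano_ks_p": float(p)}


# ---------------------------------------------------------------------------
# depth robustness
# ---------------------------------------------------------------------------


def _structured_spec():
    """A spec with every architectural feature active and an asymmetric
    A/B contrast, so no attribute sits at zero."""
    spec = default_spec(c=1.5, d=0.4, loop_mult=5.0)
    labels = spec.labels()
    comp = np.where(labels, 0.0235, 0.0135)
    return default_spec(
        c=1.5, d=0.4, loop_mult=5.0, comp_value=tuple(comp)
    )


def depth_robustness(
    shallow_depth: int = 200_000,
    deep_depth: int = 1_000_000,
    n_shallow: int = 16,
    n_deep: int = 8,
    seed: int = 0,
) -> dict:
    """Attribute agreement between shallow and deep sequencing of one spec.

    Scalars are compared as replicate means at each depth (relative
    difference); scA/B is compared per bin between one shallow and one deep
    sample against the binomial sampling-noise model.
    """
    spec = _structured_spec()
    ctx = _context_for(spec)
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_shallow + n_deep)]
    shallow = {
        f"s{i}": simulate_contacts(spec, shallow_depth, seeds[i], f"s{i}")
        for i in range(n_shallow)
    }
    deep = {
        f"d{i}": simulate_contacts(spec, deep_depth, seeds[n_shallow + i], f"d{i}")
        for i in range(n_deep)
    }
    tbl_s, _ = attribute_table(shallow, ctx)
    tbl_d, _ = attribute_table(deep, ctx)
    rel = {}
    for attr in SCALAR_ATTRIBUTES:
        ms, md = tbl_s[attr].mean(), tbl_d[attr].mean()
        rel[attr] = abs(ms - md) / abs(md)
    worst = max(rel, key=rel.get)

    fracs = []
    for k in range(min(4, n_deep)):
        ps = scab_profile(shallow[f"s{k}"], ctx.cpg)
        pdp = scab_profile(deep[f"d{k}"], ctx.cpg)
        sd = scab_sampling_sd(ps, pdp, ctx.cpg)
        ok = np.isfinite(ps.values) & np.isfinite(pdp.values)
        within = np.abs(ps.values[ok] - pdp.values[ok]) < 3 * sd[ok]
        fracs.append(within.mean())
    return {
        "depth_max_rel_diff": float(rel[worst]),
        "depth_worst_attribute": worst,
        "depth_rel_diff": {k: float(v) for k, v in rel.items()},
        "scab_frac_within_3sd": float(np.mean(fracs)),
    }


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------


def structural_invariants(seed: int = 0) -> dict:
    """Exact identities: distance fractions sum to one, differential-map
    antisymmetry, interaction residual identity, seeded reproducibility."""
    from .differential import differential_map
    from .locality import distance_profile
    from .screen import interaction

    spec = default_spec(chrom_lengths=(30_000_000, 30_000_000))
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(rng.integers(2**31)) for _ in range(3))

    cs = simulate_contacts(spec, 100_000, s1, "a")
    prof = distance_profile(cs)
    sum_err = abs(float(prof.fractions.sum() + prof.trans_fraction) - 1.0)

    csb = simulate_contacts(spec, 80_000, s2, "b")
    bins = spec.genome_bins(1_000_000)
    ma, mb = bin_contacts(cs, bins), bin_contacts(csb, bins)
    dm = differential_map(ma, mb)
    anti_err = float(np.max(np.abs(dm + differential_map(mb, ma))))

    a, b = rng.normal(size=120), rng.normal(size=120)
    comb = rng.normal(size=120)
    res = interaction(a, b, comb)
    resid_err = float(np.max(np.abs((comb - (a + b)) - res["residual"])))

    cs_rerun = simulate_contacts(spec, 100_000, s1, "a")
    identical = bool(
        np.array_equal(cs.c1, cs_rerun.c1) and np.array_equal(cs.p1, cs_rerun.p1)
        and np.array_equal(cs.c2, cs_rerun.c2) and np.array_equal(cs.p2, cs_rerun.p2)
    )
    return {
        "distance_fraction_sum_err": sum_err,
        "diffmap_antisymmetry_err": anti_err,
        "interaction_residual_err": resid_err,
        "seeded_rerun_identical": identical,
    }


# ---------------------------------------------------------------------------
# mode separation
# ---------------------------------------------------------------------------


def make_mode_deltas() -> tuple:
    """Three planted restructuring modes: scA/B shifts on disjoint locus
    sets, two magnitudes per mode (six conditions)."""
    locus_sets = (tuple(range(5, 25)), tuple(range(45, 65)), tuple(range(85, 105)))
    deltas, truth = [], []
    for mode, loci in enumerate(locus_sets):
        sign = -1.0 if mode == 2 else 1.0
        for j, mag in enumerate((0.003, 0.005)):
            deltas.append(
                PerturbationDelta(
                    shift_bins=loci, shift_value=sign * mag,
                    name=f"mode{mode + 1}_{'lo' if j == 0 else 'hi'}",
                )
            )
            truth.append(mode)
    return deltas, np.asarray(truth)


def mode_separation(
    n_seeds: int = 10,
    depth: int = 200_000,
    n_replicates: int = 2,
    seed: int = 0,
) -> dict:
    """Rand index of hierarchical clustering against planted modes."""
    from sklearn.metrics import rand_score

    from .screen import build_signatures, embed_and_cluster

    deltas, truth = make_mode_deltas()
    spec = default_spec()
    cpg = spec.make_cpg_track(0)
    scores = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        fixture_seed = int(child.generate_state(1)[0] % 2**31)
        sheet, sets, _ = make_screen_fixture(
            len(deltas), n_replicates, depth, fixture_seed,
            deltas=deltas, base_spec=spec,
        )
        profiles = pd.DataFrame(
            {sid: scab_profile(cs, cpg).values for sid, cs in sets.items()}
        ).T
        sig = build_signatures(profiles, sheet)
        centroids = sig.centroids.drop(index="vehicle")
        emb = embed_and_cluster(
            centroids, n_clusters=3, seed=fixture_seed, run_umap=False
        )
        order = {name: i for i, name in enumerate(centroids.index)}
        got = np.empty(len(truth), dtype=int)
        for k, delta in enumerate(deltas):
            got[k] = emb.labels[order[delta.name]]
        scores.append(rand_score(truth, got))
    return {
        "mode_rand_index_mean": float(np.mean(scores)),
        "mode_rand_index_min": float(np.min(scores)),
    }
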