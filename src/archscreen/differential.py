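"""Differential statistics against vehicle controls.

All group comparisons use the classical two-sided, equal-variance
(pooled) two-sample t-test, with Benjamini-Hochberg step-up correction
across an explicitly declared family: across loci within one contrast for
per-locus scA/B volcanoes, or across condition x attribute pairs within
one screen for attribute summaries. Significance tiers at adjusted
p < 0.05 / 0.01 / 0.001 mirror the */**/*** convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contacts import ContactSet
from .matrix import BinnedMatrix

__all__ = [
    "ttest_equal_var",
    "bh_adjust",
    "differential_attributes",
    "screen_differential",
    "differential_scab",
    "differential_map",
    "pseudobulk_contacts",
    "pseudobulk_scab",
]

DEFAULT_PSEUDOCOUNT_CPM = 0.5


def ttest_equal_var(x, y):
    """Two-sample pooled-variance t-test, two-sided.

    Returns ``(t, df, p)`` with ``df = nx + ny - 2``. With zero pooled
    variance: p = 1 if the means are equal, else (t, p) = (+/-inf, 0) as a
    degenerate flag.
    """
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), df, float(p)


def _ttest_rows(x: np.ndarray, y: np.ndarray):
    """Vectorized pooled t-test across rows of two (n, loci) matrices."""
    from scipy.stats import t as t_dist

    nx, ny = x.shape[0], y.shape[0]
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(axis=0, ddof=1) + (ny - 1) * y.var(axis=0, ddof=1)) / df
    diff = x.mean(axis=0) - y.mean(axis=0)
    denom = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    p = 2.0 * t_dist.sf(np.abs(t), df)
    zero = sp2 == 0
    t[zero & (diff == 0)] = 0.0
    p[zero & (diff == 0)] = 1.0
    p[zero & (diff != 0)] = 0.0
    return t, df, p, diff


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj(i) = min_{j: p(j) >= p(i)} m * p(j) / rank(j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_attributes(
    tbl: pd.DataFrame,
    condition: str,
    vehicle: str = "vehicle",
    attributes=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-attribute DiffResults of one condition against vehicle.

    ``tbl`` is an attribute table with a ``condition`` column; samples
    failing QC are excluded. Log2 ratios are reported where both group
    means are positive. BH adjustment here spans this condition's
    attributes; use :func:`screen_differential` for screen-wide families.
    """
    from .attributes import SCALAR_ATTRIBUTES

    attributes = list(attributes or SCALAR_ATTRIBUTES)
    if vehicle not in set(tbl["condition"]):
        raise ValueError(f"vehicle condition {vehicle!r} missing from table")
    qc = tbl["qc_pass"] if "qc_pass" in tbl else pd.Series(True, index=tbl.index)
    trt = tbl[(tbl["condition"] == condition) & qc]
    veh = tbl[(tbl["condition"] == vehicle) & qc]
    rows = []
    for attr in attributes:
        x = trt[attr].to_numpy(float)
        y = veh[attr].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        t, df, p = ttest_equal_var(x, y)
        mx, my = x.mean(), y.mean()
        rows.append(
            {
                "unit": attr, "condition": condition,
                "effect": mx - my,
                "log2fc": np.log2(mx / my) if mx > 0 and my > 0 else np.nan,
                "t": t, "df": df, "p": p,
                "n_treated": x.size, "n_vehicle": y.size,
            }
        )
    res = pd.DataFrame(rows)
    if adjust:
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        res["stars"] = significance_stars(res["p_adj"])
    return res


def screen_differential(
    tbl: pd.DataFrame, vehicle: str = "vehicle", attributes=None
) -> pd.DataFrame:
    """All conditions against vehicle, BH across condition x attribute."""
    conditions = [c for c in tbl["condition"].unique() if c != vehicle]
    parts = [
        differential_attributes(tbl, cond, vehicle, attributes, adjust=False)
        for cond in conditions
    ]
    res = pd.concat(parts, ignore_index=True)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["stars"] = significance_stars(res["p_adj"])
    return res


def significance_stars(p_adj) -> list:
    return [
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        for p in np.asarray(p_adj, dtype=float)
    ]


def differential_scab(
    profiles: pd.DataFrame | np.ndarray,
    treated_ids,
    vehicle_ids,
) -> pd.DataFrame:
    """Per-locus differential scA/B (volcano table), BH across loci.

    ``profiles`` is a sample x locus matrix; loci masked (NaN) in any
    replicate of either group are dropped listwise.
    """
    if isinstance(profiles, pd.DataFrame):
        x = profiles.loc[list(treated_ids)].to_numpy(float)
        y = profiles.loc[list(vehicle_ids)].to_numpy(float)
        loci = np.asarray(profiles.columns)
    else:
        profiles = np.asarray(profiles, dtype=float)
        x = profiles[np.asarray(treated_ids)]
        y = profiles[np.asarray(vehicle_ids)]
        loci = np.arange(profiles.shape[1])
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("each group needs at least 2 replicates")
    shared = np.isfinite(x).all(axis=0) & np.isfinite(y).all(axis=0)
    if not shared.any():
        raise ValueError("no shared unmasked loci between the groups")
    t, df, p, diff = _ttest_rows(x[:, shared], y[:, shared])
    res = pd.DataFrame(
        {
            "locus": loci[shared], "effect": diff, "t": t, "df": df, "p": p,
            "p_adj": bh_adjust(p),
            "n_treated": x.shape[0], "n_vehicle": y.shape[0],
        }
    )
    res["neg_log10_p_adj"] = -np.log10(np.maximum(res["p_adj"], 1e-300))
    return res


def differential_map(
    ma: BinnedMatrix, mb: BinnedMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_CPM,
) -> np.ndarray:
    """log2 ratio of CPM-normalized maps (A over B) with pseudocount.

    Exactly antisymmetric under swapping the groups. Intended for coarse
    (1-2.5 Mb) bins where the dense genome-wide matrix is small.
    """
    if not ma.bins.same_assembly(mb.bins) or ma.bins.binsize != mb.bins.binsize:
        raise ValueError("matrices must share bins")
    from .matrix import cpm_dense

    # difference of logs (not log of ratio) keeps the swap antisymmetry exact
    return np.log2(cpm_dense(ma) + pseudocount) - np.log2(cpm_dense(mb) + pseudocount)


def write_diffmap_triplets(dm: np.ndarray, path, threshold: float = 0.0):
    """Write a differential map as (bin1, bin2, log2fc) triplet text,
    keeping the upper triangle with |log2fc| > threshold."""
    i, j = np.triu_indices(dm.shape[0])
    keep = np.abs(dm[i, j]) > threshold
    pd.DataFrame(
        {"bin1": i[keep], "bin2": j[keep], "log2fc": dm[i, j][keep]}
    ).to_csv(path, sep="\t", index=False)


def pseudobulk_contacts(cells: list, unit_labels) -> dict:
    """Union of per-cell contacts for each replicate unit (e.g. animal).

    The replicate unit — not the cell — is the unit of downstream testing,
    avoiding pseudo-replication in single-cell comparisons.
    """
    unit_labels = list(unit_labels)
    if len(unit_labels) != len(cells):
        raise ValueError("one unit label per cell required")
    out: dict = {}
    for unit in dict.fromkeys(unit_labels):
        members = [c for c, u in zip(cells, unit_labels) if u == unit]
        if not members:
            raise ValueError(f"empty pseudobulk unit {unit!r}")
        merged = members[0].concat(*members[1:]) if len(members) > 1 else members[0]
        merged.sample_id = str(unit)
        out[unit] = merged
    return out


def pseudobulk_scab(profiles: list, unit_labels) -> dict:
    """Support-weighted mean of per-cell scA/B profiles per replicate unit."""
    unit_labels = list(unit_labels)
    if len(unit_labels) != len(profiles):
        raise ValueError("one unit label per cell required")
    out = {}
    for unit in dict.fromkeys(unit_labels):
        members = [p for p, u in zip(profiles, unit_labels) if u == unit]
        if not members:
            raise ValueError(f"empty pseudobulk unit {unit!r}")
        wsum = np.zeros_like(members[0].values)
        ssum = np.zeros_like(members[0].support)
        for p in members:
            ok = np.isfinite(p.values)
            wsum[ok] += p.values[ok] * p.support[ok]
            ssum[ok] += p.support[ok]
        vals = np.full_like(wsum, np.nan)
        good = ssum > 0
        vals[good] = wsum[good] / ssum[good]
        from dataclasses import replace

        out[unit] = replace(
            members[0], values=vals, support=ssum, sample_id=str(unit)
        )
    return out
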