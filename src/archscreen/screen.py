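"""Screen-level synthesis of perturbation signatures.

Treatment signatures are per-condition scA/B change vectors against the
matched vehicle. Conditions are embedded (PCA, then UMAP on top PCs) and
clustered hierarchically with average linkage on correlation distance —
correlation distance groups conditions by the *direction* of genome
restructuring regardless of magnitude. Loci are clustered by k-means on
standardized change patterns. Drug-drug interactions are decomposed
against the additive expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact, pearsonr

__all__ = [
    "TreatmentSignatures",
    "Embedding",
    "build_signatures",
    "embed_and_cluster",
    "cluster_loci",
    "dose_response",
    "interaction",
    "subtype_cells",
    "cross_context_correlation",
]


@dataclass
class TreatmentSignatures:
    """Per-condition scA/B deltas vs the matched vehicle.

    ``centroids``: condition x locus matrix of replicate-mean deltas;
    ``replicates``: sample x locus matrix of per-replicate deltas. Loci
    masked in any sample are excluded listwise from both.
    """

    centroids: pd.DataFrame
    replicates: pd.DataFrame
    replicate_condition: pd.Series  # sample id -> condition
    n_replicates: pd.Series         # condition -> replicate count


@dataclass
class Embedding:
    pca: np.ndarray                # n x n_pcs
    explained_variance_ratio: np.ndarray
    umap: np.ndarray | None        # n x 2
    labels: np.ndarray             # cluster assignment
    index: np.ndarray              # row names
    linkage: np.ndarray | None = None
    seed: int = 0


def build_signatures(
    profiles: pd.DataFrame, sheet: pd.DataFrame, vehicle: str = "vehicle"
) -> TreatmentSignatures:
    """Delta scA/B matrices (replicate-level and condition centroids)."""
    meta = sheet.set_index("sample_id").loc[profiles.index]
    if vehicle not in set(meta["condition"]):
        raise ValueError(f"no matched vehicle condition {vehicle!r}")
    shared = profiles.notna().all(axis=0)
    prof = profiles.loc[:, shared]
    veh_mean = prof[meta["condition"] == vehicle].mean(axis=0)
    deltas = prof.sub(veh_mean, axis=1)
    centroids = deltas.groupby(meta["condition"]).mean()
    counts = deltas.groupby(meta["condition"]).size()
    return TreatmentSignatures(
        centroids=centroids,
        replicates=deltas,
        replicate_condition=meta["condition"],
        n_replicates=counts,
    )


def embed_and_cluster(
    signatures: TreatmentSignatures | pd.DataFrame,
    n_clusters: int = 5,
    n_pcs: int = 20,
    seed: int = 0,
    run_umap: bool = True,
    umap_neighbors: int = 15,
    umap_min_dist: float = 0.3,
) -> Embedding:
    """PCA + UMAP embedding and hierarchical clustering of condition
    centroids (average linkage, correlation distance)."""
    from sklearn.decomposition import PCA

    mat = (
        signatures.centroids
        if isinstance(signatures, TreatmentSignatures)
        else signatures
    )
    x = mat.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 conditions to embed")
    if np.allclose(x.std(axis=0), 0):
        raise ValueError("constant signature matrix")
    n_pcs = int(min(n_pcs, x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(x)

    coords = None
    if run_umap:
        import warnings

        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=min(umap_neighbors, x.shape[0] - 1),
                min_dist=umap_min_dist,
                random_state=seed,
            )
            coords = reducer.fit_transform(pcs)

    dist = pdist(x, metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard fp noise for identical rows
    link = average(dist)
    labels = fcluster(link, t=min(n_clusters, x.shape[0]), criterion="maxclust")
    return Embedding(
        pca=pcs,
        explained_variance_ratio=pca.explained_variance_ratio_,
        umap=coords,
        labels=labels,
        index=np.asarray(mat.index),
        linkage=link,
        seed=seed,
    )


def linkage_to_newick(link: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    leaf_names = list(leaf_names)
    root = to_tree(link)

    def render(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        inner = ",".join(render(ch, node.dist) for ch in (node.left, node.right))
        return f"({inner}):{length:g}"

    return render(root, root.dist) + ";"


def cluster_loci(
    delta_matrix: pd.DataFrame | np.ndarray, k: int, seed: int = 0
):
    """k-means over loci (columns = contrasts/timepoints, rows = loci).

    Rows are standardized so clusters capture the *pattern* of change.
    Returns ``(labels, cluster_means)`` where cluster means are on the
    original scale. Constant rows are assigned by their unstandardized
    values. Restarts 20 times, keeping the lowest inertia.
    """
    from sklearn.cluster import KMeans

    mat = (
        delta_matrix.to_numpy(float)
        if isinstance(delta_matrix, pd.DataFrame)
        else np.asarray(delta_matrix, dtype=float)
    )
    if k < 1 or k > mat.shape[0]:
        raise ValueError("k must lie in [1, n_loci]")
    sd = mat.std(axis=1, keepdims=True)
    std = (mat - mat.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(std)
    means = np.vstack([mat[labels == i].mean(axis=0) for i in range(k)])
    return labels, means


def dose_response(
    tbl: pd.DataFrame,
    signatures: TreatmentSignatures,
    compound: str,
    attributes=None,
    vehicle: str = "vehicle",
) -> pd.DataFrame:
    """Per-dose attribute changes (mean +/- s.e.m.) and signature magnitude.

    Requires at least 2 nonzero doses plus vehicle (dose 0 anchor). The
    returned table flags attributes whose mean change switches sign along
    the dose grid.
    """
    from .attributes import SCALAR_ATTRIBUTES

    attributes = list(attributes or SCALAR_ATTRIBUTES)
    sub = tbl[(tbl["compound"] == compound) | (tbl["condition"] == vehicle)]
    doses = sorted(d for d in sub.loc[sub["condition"] != vehicle, "dose"].unique())
    if len(doses) < 2:
        raise ValueError("dose-response needs at least 2 doses plus vehicle")
    veh = sub[sub["condition"] == vehicle]
    rows = []
    for dose in doses:
        grp = sub[(sub["condition"] != vehicle) & (sub["dose"] == dose)]
        conds = grp["condition"].unique()
        delta_norm = np.nan
        if len(conds) == 1 and conds[0] in signatures.centroids.index:
            delta_norm = float(
                np.linalg.norm(signatures.centroids.loc[conds[0]].to_numpy())
            )
        for attr in attributes:
            x = grp[attr].to_numpy(float)
            y = veh[attr].to_numpy(float)
            change = x.mean() - y.mean()
            sem = np.sqrt(
                x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
            ) if x.size > 1 and y.size > 1 else np.nan
            rows.append(
                {
                    "compound": compound, "dose": dose, "attribute": attr,
                    "change": change, "sem": sem, "n": x.size,
                    "signature_norm": delta_norm,
                }
            )
    res = pd.DataFrame(rows)
    flags = (
        res.pivot(index="dose", columns="attribute", values="change")
        .apply(lambda col: np.any(np.sign(col[col != 0]).diff().abs() > 0))
    )
    res["sign_switch"] = res["attribute"].map(flags)
    return res


def interaction(
    delta_a: np.ndarray,
    delta_b: np.ndarray,
    delta_combined: np.ndarray,
    pc_axes: np.ndarray | None = None,
    potentiation_margin: float = 1.2,
    emergence_cosine: float = 0.5,
) -> dict:
    """Decompose a combined perturbation against the additive expectation.

    residual = combined - (A + B), exactly. Labels are descriptive, not
    significance claims: potentiation (combined larger than additive and
    aligned with it), antagonism (combined smaller than either single
    effect), emergence (residual projecting strongly on a supplied
    principal axis).
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    comb = np.asarray(delta_combined, dtype=float)
    if not (a.shape == b.shape == comb.shape):
        raise ValueError("signature shapes differ")
    additive = a + b
    residual = comb - additive
    norm = np.linalg.norm

    def cosine(u, v):
        nu, nv = norm(u), norm(v)
        return float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0

    labels = []
    if norm(residual) == 0:
        labels.append("additive")
    else:
        if (
            norm(comb) > potentiation_margin * norm(additive)
            and cosine(comb, additive) > 0.5
        ):
            labels.append("potentiation")
        if norm(comb) < max(norm(a), norm(b)):
            labels.append("antagonism")
    result = {
        "residual": residual,
        "residual_norm": float(norm(residual)),
        "norm_a": float(norm(a)),
        "norm_b": float(norm(b)),
        "norm_combined": float(norm(comb)),
        "norm_additive": float(norm(additive)),
        "cosine_combined_additive": cosine(comb, additive),
        "labels": labels,
    }
    if pc_axes is not None:
        axes = np.atleast_2d(np.asarray(pc_axes, dtype=float))
        proj = axes @ residual
        result["residual_pc_projection"] = proj
        cosines = np.array([cosine(residual, ax) for ax in axes])
        result["residual_pc_cosine"] = cosines
        if np.any(np.abs(cosines) > emergence_cosine):
            labels.append("emergence")
    return result


def subtype_cells(
    cell_profiles: pd.DataFrame,
    seed: int = 0,
    n_subtypes: int = 2,
    n_pcs: int = 20,
    treatment: pd.Series | None = None,
    run_umap: bool = True,
):
    """Structural subtyping of single cells from their scA/B profiles.

    k-means (default 2-way) on top PCs; UMAP for display. When a per-cell
    ``treatment`` series is given, a Fisher exact test asks whether subtype
    abundance shifts with treatment. Labels are canonicalized so subtype 0
    is the larger group. Returns ``(Embedding, abundance_table, fisher_p)``.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if cell_profiles.shape[0] < 20:
        raise ValueError("need at least 20 cells for subtyping")
    shared = cell_profiles.notna().all(axis=0)
    x = cell_profiles.loc[:, shared].to_numpy(float)
    n_pcs = int(min(n_pcs, x.shape[0] - 1, x.shape[1]))
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(x)
    km = KMeans(n_clusters=n_subtypes, n_init=20, random_state=seed)
    labels = km.fit_predict(pcs)
    order = np.argsort(-np.bincount(labels, minlength=n_subtypes), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(n_subtypes)
    labels = remap[labels]

    coords = None
    if run_umap:
        import warnings

        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = umap.UMAP(
                n_neighbors=min(15, x.shape[0] - 1), min_dist=0.3,
                random_state=seed,
            ).fit_transform(pcs)

    emb = Embedding(
        pca=pcs,
        explained_variance_ratio=pca.explained_variance_ratio_,
        umap=coords,
        labels=labels,
        index=np.asarray(cell_profiles.index),
        seed=seed,
    )
    abundance, fisher_p = None, None
    if treatment is not None:
        treatment = treatment.loc[cell_profiles.index]
        abundance = pd.crosstab(treatment, pd.Series(labels, index=treatment.index))
        if abundance.shape == (2, 2):
            _, fisher_p = fisher_exact(abundance.to_numpy())
    return emb, abundance, fisher_p


def cross_context_correlation(delta_a, delta_b, min_loci: int = 10):
    """Pearson correlation of two per-locus change vectors over shared
    unmasked loci. Returns ``(r, n_loci, p)``."""
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share loci")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_loci:
        raise ValueError(f"fewer than {min_loci} shared unmasked loci")
    r, p = pearsonr(a[ok], b[ok])
    return float(r), int(ok.sum()), float(p)
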