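"""Pipeline orchestration: sample sheet to screen report bundle."""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .attributes import AttributeContext, attribute_table
from .config import RunConfig
from .contacts import read_pairs
from .differential import screen_differential
from .genome import load_cpg_track, read_chrom_sizes
from .locality import read_bedpe
from .screen import build_signatures, embed_and_cluster

log = logging.getLogger("archscreen")


def load_samples(sheet: pd.DataFrame, bins) -> dict:
    """Read every sample's pairs file; missing files abort with the name."""
    sets = {}
    for _, row in sheet.iterrows():
        if not os.path.exists(row["path"]):
            raise FileNotFoundError(
                f"sample {row['sample_id']}: missing file {row['path']}"
            )
        sets[row["sample_id"]] = read_pairs(
            row["path"], bins, sample_id=row["sample_id"]
        )
    return sets


def run_screen(
    sheet: pd.DataFrame,
    chrom_sizes_path,
    cpg_path,
    config: RunConfig,
    loops_path=None,
    vehicle: str = "vehicle",
) -> dict:
    """Full screen analysis: attributes -> differential -> signatures ->
    embedding/clustering. Writes TSV/CSV/JSON outputs under config.outdir
    and returns the in-memory bundle. Deterministic given config.seed."""
    if "sample_id" in sheet and sheet["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    bins1mb = read_chrom_sizes(chrom_sizes_path, config.scab_binsize)
    cpg = load_cpg_track(cpg_path, bins1mb)
    loops = read_bedpe(loops_path, bins1mb) if loops_path else None

    sets = load_samples(sheet, bins1mb)
    ctx = AttributeContext(
        cpg=cpg,
        loops=loops,
        scab_binsize=config.scab_binsize,
        insulation_binsize=config.insulation_binsize,
        insulation_window=config.insulation_window,
        apa_binsize=config.apa_binsize,
        apa_half_window=config.apa_half_window,
    )
    # reference boundaries from the pooled vehicle, held fixed screen-wide
    veh_ids = sheet.loc[sheet["is_vehicle"].astype(bool), "sample_id"]
    if len(veh_ids) == 0:
        raise ValueError("sample sheet contains no vehicle samples")
    pooled = sets[veh_ids.iloc[0]].concat(*(sets[s] for s in veh_ids.iloc[1:]))
    ctx.set_reference_from(pooled, config.boundary_threshold)

    tbl, scab = attribute_table(
        sets, ctx, sheet=sheet,
        equalize_depth=config.equalize_depth, seed=config.seed,
    )
    n_qc_fail = int((~tbl["qc_pass"]).sum())
    if n_qc_fail:
        log.warning("%d samples quarantined by QC", n_qc_fail)

    diff = screen_differential(tbl, vehicle=vehicle)
    sig = build_signatures(scab, sheet, vehicle=vehicle)
    emb = None
    if sig.centroids.shape[0] >= 3:
        emb = embed_and_cluster(
            sig, n_clusters=config.n_modes, seed=config.seed,
            run_umap=sig.centroids.shape[0] > 4,
        )

    os.makedirs(config.outdir, exist_ok=True)
    tbl.to_csv(os.path.join(config.outdir, "attributes.tsv"), sep="\t")
    scab.to_csv(os.path.join(config.outdir, "scab_profiles.tsv"), sep="\t")
    diff.to_csv(os.path.join(config.outdir, "differential.tsv"), sep="\t", index=False)
    sig.centroids.to_csv(os.path.join(config.outdir, "signatures.tsv"), sep="\t")
    if emb is not None:
        pd.DataFrame(
            {
                "condition": emb.index,
                "cluster": emb.labels,
                "pc1": emb.pca[:, 0],
                "pc2": emb.pca[:, 1] if emb.pca.shape[1] > 1 else np.nan,
            }
        ).to_csv(os.path.join(config.outdir, "clusters.tsv"), sep="\t", index=False)
    with open(os.path.join(config.outdir, "run_config.json"), "wt") as fh:
        fh.write(config.to_json())
    log.info("run complete; config hash %s", config.config_hash())
    return {
        "attributes": tbl,
        "scab": scab,
        "differential": diff,
        "signatures": sig,
        "embedding": emb,
    }
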