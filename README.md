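# archscreen

Whole-genome architectural screening: from chromosome-conformation contact
pairs to a seven-attribute quantification of 3D genome organization,
differential statistics against vehicle controls, and clustering of
perturbation signatures into modes of genome restructuring.

High-throughput Hi-C–style screens profile hundreds of chemical or
biological perturbations across cell types, each sample yielding a
genome-wide contact map at modest depth. The analytical question is how to
reduce each map to a small set of depth-robust quantities that span the
organizational hierarchy — chromosome territories down to loops — and to
decide, replicate-against-vehicle, which perturbations remodel which
level. `archscreen` implements that pipeline for analysts working with
pairs-format contact data (bulk wells or single cells), together with a
synthetic contact-map generator that makes every stage testable by
parameter recovery.

## The seven attributes

For each sample:

| attribute | definition |
|---|---|
| intermingling | fraction of interchromosomal contacts |
| contact distances | cis fractions in short (<2 Mb), long (2–10 Mb), very-long (>10 Mb) bands |
| AA, BB, AB | mean cis O/E among top/bottom-20% bins ranked by scA/B |
| COMP | log2(AA·BB/AB²), overall compartmentalization strength |
| A–B difference | log2(AA) − log2(BB) |
| scA/B profile | per-1-Mb-bin contact-weighted mean CpG density of partners (cis ≥ 3 Mb + trans) |
| boundary strength | mean insulation prominence at fixed reference boundaries (25-kb bins, 250-kb diamond) |
| P2LL | APA center pixel over lower-left corner box, on an input loop list |

Differences against vehicle use two-sided equal-variance t-tests with
Benjamini–Hochberg correction across an explicit family (loci within a
contrast, or condition × attribute within a screen). Per-condition Δ scA/B
signatures are clustered hierarchically (average linkage, correlation
distance) and embedded with PCA/UMAP; single cells are subtyped from their
scA/B profiles with pseudobulk (per-animal) testing.

See `docs/methods.md` for definitions, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic screen:

```
python analysis/01_simulate_screen.py   # vehicle + 4 planted perturbations
python analysis/02_attributes.py        # 7 attributes per sample
python analysis/03_differential.py      # t-tests + BH vs vehicle
python analysis/04_modes.py             # signature clustering
python analysis/05_dose_interaction.py  # dose curves, drug-drug interaction
```

`03_differential.py` prints, for the fixture written by step 01:

```
planted effect recovery (screen-wide BH):
  trans_up        intermingling      effect +0.0503 p_adj 2.25e-10 *** -> detected
  comp_up         comp_strength      effect +2.1578 p_adj 2.94e-08 *** -> detected
  tad_strengthen  boundary_strength  effect +2.3782 p_adj 6.02e-09 *** -> detected
  loop_up         p2ll               effect +1.9056 p_adj 3.62e-03 **  -> detected
```

Each line is one planted perturbation: doubling the trans-contact fraction
raises intermingling by +0.050 (from 0.05 to 0.10); multiplying the
compartment contrast by 1.5 raises COMP by +2.2 log2 units; deepening
boundary depletion from 1.0 to 0.2 raises boundary strength by +2.4; and
tripling loop enrichment raises P2LL by +1.9 — every effect carrying the
planted sign at adjusted p < 0.05. `04_modes.py` recovers three planted
restructuring modes from Δ scA/B signatures with Rand index 1.000, and
`05_dose_interaction.py` charts a monotone compartment-strength
dose–response (+0.13 → +0.60 → +2.07 across three doses) and labels a
super-additive combination as potentiation.

A `archscreen` command-line interface wraps the same pipeline
(`simulate`, `attributes`, `screen`, `report`) for pairs files on disk.

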