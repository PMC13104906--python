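# Methods

## Overview

`archscreen` quantifies how perturbations remodel 3D genome organization
from chromosome-conformation contact data. Each sample (a bulk well or a
single cell) is reduced to seven architectural attributes spanning coarse
to fine scales, attributes are compared against vehicle controls with
classical two-sample statistics, and per-condition scA/B change signatures
are embedded and clustered to reveal shared modes of restructuring. A
bundled generator produces contact sets with planted architecture so every
stage is validated by parameter recovery.

## Input model and coordinates

Contacts are read from pairs-like text (read id, chrom1, pos1, chrom2,
pos2; `#` headers; gzip transparent). Positions are 1-based base pairs;
bins are 0-based half-open. Duplicates are exact 4-tuple matches — no fuzzy
window, since any window choice would be arbitrary and harder to reproduce.
Library complexity is estimated from the saturation curve
`u = C (1 - exp(-n/C))` (the expected number of distinct molecules seen
after `n` draws from `C`), solved by bracketed root finding; zero observed
duplication returns an unbounded sentinel.

## The seven attributes

1. **Chromosome intermingling** — the fraction of interchromosomal
   contacts.
2. **Contact-distance distribution** — per-band fractions of contacts with
   summary bands short (< 2 Mb), long (2–10 Mb), very long (> 10 Mb), plus
   a 20-bin log-spaced curve from 10 kb up. Cis band fractions and the
   trans fraction always sum to 1.
3. **Compartmentalization strength** — bins at 1 Mb are ranked by scA/B;
   AA is the mean cis observed/expected among top-20% (A) bin pairs, BB
   among bottom-20% pairs, AB across, diagonal excluded. The overall
   strength is `COMP = log2(AA·BB/AB²)`.
4. **A–B difference** — `D = log2(AA) − log2(BB)`, positive when A–A
   interactions are the stronger side.
5. **scA/B profile** — per-1-Mb-bin spatial CpG compartment value: the
   contact-weighted mean CpG density of the loci a bin touches, using cis
   contacts beyond 3 Mb plus all trans contacts. The near-diagonal
   exclusion keeps the value a property of the spatial neighborhood rather
   than the linear one; the radius follows the common contact-frequency
   surrogate of the original single-cell definition. Bins with fewer than
   10 supporting contacts are masked.
6. **Domain-boundary strength** — insulation scores (Crane-style sliding
   diamond, 25-kb bins, 250-kb window, log2 over the chromosome-wide
   median) are evaluated at *fixed reference boundaries*; strength is the
   mean of (flanking reference maxima − boundary score). Boundaries and
   their flank positions are called once — on a pooled vehicle, or from
   supplied positions — and held fixed across samples, so differences
   reflect insulation depth at the same loci, never re-calling
   stochasticity. Boundary calls are local minima below −0.2.
7. **Loop strength (P2LL)** — aggregate peak analysis over an input loop
   list (BEDPE) at 50-kb bins: the center pixel of the mean O/E stack over
   the mean of the lower-left corner box (`half_window // 2` square,
   half-window 5). Loops nearer than the stack size to the diagonal or
   edge are skipped.

All attributes are ratios or fractions, which removes first-order depth
dependence; comparisons can additionally downsample every sample to the
minimum per-sample count (`equalize_depth`). Samples with fewer than
10,000 contacts are flagged and excluded from tests by default.

### Observed/expected

Expected counts are per-chromosome means at each diagonal offset, computed
on the same matrix (scale invariant). For the saddle strengths the
attribute pipeline pools offsets into three geometric bands per octave
before averaging: the smoothed expected removes most of the shallow-depth
Jensen bias of O/E ratios (measured COMP shifts of ~4% between 2×10^5 and
10^6 contacts drop to ~1%). The exact per-offset expected remains the
default of `observed_expected` and is what the eigenvector uses. No matrix
balancing is applied by default; the ratio definitions above are the
depth-robustness mechanism.

### Compartment eigenvector

Per chromosome, the leading eigenvector of the Pearson correlation matrix
of the cis O/E map, sign-oriented so its correlation with CpG density is
non-negative. Offsets with no counts chromosome-wide give 0/0 ratios and
enter the correlation as the neutral value 1. Chromosomes with fewer than
10 usable bins are masked with a warning. Genome-wide trans eigenvectors
and >2-state subcompartments are out of scope.

## Differential framework

Group comparisons use the two-sided pooled-variance t-test
(`df = nx + ny − 2`); zero pooled variance returns p = 1 for equal means
and a degenerate infinite-t flag otherwise. Multiple testing uses
Benjamini–Hochberg step-up within an explicitly declared family:

* per-locus scA/B volcano: across loci within one contrast;
* screen summary: across condition × attribute pairs within one screen.

Both scopes are explicit arguments, since reported adjusted values are
meaningless without their family. Significance tiers mirror the
`*/**/***` convention at adjusted p < 0.05/0.01/0.001. Differential
contact maps are `log2(CPM_A + pc) − log2(CPM_B + pc)` with a 0.5-CPM
pseudocount (logged in output metadata); the difference-of-logs form keeps
group-swap antisymmetry exact in floating point.

For single-cell data the testing unit is the replicate unit (e.g. animal),
never the cell: contact pseudobulk is the union of cell contacts per unit,
scA/B pseudobulk the support-weighted mean. Per-cell significance claims
are refused to avoid pseudo-replication.

## Screen-level synthesis

Treatment signatures are Δ scA/B vectors against the matched vehicle
(replicate-level and condition centroids). Conditions are clustered with
average linkage on correlation distance of centroids — direction of
restructuring, not magnitude — and embedded by PCA with UMAP (15
neighbors, min_dist 0.3, top 20 PCs, fixed seed) for display. Loci are
clustered by k-means on row-standardized change patterns (20 restarts,
lowest inertia kept). Drug–drug interactions are decomposed as
`residual = combined − (A + B)`; potentiation/antagonism/emergence labels
are descriptive with configurable margins, never significance claims.
Cell subtyping is k-means (default 2-way) on top PCs of per-cell scA/B,
with a Fisher exact test for treatment-by-subtype abundance shifts.

## Synthetic data generator

Contacts are drawn from a product model by rejection sampling against a
distance-law × uniform-position proposal (no full matrix is ever built):

* cis/trans split: trans with probability `f_trans` (default 0.05),
  uniform positions reweighted by the compartment term;
* cis distance: truncated power law `P(s) ∝ s^(−α)` on [10 kb, L),
  α = 1 by default; the *count* histogram follows the power law directly;
* compartments: 1-Mb blocks carry a ground-truth compartment value in
  CpG-density units, mapped to an affinity `a ∈ [−1.5, 1.5]` around
  midpoint 0.017 (half-span 0.005); pair weight `c^(a_i·a_j)` with
  contrast c = 1.5 by default. The default layout alternates A/B in
  5-block runs on 2 × 60 Mb chromosomes — small enough for exhaustive
  oracles, large enough for stable eigenvectors;
* domains: pairs under 2 Mb that straddle a planted boundary (every
  1.2 Mb) are depleted by `d` (default 1.0, i.e. off — recovery fixtures
  perturb it);
* loops: planted 50-kb anchor pixels (spaced 1.3 Mb along the diagonal at
  1.4–1.6 Mb separations) enriched by `loop_mult` (default 1.0);
* CpG track: A bins ~ Normal(0.022, 0.003), B bins ~ Normal(0.012, 0.003),
  truncated at 0 — an arbitrary but fixed mirror of the qualitative A/B
  CpG contrast. The track is genome annotation: perturbations never touch
  it; a planted scA/B shift moves a bin's *contact affinity*, and the
  measured scA/B responds through its changed partner composition (with a
  magnitude compressed relative to the planted value — recovery tests
  therefore assert direction and detection, not unit gain);
* library complexity: reads draw molecules uniformly from `C` distinct
  molecules (exact Lander–Waterman duplication); unbounded by default.

Perturbations are multiplicative deltas on (c, f_trans, α, d, loop_mult)
plus additive ground-truth shifts at chosen loci; applying one returns a
new spec with the delta recorded for recovery tests. Screen fixtures are
byte-identical under a fixed seed (per-sample seeds spawned from one
`SeedSequence`).

What the generator does **not** emulate: polymer-physics constraints,
position-dependent coverage/mappability, translocations or CNVs, cell-type
mixtures, and realistic noise correlations between neighboring bins.
Passing recovery tests therefore demonstrates the estimators and the
statistical framework, not robustness to every artifact of real libraries.

## Validation battery and study sizes

`archscreen.validation` runs the self-checks asserted by the test suite
and reported by `scripts/acceptance.py`; sizes are chosen to keep wide
statistical margins at desk scale:

* oracle equivalence: eigenvector vs an independent dense decomposition
  (≤ 80 1-Mb bins per chromosome), insulation vs an O(n·w²) loop oracle
  (exact, since integer counts are exact in float64 sums), BH vs a naive
  step-up on 1,000 random p-vectors, t-test vs the closed form, complexity
  vs textbook bisection with saturation round-trip;
* parameter recovery: 20 fixture seeds on the default genome, depth
  5×10^5, 4 replicates per group; detection = key attribute significant
  (screen-wide BH, p_adj < 0.05) with the planted sign. Locus-shift
  recovery plants 50 of 240 loci shifted +0.004 against replicate noise
  s.d. 0.001 at the profile level (the per-locus test operates on
  profiles, so this isolates the statistics from simulator gain);
* calibration: 60 null fixtures (identity delta, 2 × 30 Mb genome, depth
  5×10^4) × 7 attributes = 420 raw p-values; plus a KS uniformity check of
  volcano p-values under label permutation;
* depth robustness: replicate-mean attributes at 2×10^5 (16 replicates)
  vs 10^6 (8 replicates) on a spec with all features active and an
  asymmetric A/B contrast (so no attribute sits at zero); per-bin scA/B
  compared over 4 sample pairs against 3 s.d. of the sampling-noise model
  `sd(CpG)/√support`, which uses the global CpG spread and is therefore
  slightly conservative;
* structural invariants: exact identities (fraction sums, differential-map
  antisymmetry, interaction residual, seeded byte-identical reruns);
* mode separation: 3 planted scA/B modes × 2 magnitudes, 10 seeds,
  hierarchical clustering scored by Rand index against truth.

## Numerical and degenerate-input choices

* Insulation diamonds are accumulated per contact with a range-add
  difference array (O(contacts), no dense matrix); with integer counts the
  result is bit-identical to naive summation, verified against both a
  dense integral-image and an explicit-loop oracle. Empty diamonds score
  −inf and may be called as (extreme) boundaries; NaN marks bins where
  the window does not fit.
* Saddle quantiles at 20%/20%; too few unmasked bins raise rather than
  return unstable estimates.
* k-means ties (identical rows) collapse to one populated cluster;
  duplicated conditions sit at correlation distance 0 and merge first.
* Downsampling, UMAP, k-means and every simulation accept explicit seeds;
  the pipeline is a pure function of (inputs, config, seeds).

## Known limitations

* scA/B planted-shift gain is compressed (direction-faithful) as noted
  above.
* P2LL is the noisiest attribute at shallow depth (its numerator is a
  single mean-stack pixel); depth comparisons use replicate means.
* The boundary-strength protocol needs a reference with visible
  boundaries; on a domain-free control the pooled-vehicle calls are noise
  minima, and ground-truth (or deep-data) positions should be supplied, as
  the bundled analysis scripts do for the synthetic screen.
* De novo loop calling is best-effort out of scope; loop lists are inputs.
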