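# Methods

## The analysis problem

`stagewise` implements the computational analysis for a staged human
ES-cell-to-neural-progenitor expression time course in which every
post-ES stage is FACS-split into a Notch-active (HES5 reporter-positive)
and Notch-inactive (HES5−) population. The default design has six ordered
stages — ES, NE (neuroepithelial), E-RG / M-RG / L-RG (early/mid/late
radial glia) and LNP (long-term neural progenitors) — with a single
unsorted ES sample and one HES5+ plus one HES5− sample per later stage,
i.e. 11 samples and a single replicate per condition. All intensities are
log2.

The pipeline is: probe-to-gene collapse → variation filter → ES-baseline
subtraction → (a) temporal-pattern classification of HES5+ trajectories
and (b) stage-specific Notch-active gene selection → marker-panel and
qPCR presentation transforms.

## Probe collapse

Multiple array probes per gene symbol are reduced to one row. The default
`max_mean_probe` keeps the single probe with the highest mean intensity
across samples, so the reported trajectory is a real measured probe rather
than an average of probes with different affinities; `mean` and
`max_per_sample` are selectable alternatives. Unmapped probes are dropped
and counted in the log, never aggregated into a placeholder gene. The
output gene count equals the number of distinct mapped symbols regardless
of method, which is what downstream gene-count bookkeeping relies on.

## Variation filter

A gene is retained iff

- max − min over **all** samples ≥ `min_range` (default 1.0 log2 units), and
- max over samples ≥ `min_level` (default 3.0 log2 units),

both inclusive, so a range of exactly 1.0 or a peak of exactly 3.0 passes.
"Change between any pair of samples" is equivalent to max − min because
some pair differs by ≥ r iff max − min ≥ r; the test suite nevertheless
keeps an exhaustive pairwise oracle and asserts set equality on random
matrices. The filter pools both populations and all stages — it runs
before any population split. It is idempotent and monotone in both
thresholds.

## Temporal-pattern classification

Trajectories are the ES-subtracted HES5+ per-stage values (baseline column
included and identically zero). Features are *unstandardized* and distances
Euclidean: the pattern threshold θ is an absolute log2 quantity and
z-scoring rows would destroy its meaning.

k-means (Lloyd, `k` default 100, `n_init` 10 restarts, `max_iter` 300,
seeded) partitions genes; centroids are recomputed as exact member means
so the centroid/membership identity holds to 1e−9. Each centroid's vector
of consecutive stage differences is tested against a grammar of trit
codes over the 5 transitions: at each position `U` requires diff ≥ θ, `D`
requires diff ≤ −θ, `F` requires |diff| < θ, `*` matches anything
(θ default 1.0, inclusive on U/D per "one or greater" semantics). A
cluster is matched to the first satisfied code in list order; its member
genes inherit the code; clusters matching no code leave their genes
unclassified. Matched clusters sharing a code form one pattern family.

The default grammar enumerates single-onset upregulation: for each
transition a sustained variant (`U` then flat) plus, wherever a later
transition remains after the drop, a transient variant (`U` immediately
followed by `D`). For the six-stage design this is exactly eight codes —
UFFFF, UDFFF, FUFFF, FUDFF, FFUFF, FFUDF, FFFUF, FFFFU — which are
pairwise mutually exclusive, so list order is immaterial for the default
set. The grammar is a plain config list: users can supply their own codes
(e.g. re-expression codes like UDUFF, or D-onset codes for ES-high
families), in which case overlap is possible and first-match-wins applies.
The published analysis this reproduces reports 26 matched clusters and
495 classified genes in one place and "7 distinct patterns" / 496 genes in
another; those internal inconsistencies are noted here and not resolved —
exact counts on the deposited data depend on the sample map and the
stochastic clustering and are reported without assertion by
`reproduce-gse65369`.

A deterministic gene-level mode (`classify_genes_directly`) applies the
same matching to each gene's own diffs, as a sensitivity check; on
noiseless data it agrees exactly with the cluster mode.

## Stage-specific Notch-active gene selection

All 11 samples' ES-subtracted values form the feature matrix for a shared
k-means (k default 100) — one cluster set serves both directions. For each
gene and post-ES stage the linear fold is 2^(Δ+ − Δ−) where Δ± are the
ES-subtracted log2 values of the two populations; because both reference
the same unsorted ES sample, the baseline cancels and the two directions
are exact reciprocals. Cluster fold profiles default to the geometric
mean (mean of log ratios), which is symmetric under direction reversal;
an arithmetic-mean option exists. A cluster is selected when its profile
**strictly exceeds 1.4** at exactly one stage and is **strictly below
1.2** at every other stage; it is assigned to its high stage. The linear
thresholds correspond to ≈0.485 and ≈0.263 log2 units. ES carries no
population split and is used only as the baseline. With single-replicate
arrays there is no per-gene statistical test to run; the dual threshold on
cluster averages is the selection rule.

## Marker and qPCR transforms

- `relative_heatmap`: per-gene rows over stages for one population,
  either divided by the row maximum (`max1`, the documented default — the
  peak stage reads exactly 1) or z-scored (population sd). Both appear in
  the figure conventions this reproduces, so both are exposed.
- ΔCT = mean(triplicate Ct of target) − mean(triplicate Ct of HPRT);
  linear relative expression is 2^−ΔCT (a ΔΔCT convenience wrapper exists
  but is not part of the main pipeline).
- Double normalization for relative-abundance pies: each gene's folds are
  divided by their sum over all (stage, population) conditions, then each
  condition column is divided by its sum over genes, so columns sum to 1.
  "Normalized to 1" is read as sum-to-1 because the outputs feed pie
  charts; the across-stages step spans both populations jointly by
  default (the wording is ambiguous; a per-population variant is a flag at
  the table-construction level by passing per-population columns).
  The transform is invariant to rescaling any single gene's raw values.
- `collapse_groups` sums member fractions (e.g. deep-layer TBR1/RELN and
  CTIP2/FEZF2 vs upper-layer CUX1/CUX2/SATB2) and by default renormalizes
  groups to fractions per condition.

## Synthetic data

The generator emulates the *structure* the analysis assumes, not any real
dataset: single replicate per condition, log2 intensities, i.i.d. Gaussian
noise (default sd 0.1 log2 units), gene baselines drawn N(6, 1.5²).
Planted gene classes:

- **pattern genes**: the HES5+ trajectory steps by ±amplitude (default 2.0,
  i.e. 2θ) at the transitions its trit code dictates; HES5− mirrors HES5+
  so pattern planting carries no population signal and composes cleanly
  with Notch planting;
- **Notch genes**: an extra log2 offset (default 1.0, fold 2.0) on one
  population at exactly one stage;
- **background genes**: flat baseline plus noise.

Planted genes' baselines are clipped at 3.5 so that, on noiseless data,
every planted gene passes the default filter by construction; background
baselines are unclipped. There is no probe-affinity, batch or gene-gene
correlation structure — a single-replicate design could not estimate such
structure anyway — so recovery results on synthetic data demonstrate the
pipeline's correctness and thresholds' semantics, not performance on real
arrays. Probe tables expand each gene to 1–3 probes with one faithful
probe and jittered lower-mean extras, making max-mean collapse an exact
inverse. Ct tables place the reference at a constant 20 cycles and targets
at 20 − log2(fold) with optional replicate noise.

One deliberate interaction: a plus-direction Notch plant with offset ≥ θ
at stage s puts a transient up-then-down bump on the HES5+ trajectory, so
on noiseless data such genes also classify under the transient pattern
code for s. The ground-truth bookkeeping in the tests accounts for this.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale problems chosen to make the
planted structure unambiguous: 300 pattern genes over three codes at
amplitude 2θ and sd 0.1 with k=12; 40 NE-specific genes among 400
background at offset 1.0 and sd 0.1 with k=100; 50 random 200×11 matrices
for the filter oracle. k-means uses seed 0 / n_init 10 defaults throughout;
`run_all` clamps k to the retained gene count so small runs stay valid.
Manifest JSON is written with sorted keys and no timestamps, making
repeated runs byte-identical. Tolerances: centroid identity 1e−9,
normalization column sums 1e−12; all threshold comparisons are exact
(inclusive for the filter and θ, strict for 1.4/1.2) rather than
tolerance-padded, because the boundary semantics are part of the method.

## Known limitations

- The printed gene counts of the published analysis (19,448 collapsed;
  6,371 filtered; 495 classified in 26 clusters) require the deposited
  accession (GSE65369), which is never downloaded; `reproduce-gse65369`
  juxtaposes computed and printed counts without asserting equality.
- The GEO reader handles the Series Matrix text dialect only, with a
  user-curated sample map; CEL processing and array normalization are out
  of scope (inputs are already-normalized log2 intensities).
- Gene-set enrichment (run in the original analysis with a commercial
  tool) and all wet-lab quantifications are out of scope.
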