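# Methods

## Scope and model

The pipeline compares two species' injury responses through a shared
ortholog anchor. Its unit of data is a genes × samples log2-scale
expression matrix per species, with samples named
`<species>_<timepoint>_<arm>_<rep>` over three timepoints (days 1, 3, 7
post-injury) and two arms (injured / control). Everything downstream is a
deterministic filter cascade plus three well-defined statistical
procedures (t-tests with BH correction, hypergeometric overrepresentation,
and a bootstrap pathway-perturbation test).

## Differential expression

Within each species × timepoint stratum, each gene is tested injured vs.
control with Welch's unequal-variance two-sided t-test; the log2
fold-change is the difference of arm means (the data are assumed already
log2-scale and normalised). The pooled-variance Student variant is
available via `equal_var=True`; Welch is the default because equal arm
variances cannot be assumed across an injury contrast. Benjamini–Hochberg
correction is applied *within* each stratum (six strata in the default
design), matching per-dataset DE tables rather than one global correction.
A gene is significant when p_adj ≤ `alpha` (default 0.05, inclusive) and
its linear fold-change is ≥ `fc_cutoff` (default 1.5, i.e. |log2 FC| ≥
log2 1.5 ≈ 0.585, inclusive).

The fold-change cutoff scale is genuinely ambiguous in practice (reports
mix "fold-change 1.5" and "log fold-change 1.5"); the default is the
linear reading, and `fc_scale="log"` switches to |log2 FC| ≥ 1.5. Both
arms with zero variance and equal means yield p = 1 by convention; fewer
than two replicates per arm is an error because the t-test is undefined.

## Consistency filter and quadrant classification

Genes are re-keyed to human symbols through a 3-column ortholog map;
unmapped genes are dropped and counted. When several source ids collapse
to one symbol, the record with the smallest p_adj per stratum is kept
(best-probe rule). A gene enters a species' *consistent set* only if it is
significant at every timepoint with the same direction each time — the
sign rule is an interpretation forced by the downstream quadrant
classification, which needs one sign per species. The cross-species
intersection of the two consistent sets is partitioned by the signs of the
per-species average log2 fold-change: group 1 axolotl-up/rat-down, group 2
up/up, group 3 down/down, group 4 axolotl-down/rat-up. After the
consistency filter the per-timepoint signs all agree, so the sign of the
average is unambiguous; a zero average would indicate an upstream filter
violation and raises. Group summaries report both exact percentages and
integer-rounded display values; empty denominators are flagged as
undefined rather than propagated as NaN.

A separate per-timepoint shared-set operation intersects the two species'
significant genes day by day *without* the consistency requirement,
optionally restricted to an annotation set (e.g. matrix genes) — the two
views answer different questions and are deliberately distinct.

## Overrepresentation

`hypergeom_upper(k, K, n, N)` accumulates the hypergeometric pmf over the
upper tail in log space (logsumexp of `logpmf`), which is exact and stable
for the small counts typical of gene-set tests; it equals one-sided
Fisher's exact p on the corresponding 2×2 table. Collections are flat GMT
sets: GO-style hierarchies must be pre-propagated upstream, and TF-target
sets arrive as precomputed lists (no promoter scanning here). The default
background is the ortholog-anchored array universe — the statistically
defensible choice when the query derives from the arrays — and external
collections are reconciled to it by intersection with warn-and-drop
accounting. BH is applied across the terms actually tested (k ≥ 1) within
a collection. TF rankings order by p_adj, then larger hit count, then
name, so ties are deterministic.

## Networks

Interaction tables are undirected weighted edge lists with association
scores in [0, 1]; subnetworks are induced on a gene class keeping edges
with scores inside [0.15, 0.999] (a deliberately broad band that retains
low-confidence text-mining-grade associations), then nodes left isolated
are removed and counted. Centralities are computed on the *unweighted*
topology: normalised betweenness (divisor (n−1)(n−2)/2), degree
centrality (degree/(n−1)), and the local clustering coefficient.
Score-weighted shortest paths would treat high association as high cost,
inverting the score semantics, so the weighted mode uses
distance = 1 − score and is off by default. Centrality is correlated with
|average log2 FC| separately per species × direction stratum; Spearman is
the default (centrality distributions are heavily right-skewed), Pearson
by flag. Zero-variance strata are flagged undefined. TF fusion takes the
union {TF} ∪ (predicted targets ∩ network) ∪ firstNeighbors(TF) with
edges induced from the class network; because the counting convention for
such fused networks varies, all three component sizes and their overlap
are reported alongside the fused node count.

## Pathway impact

Each pathway is a signed directed graph, β_ij ∈ {+1, −1} the influence of
gene j on gene i. Perturbation factors solve (I − B)·PF = ΔE with
B = β column-normalised by outdegree and ΔE the observed log2 fold-changes
of DE genes (0 otherwise); the net accumulation is tA = Σ(PF − ΔE). If
cond(I − B) > 1e10 the pathway is flagged unsolvable and skipped rather
than propagating a meaningless solve. pNDE is the hypergeometric
overrepresentation of DE genes on the pathway. pPERT reassigns the same
number of fold-changes, drawn with replacement from the observed DE pool,
to random pathway genes `n_boot` times (default 2000) and takes the
median-centered two-sided tail with add-one smoothing, so p ∈ (0, 1].
Because tA is linear in ΔE, all bootstrap systems are solved in a single
LU-factorised call, which keeps large calibration runs cheap. The
combined evidence is pG = c − c·ln c (c = pNDE·pPERT), the Fisher-product
survival function, BH-corrected across pathways; a significant pathway is
labelled activated or inhibited by the sign of tA.

## Synthetic data

The generator emulates the target study design: rat 4 injured vs. 4
control, axolotl 3 vs. 3, three timepoints, partial ortholog coverage.
Expression is simulated directly on the log2 scale with per-gene baselines
~ Normal(8, 1) (microarray-like intensity levels); injured arms add the
gene's true effect plus Normal(0, sd) residual noise. Planted genes get a
constant |log2 FC| equal to `effect_size` with the group's sign pattern in
each species, constant across timepoints; "inconsistent" genes carry a
strong effect that flips sign or goes silent at one random timepoint in
one species (so the consistency filter must remove them);
"species-specific" genes have a real effect but no ortholog anchor (so the
anchoring step must drop them); remaining genes are null. Because each
axolotl replicate represents a pool of 10 animals in the emulated design,
the axolotl residual SD defaults to sd/√10 (`pooled_axolotl_variance`,
switchable off); pooling is modelled only as variance reduction, not as an
explicit pool simulation. Defaults: 1000 genes, quadrant counts
(77, 41, 32, 132), 100 inconsistent, 100 species-specific, effect_size 2,
sd 0.3 — sizes chosen to keep a realistic mixture of signal, structured
confounders and nulls while running in seconds.

The generator also emits Barabási–Albert (preferential-attachment)
interaction tables with uniform scores in a requested band, GMT
collections of uniform random sets plus an exactly planted term, and
random signed pathways with an acyclic option (edges forward along a
random order) that guarantees solvability.

What the synthetic data does *not* model: probe-level artifacts,
background correction, batch and lab effects, correlated genes,
heavy-tailed noise, many-to-many orthology beyond an optional
many-to-one fraction, and any normalisation step. Passing tests therefore
demonstrate the correctness of the filter cascade and statistics under
idealised Gaussian conditions, not robustness to real microarray
pathologies. In particular, real axolotl arrays must be normalised and
log-transformed *before* entering the pipeline — the pipeline assumes it
and cannot detect its absence.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded once per
  generator or run; identical (design, seed) gives byte-identical outputs.
- Rank ties anywhere a ranking is emitted (top genes, enrichment, TF
  ranking, pathway tables) are broken deterministically, ultimately by
  name.
- BH validates inputs to [0, 1] and enforces step-up monotonicity; single
  values pass through unchanged.
- Thresholds are inclusive (≤ alpha, ≥ cutoff) everywhere.
- Problem sizes used in tests and in the acceptance script (e.g. 50 and
  20 simulation seeds, 200 null replicates, 500 bootstrap-calibration
  replicates at n_boot 2000, graphs ≤ 8 nodes for brute-force oracles)
  were chosen so the full suite completes in well under a minute of
  compute per stage while keeping Monte-Carlo error far below the asserted
  tolerances.

## Known limitations

- The consistency filter's sign rule and the best-probe ortholog collapse
  are interpretations of common practice; both are isolated in
  `intersect` and easy to swap.
- Combining GO categories into one flat collection ignores term
  hierarchy; enrichment p-values for nested terms are not independent,
  and BH here controls FDR only across the flat list.
- pPERT's null permutes gene positions within a pathway, ignoring
  gene-gene expression correlation; on strongly co-expressed pathways it
  is anti-conservative, a property inherited from the perturbation-
  analysis approach itself.
- The axolotl pooling model (variance division) ignores the non-linearity
  of pooling on the raw scale.
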