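# Methods

## Differential expression

The DE stage follows the classic count-based skeleton. Size factors are
median-of-ratios: `s_j = median_i(y_ij / geomean_i)` over genes with strictly
positive counts in every sample; when no such gene exists (tiny fixtures),
genes positive in at least half the samples are used with geometric means
over their positive entries. Factors are reported unrescaled — they are
defined only up to a common constant, and only their ratios matter to the
fit, so multiplying one sample's column by `c` multiplies its factor
*relative to every other sample* by `c`.

Per-gene dispersions use the method of moments on normalized counts,
`α̂ = max(1e-8, (s² − m) / m²)`, with `s²` the pooled *within-group* variance
(so planted group differences do not masquerade as dispersion) and `m` the
grand mean. At the study's group sizes (5–12 samples per group) these
gene-wise estimates carry only ~10 degrees of freedom, and plugging them
into a Wald test referenced to the standard normal behaves like a
t-statistic with ~10 df: measured null type-I error 0.082 at nominal 0.05.
We therefore moderate them, as the established DE tools do: a mean-dependent
trend `α_tr(m) = a0 + a1/m` is fitted to the gene-wise estimates (two
least-squares passes, trimming gross outliers), each gene's variance is
shrunk toward the trend variance with a scaled-inverse-chi-square posterior,
and the prior degrees of freedom are *estimated* from the excess spread of
the observed log-variances around the trend over the chi-square sampling
noise (`trigamma` matching). When genes genuinely share a dispersion the
prior df is large and shrinkage nearly total; when dispersion spread is
real, gene-wise estimates dominate. Measured null type-I error after
moderation: 0.051–0.054 across seeds. The unmoderated gene-wise estimator
remains available (`run_de(..., moderate=False)`).

The NB GLM (log link, design = intercept + group, offsets `log s_j`) is fit
by iteratively reweighted least squares, vectorized across genes: weights
`W = μ/(1+αμ)`, convergence when the deviance change falls below 1e-8
(relative), iteration cap 100. The Wald SE comes from the Fisher information
of the weighted fit, `Var(β̂) = [(XᵀWX)⁻¹]₁₁`; coefficients are reported in
log2 units. Degenerate cases are defined, not dropped: all-zero genes get
(log2FC 0, p 1); non-converged genes are flagged and set conservatively to
p 1. Benjamini–Hochberg adjustment is appended, but the DEG filter applies
**raw** p < 0.05 with |log2FC| ≥ 0.5 by default (the fold-change boundary
inclusive, the p boundary exclusive); a flag switches the filter to adjusted
p. LFC shrinkage, outlier replacement, independent filtering and
multi-factor designs are out of scope.

## Overlap

Gene symbols are harmonized before intersection: an optional two-column
ortholog table is applied first, then symbols are upper-cased (the minimal
rule that merges mouse `Ccr8` with human `CCR8`); collisions keep the record
with the smallest p. A gene is a *common* DEG only if it passes the filter
with the same direction in every dataset — the only rule under which the
common up and down totals are disjoint. Venn regions are exclusive
membership signatures and always sum to the union.

## Enrichment

The over-representation p is the upper hypergeometric tail
`P(X ≥ k)` for k query genes in a K-set, query size n, universe N —
identical (to 1e-12, tested against 200 random Fisher-exact instances) to a
one-sided Fisher exact test. The universe defaults to the union of the
collection's sets, not a whole genome: an explicit, overridable choice,
since enrichment p-values are only meaningful relative to a stated
background. BH runs across all sets of a collection; the significance
filter is strict (p = 0.05 excluded) on raw p by default.

## Network

Centralities mirror the normalized conventions of desktop network-analysis
tools so every value lies in [0, 1]: betweenness is Brandes on unweighted
shortest paths normalized by `(n−1)(n−2)/2` with `n` the node's *component*
size; closeness is the reciprocal mean shortest-path distance within the
component (isolated nodes 0); clustering is the connected fraction of
neighbor pairs (0 for degree ≤ 1). Interaction confidence scores are used
only for edge inclusion (default threshold 400, the conventional
medium-confidence cutoff); shortest paths are unweighted. Hub ranking sorts
by (degree, betweenness, closeness) descending with an alphabetical
tie-break, and an annotation filter restricts hubs to a supplied gene set
(e.g. chemokine-signaling genes) preserving rank order.

## Correlation

Spearman's ρ is the Pearson correlation of mid-ranks with the two-sided t
approximation `t = ρ·sqrt((n−2)/(1−ρ²))` on n−2 df — the convention of the
pan-cancer web platforms these statistics mirror. The approximation is
accurate at moderate-to-large n (within 10% of a 20,000-draw permutation p
at n = 30 in our checks) but crude at n ≤ 6; correlations are refused below
n = 3 and zero-variance input raises rather than reporting 0. Plain
Spearman is the default; a rank-based partial-correlation hook accepts an
optional covariate (e.g. tumor purity) but is off by default since the
source platforms' adjustment is not specified. Radar stars: `**` p < 0.01,
`*` p < 0.05.

## Scoring

The rubric bins are exactly as printed in the scoring table: p < 1e-50 → 3,
[1e-50, 1e-30) → 2, [1e-30, 1e-10) → 1, else 0 (a p exactly at a threshold
falls into the weaker bin); ρ > 0.3 → 3, (0.2, 0.3] → 2, (0.1, 0.2] → 1,
else 0 (negative correlations score 0). The TMB and MSI columns are *sums*
of per-gene bins over {CCR8, CD274, PDCD1} — the only reading under which
the published column values of 9 and 6 are reachable from 0–3 bins and
every row sums exactly to its printed final; no separate TMB weighting is
applied because none is needed for the rows to sum. Treg infiltration uses
the same correlation bins (no separate rubric exists); its raw value is a
user input. The standard-of-care ICI bonus (+3) defaults to
BRCA/HNSC/COAD/STAD true, THCA/READ false. Aggregation accepts raw
statistics or pre-binned scores per component, raw taking precedence; the
final score is monotone in every component. Ranking is descending by final
score with alphabetical tie-break (the published table does not order its
tie).

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated.

* **Counts**: NB with Var = μ + α·μ² (the same parameterization the DE
  stage assumes), baseline gene means log-normal (natural-log mean
  `log 100`, sd 1.0 — typical genes around 100 counts spanning roughly an
  order of magnitude either way), size factors log-uniform in [0.7, 1.4],
  dispersion default 0.05, planted DEGs at |log2FC| 2.0 with exact count
  `round(frac_de · n_genes)`. The trio uses the source series' case/control
  shapes (5/5, 12/6, 6/6) and plants a shared core with identical signs
  (default emulation: 57 genes, 35 up / 22 down); remaining planted DEGs
  are disjoint across datasets so the truth intersection is exactly the
  core.
* **Gene sets**: one spiked set plus uniform draws from the universe.
* **PPI**: preferential attachment grown from a seed core (size
  `max(3m+1, h+1)`) in which every planted hub is connected to every other
  core node; the head start plus rich-get-richer growth makes a single
  planted hub the strict degree maximum in ≥ 95% of seeds (measured
  99–100%). Edge scores are uniform in [400, 1000].
* **Pan-cancer panels**: Gaussian copula per cancer type. Requested
  Spearman setpoints are converted to latent Pearson correlations via
  `r = 2·sin(πρ/6)`; unspecified pairs are filled by a single-factor rule
  (product of each variable's correlation with the target gene), which
  keeps typical requested structures positive definite — infeasible
  structures raise with the nearest feasible matrix printed. Marginals:
  expression Gaussian on the log scale, TMB Poisson (rate 50; its ties
  attenuate realized ρ by well under the test tolerances), MSI
  logit-normal in (0, 1). Only the correlations are analysis-relevant; the
  marginal scales are modeling choices.

All generators take explicit seeds (no global RNG state); identical
config + seed is bit-identical output.

What the generators do **not** emulate: read-level data, single-cell
structure, batch effects, cross-species orthology (harmonization is
exercised with symbol-case fixtures instead), mean-dependent dispersion
trends, outlier samples, or the gene–gene correlation structure of real
transcriptomes. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
performance on any particular public dataset — the published GEO-derived
DEG counts, centrality table and TCGA correlations depend on external data
and database versions and are deliberately not golden targets; the planted
57/35/22 core and the checkpoint-correlation setpoints (0.584, 0.606,
0.758) are used as *generator setpoints* whose recovery the suite asserts.

## Problem sizes

The validation suites run at desk scale, chosen to make the Monte-Carlo
tolerances meaningful: null calibration at 5,000 genes (6v6), effect
recovery at 500 genes, trio recovery over 20 seeds at 2,000 genes,
enrichment oracle over 200 random instances, centrality oracle over 50
graphs with n ≤ 8 (where exhaustive path enumeration is exact), copula
recovery at n = 2,000 per cancer.

## Known limitations

* The Wald test is asymptotic; even moderated it is not exact at very small
  group sizes, and the type-I calibration band is demonstrated at the
  study's 6v6 shape, not guaranteed universally.
* Method-of-moments dispersion is less efficient than maximum likelihood;
  it was chosen for transparency and testability.
* The strict three-way intersection is conservative: a gene marginally
  missing one dataset's filter is dropped entirely.
* Enrichment p-values depend strongly on the universe choice; the default
  (union of sets) is explicit but not a biological statement.
* The scoring rubric is a published heuristic; the package reproduces it
  faithfully but attaches no uncertainty to the final scores.
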