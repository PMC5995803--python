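# Methods

## Problem and scope

Bulk brain tissue is a mixture of cell types, so bulk expression differences
between samples are confounded by cell-composition differences. `brainsig`
implements the marker-derivation half of that problem — scoring every gene's
association with each major brain cell type (astrocytes AST, endothelial
cells END, microglia MIC, neurons NEU, mature oligodendrocytes MOL, and
oligodendrocyte precursor cells OPC) from labeled expression matrices and
combining those scores across datasets — and the application half: using the
top-ranked markers to estimate per-sample surrogate cell-type proportion
variables (SPVs) from bulk expression and to residualize them out.

## Cell-type association measures

Three measures, computed per gene against a target cell type from a
gene-by-sample count matrix with per-sample labels:

* **Enrichment** — shrunken log2 fold change of the target's samples versus
  all other cell types pooled into one reference group.
* **Specificity** — the minimum shrunken log2 fold change over each other
  cell type taken individually. A gene scores high only if it is elevated
  against *every* other type; a gene high in two types has near-zero
  specificity in both while remaining enriched in both.
* **Absolute expression** — mean RPKM within the cell type (quantile
  normalization across samples, then per-gene length and per-sample library
  scaling) with its standard error and its within-type rank (1 = highest).

MOL and OPC are mutually excluded from each other's reference set: their
programs are too similar for the contrast to be informative, and the
exclusion is enforced at construction and at config validation.

Genes enter the analysis only if their arithmetic-mean raw count reaches
`min_mean_count` (default 5) in at least one cell type; the boundary is
inclusive.

### Shrunken fold changes

Raw fold changes of low-count genes are wildly unstable, so the statistic is
a predictive (shrunken) fold change: each observation is augmented by a
pseudocount proportional to its sample's relative library size,

    y*_gs = y_gs + prior * L_s / mean(L),      L*_s = L_s + 2 * prior * L_s / mean(L),

and the statistic is `log2(mean CPM*_A) - log2(mean CPM*_B)` with
`CPM* = y*/L* * 1e6`. `prior` defaults to 10 — heavy shrinkage chosen for
robust ranking rather than unbiased effect estimation; as counts grow the
shrinkage vanishes and the statistic converges to the plain log ratio. The
mean library size is taken over the samples in the comparison. Increasing
`prior` monotonically contracts |log2FC| toward zero (a tested invariant).
One consequence worth knowing: a true 16-fold (log2 = 4) marker at
baseline-100 depth estimates near 3.87, not 4.0 — ranks are unaffected.

### Testing

P-values come from a per-gene likelihood-ratio test in a negative-binomial
GLM with a log link, log-library-size offset, a target-vs-reference group
indicator, and any per-sample covariates as additive terms. Dispersion
(alpha in `var = mu + alpha*mu^2`) is estimated per gene by a
Pearson-residual method-of-moments estimator and shrunk toward a lowess
mean–dispersion trend across genes (`frac = 0.5`, prior weight equivalent to
20 samples, alpha clipped to [1e-8, 10]); the LRT then holds dispersion
fixed in both nested fits. This is a deliberately light empirical-Bayes
scheme: on null simulations its raw type-I error at nominal 0.05 sits near
0.05 (checked to stay within [0.02, 0.10]), which is the property that
matters for downstream thresholding. Benjamini–Hochberg adjustment is
applied across genes; the volcano significance rule is adj. p < 0.05
(strict) and log2FC >= 2, i.e. fold change >= 4 (inclusive).

The specificity p-value is the one from the pairwise contrast that attains
the minimum fold change — specificity is reported primarily as a fold
change, and this choice merely completes the table. Confounded covariates
(collinear with the group indicator) are rejected by name before fitting.

### Quantile normalization and RPKM

Quantile normalization maps each column's order statistics onto the mean of
sorted columns; tied values receive the mean of the target values their
positions span, making the map deterministic under ties. Normalization is
applied to raw counts (the augmented counts exist only inside the
fold-change statistic). RPKM uses the post-normalization column sums as
library sizes; genes lacking a length annotation are dropped with a warning.
All ranking ties anywhere break by (statistic descending, gene id ascending)
so outputs are byte-reproducible.

## Cross-dataset consensus

Per-dataset tables are aggregated per (cell type, measure). Fold-change
measures aggregate the per-dataset log2 fold changes — the default
aggregator is the median, with the mean available behind `agg` (aggregation
is done on the log scale, preserving up/down symmetry). Expression
aggregates within-dataset ranks by their median (the grand-median rank).
A gene is included only when present in strictly more than half of the
in-scope datasets that contain the cell type (3 of 5 qualifies, 2 of 4 does
not); the combined human+mouse scope additionally requires presence in at
least one dataset of each species. Cross-species matching is by case-folded
gene symbol; collisions after folding are surfaced, never silently merged.
The consensus ordering is invariant to dataset input order.

## Set statistics

For gene sets D1, D2 in a universe U, fold enrichment is

    FE = |D1 n D2| / (|D1| |D2| / |U|),

the observed intersection over its expectation under independent uniform
draws; the pairwise p-value is the hypergeometric upper tail. The k-way
generalization divides by `prod|Di| / |U|^(k-1)`; its exact p-value uses the
fact that, conditional on the running intersection of independent uniform
sets, the overlap with the next set is again hypergeometric, so the exact
distribution is a chained hypergeometric mixture (validated against
exhaustive enumeration at small sizes). The Monte Carlo alternative draws
the sets uniformly and applies the `(1 + hits)/(n_perm + 1)` correction.

Gene-set Fisher tests are two-sided with BH across sets and odds ratios
reported as infinite when the table's off-diagonal product vanishes. The
module-overlap matrix between two network partitions uses one-sided
(enrichment-direction) tests for every module pair, BH applied jointly over
the whole matrix — stricter than per-column adjustment — with each column
summarized by the proportion of row modules it significantly overlaps
(column normalization by the row-module count).

## Surrogate proportion variables

For each cell type the bulk matrix (assumed already normalized; log scale
recommended — integer-looking input triggers a warning only) is subset to
that type's top `n_markers` markers (default 50). Each marker row is
centered and scaled to unit variance across samples (`scale_genes`, default
on, exposed because the scaling choice is a genuine degree of freedom), and
the SPV is the first right singular vector of the resulting submatrix —
equivalently the first principal component over samples. SVD's sign is
arbitrary, so the SPV is flipped, when necessary, to correlate positively
with the per-sample mean of the scaled marker rows; averaging many markers
makes this anchor robust to a few anticorrelated markers. Consequently,
negating all marker rows negates the corrected SPV (the anchor negates);
magnitudes are unchanged. SPVs are unit vectors, relative within a cell
type across samples, and carry no absolute-fraction meaning; no simplex
constraint is imposed and none should be inferred.

The cumulative-marker curve re-estimates the SPV from the top n markers for
n = 2..N against a per-sample reference, alongside each marker's individual
correlation; it is the standard diagnostic for marker-list quality and
reproduces the known failure mode where a block of anticorrelated markers
transiently flips the estimate's sign before better markers dilute it.

Adjustment regresses each gene on all SPVs plus an intercept by OLS and
returns residual + gene mean, leaving every gene exactly uncorrelated with
every SPV (to numerical precision) and requiring
`#samples > #cell types + 1` degrees of freedom.

## Synthetic study conditions

The generators define the conditions under which the toolkit is validated:

* `simulate_cells`: 2000 genes, six cell types, 50 cells per type, 50
  disjoint planted markers per type with a log2 effect of 4, NB counts with
  baseline mean 100 (cell-population-level depth rather than shallow
  droplet-style data), dispersion alpha 0.25, log-normal library-size
  factors with CV 0.3. No zero-inflation by default; an optional dropout
  rate exists for stress tests only.
* `simulate_bulk`: 40 samples whose proportions are Dirichlet(1) across the
  six types, expected expression the proportion-weighted mixture of the
  per-type mean profiles, NB noise around the expectation (exact convex
  combination in the noiseless mode).

Everything is a pure function of (config, seed). These conditions emulate
the structure the measures assume — markers elevated in exactly one type,
library-size spread, overdispersed counts — but not ambient RNA, doublets,
batch effects, cell-type correlation of proportions, or symbol-mapping
noise; passing tests demonstrate correctness of the machinery and
recoverability under clean conditions, not performance on real tissue.

## Numerical choices and limitations

* GLM fits use IRLS with up to 100 iterations; genes whose fits fail
  (degenerate patterns) get NaN p-values and pass through BH as NaN.
* Dispersion clipping, the lowess fraction, and the prior weight are fixed
  constants, not exposed knobs; they matter only through the type-I-error
  property above.
* The consensus of a single dataset degenerates to that dataset's ranking;
  `top_n` beyond the table length returns everything with a warning.
* The NB test is a plain fixed-dispersion LRT, not a quasi-likelihood
  F-test; with very few samples per group it can be mildly liberal.
* Marker lists shared between two cell types are kept in both with a
  warning — cross-assigned markers are a data problem the tool surfaces
  rather than resolves.
* The bundled marker table is a small curated list of canonical brain
  markers for smoke tests, not a derived consensus output.
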