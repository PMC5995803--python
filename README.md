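# brainsig

Brain cell-type expression signatures, consensus marker ranking, and
SVD-based estimation of cell-type proportions from bulk expression.

Bulk brain RNA-seq measures a mixture of cell types — astrocytes (AST),
endothelial cells (END), microglia (MIC), neurons (NEU), mature
oligodendrocytes (MOL), and oligodendrocyte precursors (OPC) — so apparent
expression differences between samples are often cell-composition
differences in disguise. `brainsig` addresses both halves of that problem
for transcriptomics researchers:

1. **Signature derivation.** From a gene-by-sample count matrix with
   per-sample cell-type labels, score every gene by three measures:
   *enrichment* (shrunken log2 fold change, target versus all other types
   pooled, with a negative-binomial likelihood-ratio test), *specificity*
   (the minimum shrunken log2FC against each other type individually, so
   only genes elevated against *every* other type score high), and
   *absolute expression* (within-type mean RPKM and rank). MOL and OPC are
   mutually excluded from each other's reference set. Fold changes are
   shrunk with a library-size-proportional pseudocount (prior 10): for
   groups A and B,

       log2FC = log2(mean CPM*_A) − log2(mean CPM*_B),
       y*_gs = y_gs + prior·L_s/mean(L),   L*_s = L_s + 2·prior·L_s/mean(L).

2. **Consensus ranking.** Aggregate signatures across datasets and species
   (median log2FC, or grand-median expression rank), keeping genes present
   in more than half of the datasets and — for combined human+mouse
   rankings — in at least one dataset of each species.

3. **Set statistics.** Fold enrichment of gene-set intersections,
   FE = |D1∩D2| / (|D1||D2|/|U|), with hypergeometric p-values, an exact
   multi-set intersection test (chained hypergeometric), Fisher's-exact
   gene-set enrichment, and module-overlap matrices between coexpression
   networks.

4. **Deconvolution.** From the top ~50 markers per cell type, estimate a
   surrogate proportion variable (SPV) per cell type as the first right
   singular vector of the z-scaled marker submatrix of a bulk expression
   matrix (sign-anchored to mean marker expression), then optionally
   residualize the SPVs out of every gene to remove composition effects.

A seeded synthetic-data module generates labeled single-cell-like count
matrices with planted markers and Dirichlet-mixed bulk profiles with known
proportions, so every stage is testable against ground truth.

## Worked example

```python
import numpy as np, pandas as pd
from brainsig import (SimulationConfig, simulate_cells, simulate_bulk,
                      filter_expressed, enrichment, estimate_proportions)
from brainsig.simulate import marker_truth
from scipy.stats import spearmanr

cfg = SimulationConfig(seed=1)          # 2000 genes, 6 types, 50 planted markers each
cells, truth = simulate_cells(cfg)
cells = filter_expressed(cells)         # mean count >= 5 in at least one type
ast = enrichment(cells, "AST")
print(ast.head(3).to_string(index=False))

bulk, bulk_truth = simulate_bulk(cfg, seed=2)
mk = marker_truth(cfg)
markers = pd.DataFrame([{"cell_type": ct, "gene_id": g, "rank": i + 1}
                        for ct in cfg.cell_types
                        for i, g in enumerate(g2 for g2, c in mk.items() if c == ct)])
est = estimate_proportions(np.log2(bulk + 1), markers)
rho = spearmanr(est.spv["AST"], bulk_truth.bulk_proportions["AST"]).statistic
print(f"Spearman(SPV_AST, true proportion) = {rho:.3f}")
```

Output:

```
gene_id cell_type    measure     stat  p_value  adj_p  rank
  G0014       AST enrichment 4.111087      0.0    0.0     1
  G0009       AST enrichment 4.052165      0.0    0.0     2
  G0032       AST enrichment 4.035104      0.0    0.0     3
Spearman(SPV_AST, true proportion) = 0.988
```

The top-ranked genes are planted astrocyte markers (all 50 of the planted
markers land in the enrichment top 50; their shrunken log2FC sits near the
planted effect of 4), and the astrocyte SPV estimated from the bulk
mixtures tracks the true mixing proportions with Spearman rho ≈ 0.99.

## Command line

```sh
brainsig simulate cells --config sim.yaml --seed 1 --out data/
brainsig signatures --config run.yaml          # per-dataset signature tables
brainsig pipeline   --config run.yaml          # signatures -> consensus -> markers -> SPVs
brainsig estimate-cells --bulk bulk.tsv --markers markers.tsv --n 50 --out spv.tsv
brainsig adjust --bulk bulk.tsv --spv spv.tsv --out adjusted.tsv
brainsig overlap --sets modules.gmt --out overlap.tsv
```

Matrices are TSV/CSV (first column gene id, header row sample ids) or
MatrixMarket MTX with `<stem>.rows.txt`/`<stem>.cols.txt`; sample labels
and covariates live in a `<stem>.samples.tsv` sidecar. Every run writes a
manifest (inputs, parameter hash, seed, versions) for byte-identical
reproduction.

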