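# screlmap

Localize a curated disease gene set to the cell types that preferentially
express it, in single-cell RNA-seq data.

Congenital anomalies of the kidney and urinary tract (CAKUT) are genetically
heterogeneous: dozens of genes, diverse variant classes, no obvious shared
mechanism. One way to look for convergence is expression: if CAKUT genes act
through particular cell populations, those populations should over-express
the gene set relative to a matched background. `screlmap` implements that
analysis as a tested, reusable pipeline for any disease gene set and any
annotated cell × gene count matrix — with a packaged 91-gene CAKUT list
(a reconstructed stand-in; see `src/screlmap/data/cakut_genes_synthetic.tsv`)
and a synthetic-data generator with planted ground truth so every stage is
testable without downloads.

## The statistics

**Specificity screen.** For gene *g* and cell types *c₁ … c_k*, a
tie-corrected Kruskal–Wallis test of H₀: the expression distributions
X_{g,c₁} … X_{g,c_k} are identical, with Benjamini–Hochberg FDR control
across the tested genes. Alongside: per-type mean log-normalized expression,
detection rates, and a χ² goodness-of-fit test of "top-expressing type"
counts against the background cell-type abundances.

**Disease-relevance score.** The raw score of cell *i* is the mean
log-normalized expression of the gene set in that cell. Significance comes
from K matched control gene sets (default K = 1000): each control gene is
drawn from its seed gene's mean-expression quantile bin — optionally the
nested (expression, gene-length) bin, which guards against long, highly
detectable genes inflating the signal. Per cell,

    norm_score = (raw − mean_K) / sd_K,

and per cell type the association statistic is the mean `norm_score` over the
type's cells, with

    empirical p = (r + 1) / (K + 1),   r = #{control statistics ≥ observed},
    z = (observed − null mean) / null sd.

A companion heterogeneity test applies the same Monte-Carlo machinery to the
within-type *variance* of scores, flagging types that hide strongly scoring
subpopulations.

**Downstream.** Genes are ranked by Pearson correlation of expression with
`norm_score` (driver ranking); rankings are compared across datasets
(quadrant labels), classified across ordered developmental stages
(early-peak / late-rise / stable), and intersected with per-organ top-K
lists for cross-organ prioritization.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic data
(each prints what it found and writes TSVs under `results/`):

```bash
python analysis/01_simulate_atlas.py        # planted 20-gene program, fold 4
python analysis/02_specificity_screen.py
python analysis/03_relevance_scoring.py     # K = 1000 matched controls
python analysis/04_driver_ranking.py
python analysis/05_temporal_classification.py
python analysis/06_organ_overlap.py
```

Output of steps 2–4 on the default seed:

```
20/20 program genes significantly cell-type-specific (FDR < 0.05)
enrichment chi2 = 140.0, p = 2.82e-29
max O/E ratio: mesangial_like (8.00)
[expression_matched] strongest association: mesangial_like (observed score = 3.4426,
    null mean = -0.0000, z = 55.61, empirical p = 0.000999)
[dual_matched] strongest association: mesangial_like (observed score = 3.5295,
    null mean = -0.0000, z = 54.64, empirical p = 0.000999)
20/20 of the top-20 driver ranks are planted program genes
```

Reading this: every planted gene is cell-type-specific; the planted type is
the top-expressing type for all 20 genes (8× over-represented relative to
its abundance); the association test assigns it the minimum attainable
empirical p at K = 1000, i.e. 1/1001 ≈ 0.000999, under both the
expression-matched and the dual expression+length matched null; and the
driver ranking recovers exactly the planted program.

The same pipeline runs from a shell on real data:

```bash
screlmap run --input-dir my_atlas/ --gene-set my_genes.tsv \
    --n-control-sets 1000 --match-length --length-table lengths.tsv \
    --out-dir results/my_run --seed 1
```

Input formats: Matrix Market triplet (`matrix.mtx`, genes × cells, plus
`genes.tsv`, `barcodes.tsv`, and a `cell_meta.tsv` with a `cell_type`
column) or h5ad; gene sets as TSV with HGNC symbol and/or Ensembl-ID
columns; gene lengths as TSV (`gene_id`, `length_bp`) or derived from a GTF
(union-exon length).

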