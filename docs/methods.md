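# Methods

This note documents the models, statistics, parameter choices and known
limitations of `screlmap`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Counts are QC-filtered (cells with fewer than `min_genes_per_cell` detected
genes removed first, then genes detected in fewer than `min_cells_per_gene`
remaining cells; defaults 200 and 3, standard single-cell practice), then
library-size normalized to `target_sum` = 10,000 counts per cell and
log-transformed:

    normalized[i, g] = ln(1 + counts[i, g] · 10000 / total_i).

Natural log is used (the convention of the major preprocessing frameworks).
QC thresholds and the seed are echoed into every output header. Filtering is
idempotent at fixed thresholds; note the gene pass is not re-applied after
cell removal in a second pass, so extremely adversarial inputs could need
two applications — real data does not.

Gene identity is resolved Ensembl ID first, then HGNC symbol; unmapped
gene-set members are reported and skipped, not fatal. Gene lengths come from
a user TSV or from a GTF helper computing union-exon length (merged
overlapping exons), which tracks transcript detectability better than
genomic span.

## Specificity screen

Per gene, a tie-corrected Kruskal–Wallis H across cell types with at least
`min_cells_per_type` = 10 cells (smaller types are excluded and flagged;
fewer than two eligible types is an error), χ²_{k−1} approximation for the
p-value, Benjamini–Hochberg across exactly the tested gene list. When every
value is identical the tie-correction denominator is zero; the convention is
H = 0, p = 1. The implementation is vectorized over genes (ranks via
`scipy.stats.rankdata(axis=0)`); tests verify it against `scipy.stats.kruskal`
and against the rank-sum formula computed by hand.

Top-expressing type = argmax of per-type mean normalized expression; ties
broken by higher detection rate, then lexicographic type name. The χ²
goodness-of-fit test compares top-type counts with expectations proportional
to cell-type abundances; cells with expected count < 1 are pooled into an
"other" category before the test (classical validity rule) while O/E ratios
are always reported unpooled.

## Matched-control relevance scoring

**Binning.** Genes are assigned to `n_expr_bins` = 20 quantile bins of mean
normalized expression (over all cells). With length matching enabled,
`n_len_bins` = 5 length quantile bins are computed *within* each expression
bin (nested design). Nesting matters: when length and expression are
correlated, global length quantiles carry almost no information within an
expression stratum — except in the unbounded top expression bin, which is
precisely where a long-gene set concentrates — whereas within-stratum
quantiles match the residual length profile directly. This is the same
nesting the established single-cell disease-scoring method uses for its
mean/variance bins. Bins under `min_bin_occupancy` = 10 genes are merged
into the nearest bin (length-neighbor within the same expression bin first,
then expression-neighbor).

**Sampling.** For each of K control sets, each seed gene is replaced by a
uniform draw from its bin, without replacement within a bin while the pool
allows; an exhausted bin falls back to with-replacement sampling (logged).
Seed genes are excluded from control pools by default (`exclude_seed_genes`);
if exclusion empties a bin (possible for extreme seed sets under nested
binning), the pool falls back to the full bin membership, logged. A null
simulation at 60 replicates showed the designated-type false-positive rate
at the nominal 0.05 with exclusion on.

**Scoring.** Raw score = unweighted mean of normalized expression over the
set (the cited scoring framework uses inverse-variance weights; the
unweighted mean is the default here and satisfies the same invariants — the
aggregation is a documented, swappable choice). The observed score is
computed through the same sparse-matrix path as the control scores so that a
control set identical to the gene set reproduces it bitwise; control SDs
within one ulp of zero are treated as degenerate (norm_score 0, flagged).

**Association and heterogeneity.** Observed statistic per type = mean of
norm_score over the type's cells; the k-th null statistic applies the same
aggregation to control set k's per-cell standardized scores. One-sided
(enrichment) empirical p = (r+1)/(K+1), z against the null mean/SD.
Heterogeneity replaces the mean by the within-type variance (ddof = 1) — a
Monte-Carlo stand-in for the cited framework's heterogeneity test, which is
not fully specified in the literature we reimplement from. Emitted p-values
are raw (granular (r+1)/(K+1) values); BH across types is available but off
by default. All empirical p-values lie on the grid {1/(K+1), …, 1}; the
minimum attainable at K = 1000 is 1/1001 ≈ 0.000999.

## Driver ranking, temporal classes, organ overlap

Drivers: Pearson r between each gene's normalized expression and the
standardized score (invariant to control-set location/scale); Spearman
offered for heavy-tailed expression. Constant genes are excluded and listed;
ranks are descending in r with gene-ID tie-break. Ranking comparisons label
genes `a_specific` / `b_specific` when |r_a − r_b| exceeds a margin
δ = 0.05 (in r units, a drawing convention made explicit), else by joint
sign.

Temporal: with per-stage driver tables over the shared gene intersection,
`early_peak` requires rank ≤ `r_early` at the first stage and a rank drop of
at least `drop_frac · G` by the last; `late_rise` is the mirror; defaults
r_early = 5, drop_frac = 0.10, both explicit parameters (the source
analyses' criterion is qualitative; these defaults are one configuration,
not ground truth).

Organ overlap: top-K (default K = 100) genes per organ by driver rank,
intersected with the disease set; organ-specific = in exactly one organ's
intersection; shared = in all.

**The self-correlation floor.** A member of an L-gene scored set retains a
mechanical Pearson correlation of about 1/√L with the score even when it
carries no signal, because it contributes 1/L of the raw score. With n
cells, null correlations spread ~1/√n, so an inactive set member sits near
the P(Z > √(n/L)) quantile of the ranking — a floor below which no set
member can drop, active or not. Consequences: (i) rank-drop thresholds
larger than that quantile are unattainable for set members, so temporal
classification of set members must use drop_frac below the floor quantile;
(ii) small scored sets (large 1/√L) pin all their members near the top of
any driver ranking. This applies equally to the method on real data.

## Synthetic data generator

The generator emulates what the statistics rely on, with defaults chosen
once as a realistic desk-scale regime:

- cell types of configurable, unequal abundance;
- negative-binomial counts, mean = size_factor_i · baseline_g · fold_{g,c};
  per-gene baselines log-normal(−1.5, 1.0) (median gene ≈ 0.22 counts/cell,
  library sizes ≈ several hundred counts — sparse, 10x-like);
  NB size (dispersion) 2.0 (variance = μ + μ²/2); `np.inf` gives the Poisson
  limit;
- per-cell size factors log-normal(0, 0.3), so normalization is non-trivial;
- a planted program: `program_genes` × `program_types` get mean × fold;
- gene lengths log-normal(7.8, 0.7) (median ≈ 2.4 kb, union-exon-like),
  either independent of expression or rank-coupled to the baseline mean by a
  Gaussian copula with parameter rho ∈ [0, 1] — a one-knob confounder for
  the dual-matched null;
- stage series share a gene universe; folds may vary per stage.

Not emulated: doublets, ambient RNA, batch effects, trajectories, spatial
structure, or a *causal* effect of length on detection (length is only
correlated with expression). Passing tests therefore demonstrate the
statistical machinery — calibration, recovery, confounder control — not
robustness to those artifacts. Because baselines are redrawn per seed, raw
library-size totals differ in location across seeds; distributional
comparisons across seeds are made after scaling by the mean.

Seeds: one master seed derives independent per-stage stream seeds via
`numpy.random.SeedSequence([master, stream])`, so any stage is
independently reproducible.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

Problem sizes are desk-scale choices: thousands of cells, K = 100–200
controls, 20–100 replicates.

- **Empirical-p granularity.** Exceedance counts r = 0, 2, 6, 11 over 1000
  controls give p = 0.000999001, 0.002997003, 0.006993007, 0.011988012 —
  the arithmetic signature of a K = 1000 Monte-Carlo design.
- **Calibration.** One null dataset (2,000 genes, 5 types × 400 cells),
  100 random 50-gene "disease" sets, K = 200. The fraction of association
  p ≤ 0.05 for one designated type must lie in the exact binomial 99%
  envelope around 0.05. One type per replicate is counted because the five
  types of one replicate share control draws and are not independent
  Bernoulli trials; the pooled fraction is reported alongside.
- **Recovery.** 20 replicates of a 20-gene, fold-4 program in a 200-cell
  type (others 4 × 400); success = the program type attains the minimum
  attainable p = 1/(K+1); required in ≥ 95% of replicates.
- **Confounder control.** Lengths rank-coupled to expression (rho = 0.8);
  the "disease" set is the 50 longest genes — a null set with respect to any
  cell-type program but extreme in both covariates. Expression-only matching
  leaves a systematic global score shift (mean |z| across types ≈ 8 in this
  regime); nested dual matching must yield mean |z| no larger, averaged over
  20 replicates.
- **Oracle equivalence.** KW, BH, χ² goodness-of-fit, Pearson r, and
  empirical p/z each match an independent brute-force implementation on
  ≤ 30-element toys to 1e-10.
- **Temporal recovery.** 20 replicates; three stages share one baseline
  profile (a gene's typical level is a gene property); 30 early genes (folds
  8, 2, 1), 30 late genes (1, 2, 8) in a 100-cell target type among three
  types; the scored set is padded to L = 150 with non-dynamic members, as in
  real curated sets. Program genes are drawn from the 40th–90th baseline
  percentile — genes below it are too rarely detected to rank. Following the
  floor analysis above (n = 300, L = 150 ⇒ floor quantile ≈ 0.08), the
  classifier runs with drop_frac = 0.05 and r_early = 2 × 30; a replicate
  succeeds when ≥ 80% of each planted group gets its label; required in
  ≥ 90% of replicates.

## Limitations

- The heterogeneity statistic (within-type variance) is a declared stand-in
  for the cited framework's unspecified test; both satisfy the Monte-Carlo
  contract but may rank borderline types differently.
- Quantile binning on small gene universes (< ~200 genes) merges heavily and
  weakens matching; the pipeline logs merges but cannot manufacture
  resolution.
- The association statistic (type mean of standardized scores) is one of
  several defensible aggregations; it is documented as swappable.
- Real-data effects not in the generator (above) are untested by
  construction.
- The packaged CAKUT list is a reconstructed stand-in with placeholder
  Ensembl IDs; users analyzing real data should supply their own curated
  table.
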