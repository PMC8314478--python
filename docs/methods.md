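# Methods

This note documents the models and procedures implemented in `evoscreen`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices
that matter.

## Rank-based screen for rapidly evolving proteins

For each single-copy gene with a phylogeny, two summaries are extracted: the
**total branch length** (sum of all edges; the gene's overall evolutionary
rate) and the **focal terminal branch length** (the edge subtending the
focal species; its rate after divergence). Genes are ranked ascending by
each summary (rank 1 = shortest), partitioned into consecutive bins of
`bin_size` (default 300) by total-length rank — so that slowly and rapidly
evolving genes are compared only against genes of similar overall rate — and
within each bin the `ceil(top_fraction × bin size)` genes (default top 10%)
with the largest rank discrepancy (focal rank − total rank) are selected.
The last bin keeps the remainder; with 2992 genes this yields nine bins of
300 plus one of 292 and exactly 300 selections.

Conventions the method description leaves open, fixed here:

* **Rank direction** is ascending; under this convention a large positive
  discrepancy means the focal branch is unusually long for the gene's
  overall rate, which is the intended signal.
* **Ties** in length are ordered by larger focal terminal length first, then
  lexicographic gene id, *before* ranks are assigned, so each ranking is a
  strict permutation of 1..N and results are permutation-invariant and fully
  deterministic. The same rule breaks discrepancy ties during selection.
* **Per-bin count** uses the ceiling so every non-empty bin contributes at
  least one gene.

## Venom-gland-associated gene (VGG) filter

A gene qualifies when all three hold: (a) it is among the top `n_top`
(default 500) venom-gland genes ranked by **median FPKM across venom-gland
replicates**, descending; (b) it is significantly *higher* in the venom
gland than in the carcass — q below `q_max` (default 0.05) **and** positive
log2 fold change (the directional reading of "highly expressed relative
to"); (c) its carcass median FPKM is strictly below `carcass_fpkm_max`
(default 50). All thresholds are strict, so boundary cases (carcass median
exactly 50, rank n_top + 1, q exactly 0.05) are excluded. The filter accepts
any precomputed differential-expression table, so the built-in tester can be
swapped for another.

`cumulative_concentration` reports the minimal number of genes whose summed
expression reaches a given fraction of the total (largest first, ties broken
toward larger values then gene id); it is monotone in the fraction.

## Negative-binomial Wald test

A transparent two-group test on raw counts, standing in for shrinkage-based
NB GLM frameworks whose empirical-Bayes machinery is out of scope here:

1. **Normalisation** by median-of-ratios size factors (geometric-mean
   reference over genes positive in every sample; total-count fallback),
   factors normalised to geometric mean 1.
2. **Dispersion** per gene by method of moments, `alpha = (s² − m)/m²`
   estimated within each group, pooled with (n−1) weights, floored at 1e-8.
3. **Wald statistic** on the log2 fold change of group means (pseudocount
   0.5 normalised counts keeps it finite when one group is unobserved), with
   a delta-method standard error from the variance function `m + alpha m²`.
4. **Reference distribution**: t with `n_a + n_b − 2` degrees of freedom
   rather than a normal. With three replicates per group and moment
   dispersions the statistic is t-like, and the t reference keeps the
   empirical type-I rate at the nominal 0.05 (a normal reference inflates
   it). Genes with all-zero counts in both groups are excluded and reported.
5. **Multiplicity** by Benjamini–Hochberg over all tested genes
   (`bh_adjust`, delegating to statsmodels' step-up implementation).

Measured on the package's own null generator (5000 genes, 3 vs 3, NB mean
100, dispersion 0.1) the type-I rate is ≈ 0.044; power for 8-fold changes at
mean 200, dispersion 0.05 is ≈ 0.99 at q < 0.05. These are recomputed by
`scripts/acceptance.py`, not quoted from anywhere.

This tester does not implement dispersion shrinkage, fold-change moderation,
outlier handling, or GLMs with covariates; its fold changes will not match a
shrinkage estimator's on real data.

## Contamination screen

Contigs are split into consecutive non-overlapping windows of `unit_size`
(default 1000 bp), with the final shorter remainder window kept and counted
as a full unit in the denominator (simplest consistent rule; a minimum unit
length is configurable for users who prefer to drop tiny tails). A unit is
*matched* when it has at least one hit with e-value ≤ `evalue_max` (default
1e-5) in the supplied 12-column tabular hit file — identity and coverage are
not further filtered, matching a search-time-only e-value filter. A contig
is flagged when its matched-unit fraction is **strictly greater** than
`fraction_threshold` (default 0.40), so exactly-40% contigs survive.
Flagging is monotone under added hits, and cleaned plus flagged lengths
always conserve the input assembly length. Running the similarity search
itself is out of scope; the screen consumes its tabular output.

## Pagel-lambda phylogeny-corrected correlation

Under Brownian motion, tip trait covariance is proportional to the tree
variance-covariance matrix C (shared root-to-MRCA path lengths; diagonal =
root-to-tip depths). Pagel's lambda multiplies the **off-diagonal** of C,
leaving the diagonal unchanged: lambda = 0 removes phylogenetic covariance,
lambda = 1 is full Brownian structure.

* `fit_lambda_ml` maximises the multivariate-normal likelihood of the
  residuals of a GLS regression y ~ x under sigma²·C(lambda) over
  lambda ∈ [0, 1] (caper-style regression formulation, profiling out the
  coefficients and sigma²), using bounded Brent search with tolerance 1e-6.
  A scalar profile needs no multi-start. When the profile varies by < 1e-8
  across [0, 1] (e.g. a star tree, where off-diagonals are zero and the
  likelihood cannot depend on lambda) the fit is reported as
  `flat_likelihood` with lambda 0.
* `phylo_pearson` computes the GLS-corrected correlation under C(lambda)
  with GLS means: r = x̃ᵀ Σ⁻¹ ỹ / sqrt(x̃ᵀ Σ⁻¹ x̃ · ỹᵀ Σ⁻¹ ỹ), where x̃, ỹ are
  centred at their GLS means. At lambda = 1 this equals the correlation of
  Felsenstein's independent contrasts through the origin (verified against
  an independent pruning implementation to 1e-8); on a star tree, or at
  lambda = 0 on an ultrametric tree, it equals ordinary Pearson. On a
  non-ultrametric tree, lambda = 0 leaves unequal tip variances (the
  diagonal of C), so the "ordinary Pearson" reduction is exact only for
  ultrametric trees — every tree the generator produces is ultrametric.
* `correlation_stats` reports r², adjusted r² = 1 − (1 − r²)(n − 1)/(n − 2),
  and a two-sided p from t = r·sqrt((n − 2)/(1 − r²)) with n − 2 df. A
  perfect correlation reports the smallest positive double rather than 0.
* The two-stage reporting logic mirrors comparative practice: both ordinary
  and corrected results are always computed; the headline is the
  lambda-corrected one when the fitted lambda exceeds 0.01 and the profile
  is informative, otherwise ordinary Pearson.

Numerical choices: covariance solves use Cholesky factorisation; matrices
with condition number above 1e12 are rejected as singular rather than
regularised.

## TE divergence landscapes and genome arithmetic

Observed mismatch proportions p (to the family consensus) are converted to
Jukes-Cantor distances d = −(3/4)·ln(1 − (4/3)·p), defined for p < 0.75;
d ≥ p with equality only at p = 0, and d ≈ p + (2/3)p² for small p.
Distances are expressed in percent and pooled into left-closed right-open
bins of `bin_width` (default 1 percent unit), summing the genomic span (bp)
of each copy per TE class; binned bp totals always equal the input spans.
Divergences are proportions internally and percent only at I/O. Kimura
2-parameter and CpG-adjusted corrections are out of scope.

`genome_stats` computes component percentages, average chromosome length and
assembly size ratios, rounding **half-up to one decimal at the reporting
layer only** (e.g. a 636.5 Mb assembly with 256.3 Mb of DNA transposons and
4 chromosomes reports 40.3%, 159.1 Mb, and 1.9× a 338 Mb assembly).

## Synthetic-data generators

All generators are deterministic given `SimulationConfig.seed` and return
ground-truth labels, so every screen is testable end to end without
external data.

* **Trees**: pure-birth (Yule) trees, simulated directly (waiting times
  Exp(k) with k extant lineages, uniform lineage choice) with an Exp(n)
  hanging time after the last split so terminal branches are strictly
  positive and the Brownian covariance stays non-singular; rescaled to unit
  depth. Pure birth rather than birth-death: simpler, and sufficient to
  induce phylogenetic covariance. Default 13 tips, the size of a typical
  multi-species comparative panel.
* **Traits**: x = L·u, y = rho·x + sqrt(1 − rho²)·L·z with L the Cholesky
  factor of C(lambda_true) and u, z independent standard normals, so
  rho = ±1 yields an exactly affine relation and lambda_true is the ground
  truth for recovery checks.
* **Gene trees**: clones of the species tree scaled by lognormal(0, 0.5)
  per-gene rate multipliers (the standard rate-heterogeneity choice; no
  gene-specific model is prescribed by the screen itself); a planted 10% of
  genes have the focal terminal branch further multiplied by 5. Coalescent
  discordance is deliberately not simulated — the screen consumes branch
  lengths, not topologies.
* **Expression**: per-gene baseline expression lognormal with sd
  `gene_mean_sigma` (default 1.0; 0 gives identical means); expected counts
  proportional to gene length × expression (so FPKM-like values, computed
  with simulated lengths uniform in [300, 10000] nt, reflect expression with
  length cancelled, as in real RNA-seq); per-sample library factors uniform
  in [0.7, 1.3]; gamma-Poisson (NB) counts with dispersion `nb_dispersion`
  (default 0.1). Spiked genes emulate tissue-restricted venom genes: their
  off-tissue baseline is lognormal around the median expression scale with
  sd `spike_base_sigma` = 0.5 — a gene that is a top expresser in the
  contrast tissue is by definition not tissue-restricted, and observed venom
  genes sit at a few FPKM in the carcass against thousands in the gland —
  and their in-tissue mean is `spike_fold` (default 50) times that baseline,
  in the spike group only. The default design is two groups (venom_gland,
  carcass) × 3 replicates. The generator does not reproduce any real FPKM
  distribution, transcript-level ambiguity, batch structure, or count
  outliers; passing tests show the screens behave correctly under their
  assumed statistical structure, not that they reproduce the study's gene
  lists.
* **Assembly**: contigs with lengths uniform in [2, 200] kb and uniform
  random sequence; contaminant contigs (default 10%) receive qualifying
  hits on a unit fraction drawn from [0.55, 0.95] (forced strictly above the
  40% rule), clean contigs from [0, 0.30], plus occasional decoy hits above
  the e-value cutoff that must not count. The generator intentionally avoids
  the exact 40% boundary so label recovery is exact; boundary behaviour is
  tested separately with hand-built contigs.

## Problem sizes used in the checks

The acceptance computations use the scales the screens are specified at:
2992 genes for the binning arithmetic; 500 gene trees × 20 seeds for planted
recovery; 100-tip trees × 100 replicates per lambda setting; 5000-gene null
and 2000-gene power matrices × 10 seeds; 12000-gene transcriptomes × 20
seeds for the VGG filter; 40-contig assemblies × 10 seeds. The full run
completes in well under a minute per stage on one CPU.

## Known limitations

* The NB tester is intentionally simple; it is calibrated under its own
  generator, not validated against shrinkage GLM implementations.
* Lambda is fitted on residuals of y ~ x; a joint bivariate fit could differ
  when x itself carries strong phylogenetic signal.
* The published biological counts (154 VGGs, 183 positively selected genes,
  the real repeat landscapes and trait correlations) depend on the original
  sequencing data and external inference tools, and are not reproduced here;
  this package implements the screens themselves.
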