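# Methods

`m6apattern` implements a complete m6A-modification-pattern analysis for
bulk expression cohorts: consensus non-negative matrix factorization (NMF)
subtyping of the 23-gene m6A regulator block, single-sample immune/stromal
enrichment scoring, a phenotype gene signature distilled into a per-sample
prognostic score (the m6Sig score) with a survival-derived cutpoint, and
MAF-based mutation summaries. This note documents the models, the defaults
and why they were chosen, and what the synthetic cohorts do and do not
emulate.

## Regulator catalog

The shipped catalog contains the 23 curated m6A regulators: 8 writers
(CBLL1, KIAA1429, METTL14, METTL3, RBM15, RBM15B, WTAP, ZC3H13), 2 erasers
(ALKBH5, FTO) and 13 readers (ELAVL1, FMR1, HNRNPA2B1, HNRNPC, IGF2BP1/2/3,
LRPPRC, YTHDC1/2, YTHDF1/2/3). Symbols are matched case-sensitively; no
alias resolution is attempted.

## Preprocessing

* **FPKM → TPM**: per sample, `TPM_g = FPKM_g / Σ_g FPKM_g × 1e6`. FPKM is
  already length-normalized, so no gene lengths enter; every column sums to
  1e6 exactly.
* **Quantile normalization**: the reference distribution is the row-wise
  mean of the per-sample sorted vectors; ties within a sample receive the
  mean of the reference values their positions span. Within-sample rank
  order is preserved.
* **Batch adjustment** is parametric empirical-Bayes ComBat (Johnson, Li &
  Rabinovic 2007) without covariate terms: per-gene standardization against
  the batch-size-weighted grand mean and the pooled within-batch variance,
  normal shrinkage of batch locations, inverse-gamma shrinkage of batch
  scales (moment-matched hyperpriors), iterative joint solution, then
  removal. Linear-scale input is log2(x+1)-transformed first. Zero-variance
  genes pass through unadjusted with a warning. Note that EB shrinkage
  removes only the shrunk fraction of each gene's batch deviation, so the
  operator is contractive rather than exactly idempotent: a second
  application moves values an order of magnitude less than the first. The
  implementation is verified against `sva::ComBat` (R) to 5e-3 in the test
  suite.

## Consensus NMF subtyping

The regulator × sample submatrix is min-max scaled per gene to [0, 1]. This
choice (over z-scoring or raw expression) both enforces the non-negativity
the KL factorization requires on log-scale data and gives every regulator
equal leverage; it is a package decision, as is everything else in this
paragraph marked "default".

`nmf_factorize` uses the multiplicative KL-divergence updates of Brunet et
al. (2004) with W, H initialized Uniform(0, 1) and rescaled to the data
mean; the objective D(A‖WH) is non-increasing under the updates and
iteration stops when its relative change over a 10-iteration window falls
below `tol` (default 1e-5 standalone, 1e-4 inside consensus runs, where
many restarts are aggregated and individual-run precision matters less).

`consensus_cluster` repeats the factorization `nruns` times (default 200,
matching standard practice; the bundled experiments use 20–50 for speed)
with one RNG substream per run, assigns each sample to its dominant
metagene, and averages co-assignment indicators into a consensus matrix.
Hard labels come from average-linkage hierarchical clustering of
1 − consensus cut at k. Diagnostics per rank: the cophenetic correlation
between the dendrogram and 1 − consensus, the dispersion
mean(4(C − ½)²), and the mean silhouette on 1 − consensus. Random restarts
occasionally land in block-merging local minima — that is precisely what
the consensus aggregation absorbs.

`select_rank` min-max rescales each diagnostic across the tested ranks
(a constant metric contributes ½ everywhere), averages them, and returns
the arg-max with ties broken toward the smaller rank. The combination rule
is a package decision; the three diagnostics themselves are the standard
rank-selection trio.

## Single-sample enrichment and TME scores

`ssgsea_scores` is the rank-weighted ECDF statistic of Barbie et al.
(2009): per sample, genes are ranked by expression (average ranks on
ties); the enrichment score is the sum over all rank positions of the
weighted in-set ECDF (weights rank^α, default α = 0.25) minus the
unweighted out-of-set ECDF. Scores depend on ranks only and are therefore
invariant to any strictly monotone per-sample transform. Optional per-set
min-max normalization maps scores to [0, 1] across samples. Immune-cell
panel composition is a user input (GMT); the package ships only a
synthetic illustrative panel set inside the cohort generator.

`estimate_scores` computes immune and stromal scores as raw enrichment
scores of the two user-supplied gene sets and converts their sum to tumor
purity with the published calibration
`purity = cos(0.6049872018 + 0.0001467884 × combined)`, clipped into
(0, 1]. The constants are imported conventions from the original ESTIMATE
publication, not re-derived here.

`ips_score` z-scores each gene across samples (zero-variance genes
contribute 0 with a warning), averages member-gene Z within each panel,
combines panels within the four classes (MHC, EC, CP, SC; per-panel
weights from GMT metadata, default 1), and sums class averages with class
weights, default +1 for MHC/EC and −1 for CP/SC (user-overridable, since
published weight tables vary). Missing panel genes are dropped, not
imputed.

`ora_test` is the one-sided hypergeometric upper-tail test with BH
adjustment across sets.

## Phenotype signature and the m6Sig score

Differential expression uses the moderated t of Smyth (2004): per-gene
two-group fits, residual variances shrunk toward an empirical-Bayes prior
`s̃² = (d0·s0² + d·s²)/(d0 + d)` with (d0, s0²) estimated by moment
matching on log-variances (trigamma inversion), p-values on d0 + d degrees
of freedom, BH adjustment. The phenotype signature is the intersection of
the per-cluster one-vs-rest DEG lists at adjusted p < 0.001. One-vs-rest
(rather than all pairwise contrasts) is a package decision; with balanced
groups the three one-vs-rest effects of any gene sum to zero, so genuinely
pan-differential genes are those with one strong and two opposite moderate
contrasts.

Signature genes are screened by univariate Cox regression (Efron ties;
keep p < 0.05 — the screening threshold is a package default), then
reduced by recursive feature elimination: a random forest ranks gene
importance, the gene set shrinks down a halving subset-size grid, each
size's accuracy is estimated by stratified 10-fold cross-validation
against the *cluster labels* (the signature is phenotype-representative,
so the forest predicts the m6A pattern — a deliberate design decision),
and the final size is the smallest within one standard error of the best.

`m6sig_score` z-scores the selected genes, performs a PCA across samples,
and defines the score of sample i as `PC1_i + PC2_i`. Component signs are
arbitrary in PCA, so each component is oriented to have non-negative Cox
log-HR against training survival: a higher m6Sig score means worse
expected outcome. A component with (near-)zero singular value contributes
0 to every score; if all samples are identical, all scores are 0. The
fitted model (gene means/SDs, loadings, cutpoint) can be saved as JSON and
applied unchanged to a new cohort.

`optimal_cutpoint` scans the distinct score values whose split leaves at
least `minprop = 0.1` of the cohort on each side, computes the
standardized two-group log-rank statistic at each, and returns the
maximizer (ties toward the lower value). Because the cutpoint maximizes
in-sample separation, the log-rank p at the selected cutpoint is biased;
the test suite verifies that under a true null the selected split is not
prognostic on fresh replicate data.

## Survival machinery

Kaplan–Meier curves carry Greenwood variances; the k-group log-rank test
and all Cox fits (Efron tie handling, Wald 95% CIs, likelihood-ratio
statistic) are delegated to lifelines. Perfectly separated fits are
flagged and coefficients capped at |10|. Time-dependent AUC is the
cumulative/dynamic definition with inverse-probability-of-censoring
weights from the censoring Kaplan–Meier estimator (scikit-survival). Time
is treated as months throughout, carried as metadata only.

## Mutation summaries

Tumor mutation load counts variants classified frameshift, in-frame indel,
missense, nonsense or splice-site ("in-frame" interprets an evident typo
in the source vocabulary; the mapping is configurable). Group-wise
mutation-rate comparisons build per-gene 2×2 tables over *all* cohort
samples (absent-from-MAF samples count as wild-type) and use the two-sided
Fisher exact test with BH adjustment. Mutational signatures are extracted
by the same KL-NMF engine from the samples × 96 trinucleotide-context
matrix (COSMIC context ordering); profiles are row-normalized with
exposures rescaled to compensate, and annotation against user-supplied
reference profiles is by cosine similarity. Plain KL-NMF is used rather
than a Bayesian variant; the signature count k is user-chosen or selected
with the same rescaled-diagnostic rule as the subtyping rank.

## Synthetic cohorts: what they emulate, and what they do not

`generate_cohort` draws Gaussian log2-scale expression (microarray-like;
baseline mean 8, SD 1) for a gene universe of the 23 regulators, planted
signature genes, immune-panel genes and background genes. Defaults:

* 3 patterns × 60 samples — a desk-scale stand-in for the ~1300-sample
  multi-cohort structure the method targets;
* regulator programs: each pattern elevates its own third of the catalog
  by 2.0 SD;
* 50 signature genes, each up-shifted by 3.0 SD in exactly one pattern
  (round-robin). With balanced patterns the weakest one-vs-rest contrast
  of such a gene is half the shift (1.5 SD) — the geometry forces this —
  so the default emulates strong subtype markers that survive an adjusted
  p < 0.001 screen;
* 4 disjoint 8-gene immune panels shifted per pattern (pattern 0
  immune-hot, pattern 2 immune-cold);
* survival: exponential with baseline hazard 0.02/month and per-pattern
  log-hazards (−0.5, 0, +0.5), independent Uniform(0, c) censoring with c
  calibrated by bisection to a 30% target censoring fraction — closed-form
  ground truth for recovery tests;
* optional per-batch location/scale effects applied last.

One seed derives all substreams, so a cohort is bit-reproducible. The
generator does **not** emulate gene–gene correlation beyond the planted
programs, heavy-tailed or count-distributed expression, non-proportional
hazards, informative censoring, or copy-number structure; passing tests
demonstrate correctness of the machinery under the planted model, not
performance on real cohorts.

`generate_maf` has two independent layers: per-gene Bernoulli driver
mutations with group-specific rates, and Poisson passenger mutations with
a configurable nonsynonymous fraction; every record draws a trinucleotide
context from the sample's exposure mixture over planted 96-profiles, so
context counts are multinomial in the mixture.

## Numerical and degenerate-input choices

* NMF: `eps = 1e-12` guards all denominators; inputs with all-zero rows
  are rejected (the signature extractor drops never-observed contexts and
  reinserts zeros afterwards).
* Rank selection rounds the combined diagnostic to 12 decimals before the
  arg-max so floating-point dust cannot defeat the smaller-k tie rule.
* Fisher exact p-values are discrete and conservative; calibration checks
  therefore use the randomized (CDF-uniformized) p-value
  (`genomics.fisher_randomized_p`), which is exactly Uniform(0, 1) under
  the null. It exists for calibration experiments only, never for
  inference.
* Expression files are written with shortest-round-trip float formatting
  and parsed with correctly-rounded conversion, so write → read is
  bit-exact.

## Problem sizes in the bundled experiments

The test suite and the acceptance script run the full pipeline at
3 × 60 samples with ~400 genes, 20–50 NMF restarts per rank, 10–20
generator seeds, and 200 replicates for calibration checks — sizes chosen
so the planted effects are comfortably identifiable while the whole
analysis remains quick on a laptop.
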