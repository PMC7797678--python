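# m6apattern

N6-methyladenosine (m6A) is the most common internal mRNA modification,
deposited, removed and read by a small set of regulator proteins (writers,
erasers, readers). In bulk tumor cohorts, the joint expression of these
regulators stratifies patients into *m6A modification patterns* that differ
in immune microenvironment and outcome. `m6apattern` is a tested,
reusable implementation of that analysis for expression cohorts with
survival data:

1. **Consensus NMF subtyping** — the 23-regulator × sample block is
   factorized `A ≈ WH` by multiplicative KL-divergence NMF (Brunet
   updates); repeated random restarts are aggregated into a consensus
   matrix, and the cluster number k is chosen from cophenetic, dispersion
   and silhouette diagnostics.
2. **Tumor-microenvironment scoring** — single-sample gene-set enrichment
   (ssGSEA, rank-weighted ECDF with weight rank^0.25), ESTIMATE-style
   immune/stromal scores with the published purity calibration
   `purity = cos(0.6049872018 + 0.0001467884·(immune+stromal))`, an
   immunophenoscore-style weighted Z-score composite, and hypergeometric
   over-representation tests.
3. **The m6Sig score** — genes differential in *every* one-vs-rest cluster
   contrast (moderated-t, BH-adjusted p < 0.001) are screened by
   univariate Cox regression, reduced by random-forest recursive feature
   elimination, and summarized per sample as
   `m6Sig_i = PC1_i + PC2_i` from a PCA of the selected genes (oriented so
   higher = worse outcome); a maximally selected log-rank cutpoint splits
   the cohort into high/low score groups.
4. **Mutation summaries** — tumor mutation load, group-wise Fisher exact
   mutation-rate comparisons, and 96-trinucleotide-context mutational
   signature extraction by the same KL-NMF engine with cosine annotation
   against reference profiles.
5. **A synthetic-cohort generator** plants regulator programs, immune
   panels, pan-differential signature genes and pattern-linked exponential
   survival with known ground truth, so the full pipeline is exercisable
   and testable without any download.

All inputs are plain text: TSV expression/clinical tables, GMT gene sets,
MAF mutation tables. See `docs/methods.md` for the models, defaults and
their rationale.

## Worked example

```python
import numpy as np
from m6apattern import CohortSimulationParams, generate_cohort, run_m6sig_pipeline

params = CohortSimulationParams(seed=7)          # 3 planted patterns, 60 samples each
cohort = generate_cohort(params)

result = run_m6sig_pipeline(cohort.expression, cohort.clinical,
                            k=3, nruns=20, seed=0)

print(f"cluster sizes:      {result.cluster_labels.value_counts().sort_index().tolist()}")
print(f"signature genes:    {len(result.signature_genes)}")
print(f"prognostic (Cox):   {int(result.screened['keep'].sum())}")
print(f"RFE-selected:       {len(result.selected_genes)}")
print(f"m6Sig cutpoint:     {result.cutpoint.cutpoint:.4f}")
print(f"high/low log-rank p: {result.km.p:.2e}")
means = cohort.true_log_hazard.groupby(result.cutpoint.groups).mean()
print(f"true log-hazard, high group: {means['high']:+.3f}")
print(f"true log-hazard, low group:  {means['low']:+.3f}")
```

Output:

```
cluster sizes:      [60, 60, 60]
signature genes:    70
prognostic (Cox):   33
RFE-selected:       8
m6Sig cutpoint:     0.5126
high/low log-rank p: 5.21e-07
true log-hazard, high group: +0.225
true log-hazard, low group:  -0.345
```

The consensus clustering recovers the three planted patterns exactly; the
phenotype signature contains the 50 planted pan-differential genes (plus
regulators/immune genes, which are pattern-differential by construction);
and the m6Sig high-score group is precisely the group simulated with the
higher hazard — low score, better outcome.

The same stages are scriptable from the shell:

```bash
m6apattern simulate --seed 7 --out cohort/
m6apattern subtype --expr cohort/expression.tsv --kmin 2 --kmax 6 --nruns 200 --seed 7
m6apattern signature --expr cohort/expression.tsv --clinical cohort/clinical.tsv --seed 7
```

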