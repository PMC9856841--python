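# sigsurv

Gene-signature module scoring and survival stratification for two-arm
expression studies.

`sigsurv` is for computational biologists who derive a prognostic gene
signature from a small controlled experiment (e.g. a 3-vs-3
control-vs-overexpression xenograft RNA-seq design) and want to test it on
independent patient cohorts with survival follow-up. It covers the full
chain:

1. **Differential expression** — per-gene two-sided Student *t*-tests
   (pooled variance) on log2 expression, fold changes, volcano tables, and
   PCA quality control.
2. **Signature construction** — a filter keeping genes with
   (*p* < 0.05 and fold change beyond 2×) or fold change beyond 4×
   regardless of *p*, then four signature variants: all genes with signed
   weights (`Sig`), all genes unsigned (`NoDir`), up-regulated only (`Up`),
   down-regulated only (`Dn`).
3. **Module scoring** — for a signature with weights *Wᵢ* ∈ {+1, −1} and
   log2 expression *Xᵢ*, the per-sample score

   *s* = Σᵢ *Wᵢ Xᵢ* / Σᵢ |*Wᵢ*|,

   rescaled per cohort so the empirical 2.5% / 97.5% quantiles map to
   −1 / +1.
4. **Survival stratification** — optimal cutpoints by maximally selected
   rank statistics (the maximum standardized log-rank statistic over all
   admissible splits, with a Miller–Siegmund-adjusted or
   permutation-adjusted *p*), median cutoffs, Kaplan–Meier curves, and
   univariate Cox hazard ratios with Wald tests.
5. **Multi-cohort reporting** — forest tables of HRs across cohorts and
   Wilcoxon rank-sum comparisons of score distributions between race
   groups.

Synthetic-data generators (a planted-effect two-arm experiment and a
cohort whose hazard is log-linear in the true signature score) make every
stage testable without any external download.

## Worked example

```python
import numpy as np
import pandas as pd
from sigsurv import datagen, diffexpr, signature as sg, cohorts

# two-arm experiment: 5000 genes, 10% carrying a planted shift
cfg = datagen.XenoSimConfig(n_genes=5000, n_per_arm=3, frac_de=0.1,
                            log2fc_effect=2.0, noise_sd=0.5, seed=1)
matrix, truth = datagen.simulate_xenograft(cfg)
groups = pd.Series([s.split("_")[0] for s in matrix.samples],
                   index=matrix.samples)

de = diffexpr.ttest_per_gene(matrix, groups)        # 611 genes at p < 0.05
filtered = diffexpr.filter_signature_genes(de)      # 406 genes kept
sigs = sg.build_signatures(filtered)                # 178 up, 228 down

# an independent cohort in which a high true score halves the hazard
ccfg = datagen.CohortSimConfig(n_patients=300, signature_truth=sigs["Sig"],
                               beta=np.log(0.5), seed=2)
expr, clinical = datagen.simulate_cohort(ccfg)
results = cohorts.evaluate_signature_on_cohort(expr, clinical,
                                               {"Sig": sigs["Sig"]}, seed=3)
for r in results:
    print(r.cutoff_method, f"HR={r.hr:.3f}",
          f"CI=({r.ci95[0]:.3f}, {r.ci95[1]:.3f})", f"p={r.wald_p:.2e}")
```

Output:

```
optimal HR=0.291 CI=(0.196, 0.432) p=9.29e-10
median HR=0.444 CI=(0.332, 0.595) p=5.06e-08
```

Both stratifications recover the protective direction (HR < 1): patients
with a high signature score fare better, and the optimal cutoff separates
the groups more sharply than the median — at the cost of a selection
optimism that the adjusted cutpoint *p*-value corrects for.

The same chain is available from the shell:

```bash
sigsurv simulate xeno --config xeno.yaml --out-dir sim/
sigsurv de --expr sim/expression.tsv --groups sim/groups.tsv --out de.tsv
sigsurv build-sig --de de.tsv --out signatures.csv
sigsurv score --expr cohort_expr.tsv --sig signatures.csv --out scores.tsv
sigsurv survfit --scores scores.tsv --clinical clinical.tsv --cutoff both --out fit/
sigsurv cohort-report --cohorts manifest.yaml --sig signatures.csv --out report/
```

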