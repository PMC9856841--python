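# Methods

## The model

The package operationalizes a common translational workflow: a gene
signature is derived from a small two-arm experiment and carried to
independent patient cohorts, where a per-patient score stratifies survival.

**Differential expression.** Input matrices are assumed already
log2-normalized; the package performs no count normalization. Each gene is
tested with a two-sided Student *t*-test with pooled variance between the
two arms (Welch is available via `equal_var=False`, but pooled is the
default because it is the classical two-sample test for a 3-vs-3 design
with a shared noise model). The log2 fold change is the difference of
group means on the log2 scale, with group B the treatment/overexpression
arm; `fc_linear = 2**log2fc`. Genes constant in both groups have an
undefined statistic and are assigned *p* = 1 with a warning. No
multiple-testing correction enters the downstream filter — the filter is
deliberately liberal at the per-gene stage because the signature is
validated as a whole on independent data; a Benjamini–Hochberg `q_value`
column is emitted for reference only.

**Signature filter.** A gene is shortlisted when (*p* < 0.05 and its fold
change is beyond 2× in either direction, i.e. `fc_linear >= 2` or
`<= 1/2`) or when its fold change is beyond 4× in either direction
regardless of *p* (a rescue branch for large effects that miss nominal
significance at n = 3 per arm). The *p* comparison is strict; the
fold-change comparison is inclusive. Thresholds are parameters.

**Module score.** For a signature with unit weights *Wᵢ* ∈ {+1, −1}:

    s = sum_i(W_i * X_i) / sum_i(|W_i|)

The denominator is the total weight magnitude, not the signed sum: a
signed-sum denominator is zero whenever up- and down-weighted genes are
equally many and flips sign when down-weighted genes dominate, so it
cannot serve as a normalizer for mixed-direction signatures. With all
weights +1 the score reduces to the mean of member-gene expression.
Signature members are matched to matrix rows by Entrez ID when both sides
carry one, falling back to gene symbol; unmatched members are dropped and
counted, with a warning below 50% coverage. Duplicate matrix rows are
collapsed by mean before scoring.

**Quantile rescaling.** Raw scores are mapped affinely so the cohort's
empirical 2.5% and 97.5% quantiles land on −1 and +1:

    s' = 2 * (s - q_low) / (q_high - q_low) - 1

Quantiles use the linear-interpolation convention (Hyndman–Fan type 7, the
numpy default); the anchors are configurable. Scores beyond ±1 are kept
unclipped — the contract fixes two quantiles, nothing else. Rescaling is
monotone, so every rank-based downstream quantity (cutpoint partitions,
rank-sum tests) is identical on raw and scaled scores; the scaled score
only fixes the scale on which per-unit hazard effects are expressed.

**Optimal cutpoint.** For each candidate cutpoint μ among the distinct
score values whose split (low: score ≤ μ) leaves at least a fraction
ε = 0.1 of subjects on each side, the package computes the standardized
two-group log-rank statistic

    Z(mu) = (O_low - E_low) / sqrt(V_low)

with the observed/expected event counts and hypergeometric variance
tabulated over distinct event times, and selects the μ maximizing |Z|
(smallest μ on ties). ε = 0.1 is the conventional admissibility
restriction for maximally selected statistics and is configurable. Because
max |Z| over many correlated splits is strongly anti-conservative (the
acceptance run measures ≈ 0.41 type-I error at nominal 0.05 for the
unadjusted minimum *p*), the reported *p* is adjusted by either

* the Miller–Siegmund improved Bonferroni bound for the maximum of the
  standardized process over the quantile interval (ε, 1 − ε):
  `p ≈ 4φ(b)/b + φ(b)(b − 1/b) log[(1−ε)²/ε²]`, clamped to
  [*p*-unadjusted, 1]; this is the fast default, or
* a seeded permutation null that re-runs the full maximization on
  score-permuted data (`(1 + #exceedances) / (1 + n_perm)`), the
  verification path.

The scan is vectorized: per-subject at-risk indicator rows over distinct
event times are precomputed once, so every split (and every permutation
re-run) is a cumulative sum — this is what makes 500-replicate calibration
runs affordable.

**Cox hazard ratio.** The high-vs-low contrast is a univariate Cox
proportional-hazards fit solved by Newton–Raphson on the partial
likelihood, Breslow tie handling by default (Efron optional; the two
coincide on tie-free simulated times). HR = exp(β̂), 95% CI =
exp(β̂ ± 1.96·SE), Wald *p* from β̂/SE against the standard normal. A
monotone partial likelihood (complete separation) is detected when the
iteration escapes |β| > 15; the coefficient is capped there with a
warning rather than diverging. Non-convergence within 50 iterations is an
error. The fit is cross-checked against lifelines in the test suite;
Kaplan–Meier curves come from lifelines directly.

**Race comparison.** Score distributions between two groups are compared
with a two-sided Wilcoxon rank-sum test (robust to the score
distribution's shape; Welch's *t* available), with per-group medians and
IQRs reported for box plots.

## Synthetic data

`simulate_xenograft` emulates a small two-arm bulk expression experiment
directly on the log2 scale: per-gene baselines ~ N(8, 1.5²), i.i.d.
Gaussian noise (SD 0.5 by default) per gene and sample, and a planted mean
shift in the treatment arm for exactly `round(n_genes × frac_de)` genes,
with gamma-distributed |log2FC| magnitudes (shape 4, mean
`log2fc_effect` = 2 by default — large effects, as expected of a strong
overexpression construct) and a configurable up/down split. Defaults are
3 samples per arm and 10% of genes shifted. Simulating on the log2 scale
keeps the *t*-test's Gaussian assumption explicit; the generator does not
model library-size effects, count overdispersion, batch structure, or
gene–gene correlation beyond the planted shifts, so passing tests certify
the statistics pipeline, not robustness to those real-data artifacts.

`simulate_cohort` emulates a patient cohort (n ≥ 20; defaults n = 300) in
which a standard-normal latent factor *uᵢ* moves every signature gene
along its weight direction (Xᵢg = μg + Wg·uᵢ + noise, noise SD 0.5), so
the true module score tracks *uᵢ* almost perfectly. The true score is
quantile-rescaled within the cohort and drives an exponential event time
with rate `baseline_hazard × exp(beta × scaled_score)` (defaults 0.1 per
unit time, β = 0); censoring is an independent exponential clock (default
rate 0.05, ≈ 2/3 of subjects observed to an event). Race labels are drawn
i.i.d. (default 70/30), and `race_score_shift` adds `shift × Wg` to the
signature genes of the shifted group (default: the last label), moving
that group's module score by exactly the stated amount — an additive shift
ignoring weight direction would cancel in mixed-weight signatures, whose
mean weight is near zero. A single latent factor is the simplest structure
consistent with a proportional-hazards score effect; it does not emulate
pathway-level correlation among non-signature genes.

## Verification experiments

The acceptance script (`scripts/acceptance.py`) measures, at the stated
problem sizes:

* **Scaling contract** — rescaled 2.5%/97.5% quantiles on a 1000-sample
  score vector (exactly −1/+1 by construction; asserted to 1e−9).
* **Cutpoint-search correctness** — agreement of the vectorized scan with
  brute-force enumeration of every admissible split on 50 random cohorts
  of n ≤ 30 (exact cutpoint, statistic to 1e−9).
* **Null calibration** — 500 replicate cohorts (n = 150, β = 0), 199
  permutations each: rejection rate of the permutation-adjusted *p* at
  0.05 (within the binomial band 0.05 ± 0.029) against the unadjusted
  minimum-*p* rate (≈ 0.41, demonstrating the selection bias). 199
  permutations give an exact test with achievable level 9/200 = 0.045.
* **HR recovery** — 200 two-arm cohorts (n = 300) with true HR 0.5: mean
  estimate and 95% CI coverage.
* **End-to-end direction** — 30 replicate cohorts (n = 300, β = log 0.5):
  mean HR and detection rate (HR < 1, Wald *p* < 0.05) under both cutoffs;
  a single cohort's HR varies enough (5–95% range ≈ 0.48–0.70 at the
  median cutoff) that a replicate mean is the honest summary.
* **Null-signature control** — 100 cohorts scored with the same weight
  multiset placed on background genes: 95% CI covers HR = 1 at ≈ 95%.
  Note that literally permuting the weights *within* the signature is not
  a null under this generator: with unit weights and one shared latent
  factor the permuted-weight score retains a random alignment
  Σ Wperm·W/n with the truth (SD ≈ 0.3 for a 20-gene signature), and its
  measured CI coverage is far below nominal. The background-gene scramble
  is the genuine negative control.
* **Filter logic** — the hand-constructed 10-gene table covering every
  filter branch, plus the *t*-test's null false-positive rate on a 10,000
  gene, no-effect simulation.

## Numerical conventions and edge cases

* Ties at any cutpoint go to the low group (score ≤ μ is "low"),
  recorded in the survfit JSON metadata.
* The maxstat search requires ≥ 10 subjects, ≥ 2 distinct scores and
  ≥ 1 event; constant scores, empty admissible ranges, zero-variance
  rescaling inputs, and groups without events are validation errors, not
  silent degenerate output.
* Variance-zero splits inside the scan contribute Z = 0 rather than NaN.
* All stochastic steps (generators, permutation null) take explicit seeds;
  fixed seeds give bit-identical outputs.
* Time units are cohort-relative and never converted; HR and Wald *p* are
  invariant under time rescaling (asserted by test).

## Known limitations

* The Cox fit is univariate (the binary group indicator only); no
  covariate adjustment, time-dependent effects, or competing risks.
* The Miller–Siegmund adjustment is an asymptotic bound; at small n or
  very few events the permutation path is the reliable reference.
* Signatures carry unit weights only; continuous-weight scoring and
  enrichment-style scores (ssGSEA/GSVA) are out of scope.
* The generators' independence assumptions (genes, censoring) mean test
  results quantify correctness of the statistics, not performance on
  correlated real cohorts.
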