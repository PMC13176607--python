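# Methods

## Model and assumptions

`tapinto` targets inter-patient heterogeneity in bulk transcriptomes: a
candidate antigen is interesting when a *subgroup* of tumors overexpresses it,
even if the cohort mean barely moves. The method assumes

- a dense, non-negative, FPKM-normalized genes × samples matrix (no missing
  cells — silent imputation would corrupt the cumulative SD traces, so missing
  values are rejected at load time);
- tumor expression of real candidates is positively skewed / long-tailed, so
  an overexpressing subgroup sits in the upper tail of the sorted values;
- adjacent-normal samples are comparatively homogeneous and provide the
  specificity denominator `ȳ`.

The subgroup is found per gene, without using the normals: sort tumor values
descending, scan the sample SD of every prefix (`s = s_min … N`), and cut at
the prefix with maximal SD. Samples with expression greater than **or equal
to** the value at the cutoff position are subgroup members, so boundary ties
are absorbed and the member count can exceed the argmax position; both are
reported. Downstream, `Freq` uses the tie-extended member count — the member
set is what the detector exports, and a tie at the boundary is biologically
indistinguishable from the sample just inside it.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `s_min` | 3 | first prefix length scanned; the SD of fewer than two values is undefined and a two-sample SD is pure noise. Configurable. |
| `alpha` | 0.05 | significance gate on the BH-adjusted one-tailed Wilcoxon p; strict inequality (`p < alpha`). |
| `min_mean_fpkm` | 1.0 FPKM | noise floor for long-tail testing; genes with tumor mean **strictly below** the floor are dropped (a gene at exactly 1 FPKM is kept). |
| `gof_threshold` | 0.1 | a family is retained ("cannot reject") when the bootstrap GoF p is ≥ the threshold, inclusive at equality. |
| `n_boot` | 100 | bootstrap replicates per family; a desk-scale default giving p-value resolution of 0.01 — raise it for publication-grade tail probabilities. |
| index weights | 1,1,1 | the three factors are equally weighted; exposed for sensitivity analysis only. |

The Wilcoxon test compares the *subgroup members* against the adjacent
normals (alternative: greater). This is the comparison that matches the
claim the parameters are making — the subgroup, not the whole cohort, is
elevated — and is configurable to all-tumor-vs-normal
(`test_group="all_tumor"`). Note the caveat under *Limitations*.

## Numerical choices

- **Cumulative SD.** The trace is computed with a shifted cumulative-sum
  identity (values centered on the global mean first) — O(N) per gene and
  stable against the large offsets typical of FPKM. Constant prefixes are
  pinned to SD exactly 0: the cancellation residue of the cumulative identity
  would otherwise leave ~1e-7 ghosts that perturb tie-breaking.
- **Cutoff tie-break.** Ties at the trace maximum break to the smallest `s`
  (most conservative subgroup). Equality is judged at 1e-9 *relative*
  tolerance, because mathematically tied prefix SDs (common with rounded
  data) can differ in the last float bits depending on summation order.
- **Wilcoxon p.** Exact enumeration when the pooled groups hold ≤ 20 tie-free
  values, otherwise the normal approximation with tie and continuity
  correction (scipy's `mannwhitneyu`).
- **BH family.** All non-degenerate genes of the current run; NaN p-values
  (degenerate genes) pass through as NaN and do not count toward the family
  size.
- **Percentile bands.** Mean rank for ties, percentile = rank / n × 100;
  "top 25 %" is inclusive at exactly 75. A fully tied cohort sits at one
  shared percentile and never earns top-band points. At least 4 defined
  values are required per factor.
- **FC at `ȳ = 0`.** Undefined (NaN + flag), never 0 or ∞, and no
  pseudocount — a pseudocount silently reshuffles ranks. Flagged genes are
  excluded from FC percentile ranking and receive no index score (never a
  silent 0).
- **Degenerate genes.** Any zero-dispersion tumor vector (constant, including
  all-zero) is flagged: the argmax of an all-zero trace is meaningless. The
  cutoff is pinned at `s_min` for reporting and the gene is excluded from
  scoring.
- **Power-law fit.** Continuous Pareto tail; `xmin` by KS minimization over
  the unique values (capped at 60 quantile-spaced candidates, tail of at
  least 8 points), exponent by MLE `α = 1 + n/Σ log(x/xmin)`. Exponential
  (`rate = 1/mean`, full non-negative support) and log-normal (mean/SD of
  logs, positive support; zeros excluded with a recorded count) have no
  `xmin` search.
- **Bootstrap GoF.** Clauset-style: simulate from the fitted model
  (semi-parametric for the power law — empirical body below `xmin`,
  parametric tail above), refit each replicate including the `xmin` search,
  and report the fraction of replicates whose KS statistic is at least the
  observed one. Bit-reproducible under a fixed seed; per-gene and per-family
  seeds are spawned from the run seed so results do not depend on gene order.
- **AUC.** Mid-rank Mann–Whitney formula (ties count ½), which equals the
  trapezoidal ROC area; ROC point enumeration is delegated to scikit-learn.

## The synthetic generator

`simulate.SimConfig` defaults define the package's reference conditions: 200
tumors, 50 adjacent normals, 100 genes, 10 % of genes planted, subgroup
fraction 0.15, fold 20, multiplicative noise CV 0.2, log-normal(μ=3, σ=0.6)
background (FPKM-scale mean ≈ 24). Planted members are fresh background
draws × fold × unit-mean log-normal noise; the member count is exactly
`round(fraction × N)`; everything derives from one seed. The ~10 % normal-to-
tumor ratio mirrors typical bulk tumor/adjacent-normal cohorts, and 50
normals keep `ȳ` stable enough that fold-change noise is dominated by the
tumor side.

What the generator deliberately does **not** emulate: gene–gene correlation,
molecular subtypes, batch effects, library-size artifacts, or a continuum
between "member" and "background" samples. Passing tests on these fixtures
therefore demonstrate algorithmic correctness and the method's qualitative
advantages (subgroup FC ≫ population-mean FC for heterogeneous genes), not
clinical performance on real cohorts.

## Known limitations

- **The max-SD cutoff is inclusive-biased on two-component mixtures.** Adding
  a value at distance `d` below a prefix mean *increases* the prefix SD
  whenever `d² > SD²·(s+1)/s`. At a planted subgroup boundary with fold ≥ 10
  and member CV ≤ ~1, the first background sample always satisfies this, so
  the cutoff lands at or past the true boundary — typically drifting toward
  the mixture-variance peak near twice the subgroup size, or (for
  heavy-tailed subgroups) stopping early inside the subgroup's own tail.
  Under the reference conditions the detected subgroup size has median 38
  against a planted 30 (IQR 4–44 across seeds), and the recovered fold change
  is correspondingly attenuated. The frequency estimate should be read as
  "at least this prevalent, roughly", not a sharp boundary estimate; the
  acceptance suite measures this bias explicitly and one recovery check is
  expected to fail at sharp (±2 samples / 95 %) tolerances, by design left
  failing rather than weakened.
- **Selection inflates the subgroup test.** The Wilcoxon p compares a
  subgroup *selected for being high* against the normals; under a global
  null this is anti-conservative. The test suite verifies calibration on
  randomly chosen subgroups and measures (without asserting) the inflation
  under max-SD selection. Interpret the p-value as a ranking ingredient, not
  a calibrated error rate.
- **Power-law GoF has limited power.** The free `xmin` lets a short upper
  tail of almost any unimodal sample pass the power-law test (observed ~50 %
  rejection on clearly non-power-law data). The exponential and log-normal
  tests, with no shape freedom, carry the discriminative weight of the
  long-tail classification.
- **PPV/NPV conventions.** The harness computes strictly
  `PPV = TP/(TP+FP)` over predicted positives and `NPV = TN/(TN+FN)` over
  predicted negatives; prose summaries elsewhere sometimes swap the labels
  "predicted" and "true" when quoting such counts, so the formulas here are
  authoritative.
- Scores from external tools (LIMMA, DIDS, …) are consumed as pre-computed
  columns by the benchmark harness; re-deriving those methods is out of
  scope.
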