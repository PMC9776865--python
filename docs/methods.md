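# Methods

## Model and procedure

The pipeline predicts per-gene binary mutation status from a patient ×
feature table of continuous radiomics measurements. Its assumptions are
modest but worth stating:

* Associations between features and mutation status are monotone enough that
  Spearman rank correlation is a sensible screening statistic; the feature
  reduction (clustering and representative choice) is entirely rank-based
  and therefore invariant to any strictly increasing transform of any
  feature column.
* The cohort is small (default 47 patients), so discrimination is assessed
  as a *distribution* over repeated random train/test partitions rather
  than a single number.
* The logistic models are small (at most seven predictors) and unregularized
  by default; regularization exists only as a numerical fallback, not as a
  modeling choice.

Stages, in order: (1) per-column normalization, (2) complete-linkage
clustering of features, performed once, independently of mutation status,
(3) per-gene cluster representatives by largest squared Spearman correlation
with the labels, (4) per-feature raw-vs-log modeling decision, (5) repeated
cross-validation with exhaustive subset search (Method 1) or a fixed subset
(Method 2), (6) metric summaries and importance counts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k_clusters` | 7 | clusters the dendrogram is cut into, hence candidate features per gene. The default mirrors a choice made by visual inspection of cluster trees in the design this reproduces; there is deliberately no automatic selection. |
| `n_sets` | 1000 | cross-validation resamples; at 1000 the 2.5/97.5 percentile endpoints are stable to about ±1 order statistic. |
| `test_size` | 10 | patients per test set (37 train at n=47). |
| `threshold_rule` | `fixed` (0.5) | probability cutoff for classifying positive. `youden` instead uses the training-ROC-optimal cutpoint per model (ties resolved toward the larger threshold). 0.5 is the default because it is the minimal assumption; nothing in the design pins the alternative down. |
| `seed` | 0 | governs split generation only; every fit is deterministic. |

Synthetic-cohort generator: `within_corr`/`between_corr` (defaults 0.8/0.2)
are the latent within/between-block Gaussian correlations — conventions
chosen to make the block structure clearly recoverable at cohort scale, not
estimates of any real feature table. `skew_fraction` (0.3) of columns are
passed through `exp(1.5·z)`, giving a population mean/median ratio of
`exp(1.5²/2) ≈ 3.1`, safely beyond the 1.5 rule at realistic sample sizes.
Target prevalences default to 81/68/26/19% for KRAS/TP53/SMAD4/CDKN2A; the
logistic intercept per gene is solved by 1-D root finding (Brent) so the
expected prevalence over the realized cohort matches the target to 1e-6.

## Numerical choices

* **Normality score.** Standardize, bin into ⌈n^0.4⌉ bins equiprobable under
  the standard normal, Pearson χ² divided by (bins − 3) degrees of freedom.
  Candidate transform families are searched in a fixed order (identity,
  shifted log, square root, asinh, maximum-likelihood Yeo–Johnson,
  rank-inverse-normal with Blom offset) and ties break in that order, so the
  selection is deterministic. A family that fails numerically on extreme
  inputs (e.g. Yeo–Johnson likelihood overflow) scores +inf and is skipped
  rather than aborting the column.
* **Raw-vs-log rule.** log is used iff sample mean/median > 1.5, with an
  additive shift of 1 − min when non-positive values are present. A zero
  median leaves the ratio undefined: the column stays raw and the decision
  record is flagged, rather than letting an undefined ratio silently decide.
  The decision is made once on the full cohort, before cross-validation, so
  all splits share one fixed map.
* **Clustering distance and tie-breaks.** d = 1 − ρₛ², so anti-correlated
  duplicates cluster together, consistent with the squared-correlation
  selection rule. Merging follows scipy's deterministic complete-linkage
  order; exact height ties have measure zero on continuous data. Cluster
  labels are relabelled 1..k by first occurrence in column order.
  Representative ties (equal ρₛ²) go to the lexicographically smallest
  feature name. Zero-variance columns are an error, never silently dropped.
* **Logistic fitting.** Newton/IRLS on per-item standardized predictors,
  vectorized across all cross-validation splits at once (batched Hessian
  solves), convergence at step-norm < 1e-9, steps clipped at 10 per
  coordinate. On non-convergence or separation (any standardized slope
  |β| > 15) the fit is repeated with ridge λ = 1e-4 on slopes only and
  flagged `penalized`; at 37 training patients with up to 7 predictors,
  separation is routine, and every subset must still yield a comparable
  finite model. Coefficients are reported on the raw predictor scale
  (the ML solution is affine-equivariant, so this matches an unstandardized
  fit). The intercept-only model is excluded from the search; an empty
  subset fit (available as a function) has the closed form logit(mean y).
* **Subset search order.** Subsets are enumerated by (size, lexicographic
  name tuple) and the first strict maximum of the training Youden index
  wins — i.e. ties prefer fewer features, then smaller names. Training-set
  (resubstitution) Youden is the criterion; the test set is touched only for
  evaluation.
* **Degenerate cases.** Splits whose training labels are single-class are
  skipped and counted (they admit no fit). Test-set 0/0 ratios are defined
  as 0 and flagged per record; the Youden identity holds exactly on flagged
  records too. Quantiles are linear-interpolation (numpy default, type-7)
  so summaries are bit-reproducible.

## What the synthetic generator does and does not emulate

It reproduces: blocks of mutually rank-correlated features (exchangeable
within-block Gaussian factor model), heavy right skew in a fraction of
columns via a strictly increasing convex map, and per-gene logistic labels
with calibrated marginal prevalence on a small set of planted informative
features. It does not emulate: real radiomics marginal distributions or
inter-family correlation patterns, scanner/acquisition batch effects,
heavy ties or detection limits, label noise in variant calling, or any
spatial image structure. Consequently, passing tests demonstrate that the
*pipeline machinery* is correct and calibrated under its stated assumptions
— not that any particular discrimination level is attainable on real CT
cohorts.

## Design decisions that were genuinely open

* Normalization feeds only the (unsupervised, rank-based) clustering, so it
  is computed from and applied to the full table; this mirrors performing
  clustering once for the entire feature set and has no effect on the
  clustering result (rank invariance), only on the audit trail.
* Splits are unstratified simple random partitions; stratification is
  available as a flag but off by default, matching random allocation.
* Method 1's per-split search and Method 2's full-data search share one code
  path (Method 2 is a batch of size one), so their tie-breaking and fallback
  behavior cannot drift apart.
* Problem sizes in the test suite (e.g. 200 resamples for calibration
  checks, n = 400 for signal-recovery checks) are chosen so each property
  is comfortably resolved by Monte-Carlo at that scale.

## Known limitations

* Exhaustive search is exponential; the guard refuses more than 20
  candidates (the design intent is 7 after reduction).
* The number of clusters k is a parameter, not inferred; nothing replaces
  the original visual dendrogram inspection.
* Method 2 selects its subset on the complete cohort, including every
  split's future test patients. This is inherent to the method's definition
  (only coefficients are re-estimated per split) and shows up as optimism
  under null labels; the per-method null medians remain centered at 0, but
  per-gene medians on a single permuted cohort can drift by a few tenths
  because chance associations in a 47-patient cohort are real, findable
  structure.
* With ten-patient test sets all metrics are coarse lattices (steps of
  ~0.1–0.5 depending on class balance); medians and interval endpoints
  inherit that granularity.
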