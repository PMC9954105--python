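# Methods

This note documents the models, numerical choices and open design decisions
behind `vocchemo`, and states what the synthetic study designs do and do not
establish about real GC-MS data.

## Data model

The unit of analysis is an aligned feature table: `n_features × n_samples`
nonnegative integrated GC-MS signals in arbitrary instrument units, with a
retention-time mean and across-sample retention-time spread (minutes) per
feature and optional compound annotations (name, functional group, exogenous
flag). A signal of 0 always encodes *not detected*; missing cells are not
representable, so presence/absence is unambiguous for the presence filter.
Clinical metadata lives in a separate table keyed by sample id. Binary class
labelings are derived from it: `cancer_vs_none` (case iff ISUP grade ≥ 1),
`aggressive_vs_rest` (case iff grade ≥ 3; grades 0–2 pooled because indolent
disease and negative biopsies are the clinically relevant reference for a
surveillance test), and `tumor_vs_control` for mice.

## Screening cascade

Rules are applied in a fixed order — retention-time spread, presence,
exclusion, normalization — and the report attributes every removed feature to
exactly one rule, so counts are reproducible and sum to the input size.

- **RT spread** (`max_rt_spread`, default 0.10 min). "High retention-time
  variation" has no universal cutoff; 0.10 min is a typical capillary-GC
  alignment tolerance and is exposed as a plain knob, not a claim.
- **Presence** (`presence_min_fraction`, default 0.5; `presence_mode`,
  default `any_class`). The default keeps a feature detected in at least half
  the samples of *at least one* class: a biomarker absent in one class but
  consistently present in the other is exactly what a diagnostic search wants
  to keep. The stricter `all_classes` mode is available. The filter accepts
  any sample partition, so a four-class clinical labeling can drive it while
  a two-class comparison drives the statistics.
- **Exclusion**: features flagged exogenous (siloxanes from the SPME
  fiber/column, plasticizers) or named in a user exclusion list.
- **Normalization**: each signal divided by its sample's total signal
  (relative abundance). This cancels any per-sample multiplicative factor —
  urine concentration, injection efficiency — exactly in real arithmetic;
  columns sum to 1 within 1e-9. An all-zero sample is an error naming the
  sample rather than a silent NaN.

Curation steps that need raw spectra (splitting features that mix two
molecular subpopulations) are upstream of this package and out of scope.

## Univariate statistics

Per feature, a two-tailed pooled-variance Student *t* test (df = n₀+n₁−2) of
case versus reference; Welch is available because normalized signals are
often heteroscedastic, but Student is the default and the primary path.
Degenerate zero-variance input is resolved explicitly: equal means give
(t, p) = (0, 1); unequal means give the (±∞, 0) limit with a warning. Raw p
values are the interface — feature subsets downstream use the conventional
0.05 and 0.10 thresholds — and a Benjamini–Hochberg column is an opt-in
extra, because the staged panel search, not the t test, is the multivariate
inference step.

Fold changes are log₂(mean_case / mean_ref), so case-upregulated features
plot right of zero on a volcano. When one mean is zero, both means are offset
by ε = half the smallest nonzero normalized value in the matrix before the
ratio; when both are zero the feature is flagged and excluded from volcano
coordinates.

Heatmap ordering: per-feature z-scores (constant rows become all-zero and are
flagged), average-linkage (UPGMA) Euclidean agglomerative clustering of rows
and columns, scipy's deterministic leaf order. Linkage and metric are
arguments; the defaults are the common chemometric choice.

## PCA

Samples are observations; features are centered and, by default, autoscaled
to unit variance (standard in chemometrics where signals span orders of
magnitude; `scaling="none"` is exposed since the choice changes
explained-variance percentages). The decomposition is a full SVD; each
loading vector is sign-fixed so its largest-magnitude entry is positive,
making score files platform-stable. Two small analyses are layered on top:
a Student *t* test of one component's scores between classes, and a
"separation accuracy" — the training accuracy of Fisher LDA on the first k
score dimensions — which operationalizes the visual claim that classes are
distinguished in a k-dimensional score plot.

## Fisher LDA

Two-class Fisher discriminant with equal priors:

    w = (S_w + λ·(tr S_w / p)·I)⁻¹ (μ₁ − μ₀),    score(x) = w·x − w·(μ₀+μ₁)/2

with S_w the pooled within-class covariance over p panel features. The ridge
is scaled by the mean pooled variance so λ is dimensionless; the default
λ = 1e-6 is numerically negligible for well-conditioned panels but keeps the
solve stable when panel size approaches the per-fold training size. λ = 0 is
allowed and raises an instructive error on a singular S_w. Identical class
means yield the zero weight vector and a degeneracy flag rather than an
error.

## Panel search

The candidate pool is the screened matrix, optionally pre-filtered to
features with univariate p below `pool_p` (default 0.10 in the pipeline) —
the standard way to make a combinatorial search tractable on a
few-hundred-feature matrix.

- **Criterion**: stratified 5-fold cross-validation; per fold, LDA is fitted
  on the training folds and the held-out fold is scored; the criterion is the
  AUC of the pooled held-out LD1 scores. AUC is the default because it is
  threshold-free; accuracy at the LD1 midpoint threshold (`cv_accuracy`) is
  available. The fold assignment is drawn once per search from the seed and
  shared by all candidates, so criterion values are comparable.
- **Stage 3**: every 3-subset of the pool is evaluated exhaustively.
- **Expansion k → k+1**: "keep part of the panel and re-search the rest" is
  implemented at two widths. `reserve_one` evaluates every (k+1)-subset that
  retains at least one current member — the literal, exponentially wide
  reading. `swap_add` evaluates the panel plus one feature, and the panel
  with one member swapped for two new ones — a tractable neighbourhood that
  still allows the search to back out of an early mistake. `auto` uses
  `reserve_one` while its model-fit count stays under a budget (default
  2×10⁶ fits) and falls back to `swap_add`; the mode used at each stage is
  recorded in the result so any reported panel states its search space.
- **Stopping**: the search stops when the best enlarged panel does not
  strictly improve the criterion, or at `max_size` (default 10). Criterion
  ties between candidates break to the lexicographically smallest feature-id
  tuple and are logged.
- Candidate evaluation shares per-fold sufficient statistics (full-pool
  pooled covariance and class means), so scoring a panel is a small solve
  plus a projection; a unit test pins the fast path to the plain per-panel
  implementation at 1e-12.

"All permutations of three compounds" is treated as combinations: LDA is
invariant to feature order.

## Hold-out perturbation validation

A fixed panel is validated by `n_reps` (default 1000) random stratified
splits holding out a fraction (default 1/5) of each class for testing; LDA is
refitted on the remainder each time. Per split, the held-out ROC (full
threshold sweep; tied scores collapse to one threshold, giving diagonal
segments) is interpolated onto a fixed FPR grid (0…1, step 0.01) by staircase
interpolation and the grid-wise mean over splits is the averaged curve. The
summary AUC is the trapezoid of the averaged curve; the operating point
maximizes Youden's J = sensitivity + specificity − 1, with ties broken toward
higher specificity (the choice of operating-point rule is this package's
convention; single reported sensitivity/specificity pairs rarely name one).
Per-repeat seeds are spawned from one seed via `SeedSequence`, so any single
repeat is reproducible in isolation and the whole summary is bit-stable.
Training metrics (fit on all samples, in-sample ROC) use the same summary
container with `n_reps = 0`; training AUC exceeding the hold-out AUC is the
expected overfitting signature and is exercised by the test suite.

## Functional groups

Each significant feature maps to exactly one class from {terpene/terpenoid,
aromatic, nonaromatic cyclic, ketone, aldehyde, ester, alcohol,
sulfur-containing, other}; multi-group annotations resolve by a configurable
priority order (default: that list order, so an aryl ketone counts as
aromatic). One class per compound keeps frequencies summing to the number of
significant features and ratios summing to 1; "frequency ratio" is normalized
within a comparison. Unresolvable annotations go to "other" with a warning.

## Synthetic cohorts

The generator draws log-normal signals: log-signal = baseline + class effect
+ N(0, intraclass log-sd), times a per-sample log-normal dilution factor,
then censors below the global `lod_quantile` threshold (default 5 %) to zero.
The log-normal choice matches positive, right-skewed integrated intensities
and makes class effects multiplicative, i.e. additive on the log₂ scale the
fold changes are read on. Censoring is applied to raw (pre-normalization)
signals because detection physically happens before any rescaling.

Scenario defaults encode the two study designs the pipeline targets:

| scenario | classes | features | informative | log₂FC | intraclass log-sd |
|---|---|---|---|---|---|
| `mouse_like` | 8 control / 9 tumor | 161 | 16 | 2.0 | 0.25 |
| `human_screen` | 67 / 95 (grades 38/30/8/5/14 over ISUP 1–5) | 367 | 6 | 1.0 | 0.8 |
| `human_aggressive` | 135 / 27 (same cohort, grade ≥ 3 as case) | 367 | 6 | 1.0 | 0.8 |
| `null` | 67 / 95 | 367 | 0 | — | 0.8 |

Both human scenarios share the grade composition, so one cohort supports both
labelings. The mouse design has large effects and low intraclass variance
(a controlled experiment: same animals, diet and housing); the human design
has moderate effects and high intraclass variance (free-living subjects).
Up-regulated fractions are 0.6 (mouse), 0.7 (screening) and 0.3 (aggressive),
reflecting that most screening biomarkers rise with disease while the
aggressive comparison is dominated by down-regulation. Baseline log-means are
uniform on [9, 16] (natural log; roughly 8×10³–9×10⁶ signal units);
informative features draw their baselines from the upper three quarters of
that range, because a biomarker candidate that is mostly below the detection
limit could not be discovered by any screening pipeline — planting one would
test censoring, not recovery. Dilution log-sd defaults to 0.5 (human) and
0.3 (mouse). Planted nuisance features: high-RT-spread features get spreads
of 0.15–0.50 min, exogenous features carry known plasticizer/siloxane names
and the exogenous flag.

The feature, signal, dilution and metadata random streams are spawned
independently from the seed, so disabling dilution leaves the signal draws
untouched. With censoring off, normalizing a diluted cohort equals
normalizing the undiluted one — exactly in real arithmetic; tests assert it
at relative 1e-12, the agreement attainable once each entry has been rounded
through IEEE multiplication and summation.

What the generator does *not* emulate: correlated feature blocks
(co-regulated metabolites), retention-time drift within a batch, run-order
and storage-time effects, heavy-tailed contamination, and compositional
closure beyond what normalization itself induces. Passing tests therefore
demonstrate that the algorithms are correct and well-behaved under the
designed signal/noise regimes, not that any particular real cohort will reach
the same accuracies.

The run-order utility produces a randomized sample order with no two
consecutive same-grade samples, via a greedy scheduler that must place any
key holding a strict majority of the remaining slots; this is feasible
exactly when the largest grade count is at most ⌈n/2⌉, and otherwise the
order is best-effort with the violation count reported.

## Pipeline reproducibility

`run_pipeline` fans a single master seed out to fixed per-stage seeds
(recorded in the manifest), writes one artifact per stage with SHA-256
checksums, and is byte-reproducible for identical configuration and seed.
Stage artifacts are plain CSV/JSON so each stage can be rerun in isolation
through its subcommand on the previous stage's outputs.

## Problem sizes in tests and the acceptance script

The test suite exercises the full study designs (367-feature human cohorts,
161-feature mouse cohorts) for screening, univariate, PCA and validation
checks; repeated-search checks (planted-panel recovery over 20 cohorts) run
the forward search in `swap_add` mode on the p < 0.10 pre-filtered pool, and
hold-out validation is run at 200 repeats where it is repeated across many
seeds and at the full 1000 repeats for single summaries. These sizes are the
package's chosen defaults for routine verification; all knobs accept larger
values.

## Known limitations

- Only two-class Fisher LDA is provided (no logistic regression, QDA or
  SVM) and no nested cross-validation for hyperparameter tuning — the
  analysis this package implements does neither.
- `reserve_one` grows combinatorially; on realistic pools the auto mode
  switches to `swap_add` within a few stages, and results must be read
  together with the recorded search mode.
- The cross-validated criterion is maximized over many candidate panels, so
  the criterion value of the winning panel is optimistically biased;
  the honest stability estimate is the held-out perturbation AUC, and even
  that shares samples with the search. A truly unbiased estimate needs an
  external cohort, which is beyond any resampling scheme.
- Compound identity and functional groups come from annotations; nothing is
  inferred from spectra.
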