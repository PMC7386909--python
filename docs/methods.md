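# Methods

`nkdetect` implements a blood-based prostate-cancer detection pipeline built
on flow-cytometric NK-cell subset phenotyping.  The input is a table of 32
percentage features per patient (CD56dim/CD56bright subsets with their CD16
composition, CD8 co-expression, and activating/inhibitory receptor
fractions), a serum PSA value, and a binary outcome.  Two tasks are
supported: *detection* (benign prostate disease vs cancer in asymptomatic
men with PSA < 20 ng/ml) and *risk* (D'Amico low/intermediate vs high risk
among cancer patients).

## Prediction model

The classifier is a random-subspace ensemble of k-nearest-neighbour weak
learners.  With d predictors, n_learners = 30 learners are each bound to a
random subset of m = min(16, d) predictors chosen without replacement; a
learner scores a probe as the fraction of its k nearest training neighbours
(Euclidean distance in its subspace; k = 1 by default) carrying the positive
label, and the ensemble score is the mean learner score.  Averaging (rather
than hard majority voting, which is available via `vote="hard-majority"`)
yields the continuous ranking that ROC analysis requires.  Design details:

- **Subspace cap.** A subspace dimension of 16 is undefined when d < 16
  (e.g. the 8-feature signature panel); m is capped at d and the cap is
  recorded on the model.
- **Neighbour ties.** All training points at the k-th smallest distance are
  included ("radius-inclusive"), making scores independent of row order.
- **Decision threshold.** Scores >= 0.5 are classified positive (ties go to
  the positive class).
- **Feature scaling.** The phenotypic features share a 0-100 percentage
  scale and are used raw.  When PSA enters a predictor set it is min-max
  rescaled to [0, 100] so its Euclidean contribution is commensurate;
  raw ng/ml values would be negligible against percentages.
- Baseline comparators (plain kNN with k = 2/5/10, Gaussian naive Bayes)
  are provided through scikit-learn behind the same scoring interface.

## Feature selection

Two routes nominate features, kept deliberately separate from the
classifier:

1. **Rank screen.**  Per-feature two-group Kruskal-Wallis (tie-corrected,
   1 df) at a raw alpha = 0.05; no multiple-testing correction by default
   (a Bonferroni option exists).  Normality is assessed per feature with the
   Lilliefors-corrected Kolmogorov-Smirnov test plus Shapiro-Wilk on the
   pooled sample (df = n); the screen's role is to justify the
   nonparametric route, not to gate it.
2. **GA + mRMR.**  A genetic algorithm searches subsets of exactly λ
   features, maximizing the difference-form mRMR criterion
   `mean_i I(x_i; y) − mean_{i<j} I(x_i; x_j)` with plug-in mutual
   information on equal-frequency-discretized features (4 bins by default;
   n ≈ 71 supports about 4 bins per margin).  GA operators: tournament
   selection (size 3), uniform crossover with repair to exactly λ distinct
   ids, single-feature swap mutation, elitism of 2; population 50,
   generations 100, crossover 0.8, mutation 0.1.  These hyperparameters are
   not load-bearing: the protocol runs the GA 30 times (seeds derived as
   master + run index) and reports each subset's run frequency fc and
   relative frequency rfc = fc / runs; the modal subset is the consensus
   selection.

Named feature-set conditions used in the evaluation: `GA` = {2, 20, 27, 28}
(CD56dim CD16high, DNAM-1−, LAIR-1+, LAIR-1−), `STAT` = {14, 15, 16, 17}
(CD56bright CD8+, NKp30±, NKp46+), `GA+STAT` their union, `PSA+GA+STAT`,
`PSA` alone, and `ALL` 32 features.

## Evaluation protocol

10-fold cross-validation repeated 30 times with a fresh partition seed per
run (unstratified by default, matching random partitioning of 71 records
into one fold of 8 and nine of 7; a stratified option exists because small
unstratified folds can be single-class).  Out-of-fold scores are pooled
across the 10 folds and one AUC, optimal-ROC-point FPR/TPR, and accuracy
are computed per run (per-fold averaging is available but fold-level AUC on
7 samples is ill-defined whenever a fold lacks a class).  Aggregates are
the mean and sample standard deviation (n−1) over runs, plus the mean of
the four metrics' standard deviations ("mean std", the stability summary).

The optimal ROC point slides a line of slope
`S = (Cost(P|N) − Cost(N|N)) / (Cost(N|P) − Cost(P|P)) × N/P` down from the
(FPR 0, TPR 1) corner; with the default unit misclassification costs and
zero correct-classification costs, S = N/P.  The selected vertex maximizes
TPR − S·FPR, ties broken toward the smaller FPR.  AUC is the trapezoid area
of the tie-grouped ROC curve and equals the Mann-Whitney U statistic over
P·N with half-credit for score ties (asserted against a brute-force
pairwise oracle in the tests).

Conditions are ranked by mean AUC (ties by higher accuracy, then lower ORP
FPR — a declared convention).  Differences across conditions are tested
with the Friedman rank test on the runs × conditions AUC matrix (mid-ranks,
tie correction, k−1 df), followed by pairwise mean-rank z-tests with
standard error sqrt(k(k+1)/(6n)), Bonferroni-multiplied p-values and
simultaneous 95% confidence intervals.  Mean ranks are reported on the
within-run 1..k scale.

## Risk experiment

The risk model uses all 32 phenotypic features and deliberately excludes
PSA (the clinical point is risk prediction without PSA/Gleason/stage).  A
stratified hold-out of 5 + 5 records is drawn once per experiment; the
remaining 44 records undergo 30 iterations of 10-fold CV (300 fold-level
fits), and per iteration a model trained on the full remainder scores the
10 hold-out records.  Both surfaces (validation and test) are computed by
the same evaluation code path and aggregated as mean ± std over iterations.

## Synthetic cohort generator

The generator emulates the *printed marginal structure* of the study
cohort: group-conditional location/scale/bounds for each of the 32 features
and PSA, transcribed from the published descriptive table (defaults: 30
benign + 41 cancer; risk cohort 38 L/I + 16 H).

- **Families.**  Truncated normal (sampled by inverse CDF) for roughly
  symmetric features; a bound-anchored shifted log-normal, moment-matched
  and clipped, for features whose printed std exceeds half the mean in
  either group for either member of the pair (the LAIR-1, DNAM-1, NKp44,
  NKG2D and 2B4 negative fractions are strongly skewed; the published
  normality table shows most features non-Gaussian).  PSA is modelled as
  right-skewed within [4.7, 19.0) ng/ml.
- **Structure.**  One member of each marker+/marker− complement pair is
  simulated (inside the intersection of its own bounds and the complement
  of its partner's) and the partner derived as 100 − x, so pairs sum to
  exactly 100 by construction.  The CD16 high/low/negative components are
  drawn and rescaled to their gate total (CD56dim total, itself simulated;
  CD56bright total = 100 − dim), with CD16+ = high + low.  During
  rescaling, components are kept in bounds by redistributing the residual;
  an irreducible residual is absorbed by the CD16− component so the
  compositional identity is exact (bounds on derived block components can
  therefore be exceeded marginally in rare draws).
- **Effect size control.**  `effect_scale` multiplies the between-group
  location differences around the two-group midpoint; scale and bounds are
  pooled as the factor drops toward 0 (an exact null) but never
  extrapolated past the group's own values.  Type-I calibration under
  `effect_scale=0` (Kruskal-Wallis rejection rate 0.05 ± 0.02 over 1000
  replicates; CV AUC 0.5 ± 0.08) is asserted in the acceptance tests.
- **Risk effect.**  The packaged high-risk shift moves the eight-feature
  signature panel by 1.5 pooled standard deviations toward the bound with
  more room.  Since a complement pair is one degree of freedom, the shift
  attaches to the simulated member of each pair, giving six independent
  shifted coordinates (features 2, 14, 15, 17, 19, 27).  The high-risk PSA
  is a heavy-tailed log-normal (median 60 ng/ml, log-sd 1.4) clipped to
  [4.3, 2617].  This default was fixed by a one-off parameter-recovery
  experiment (CV validation AUC ≥ 0.9 across master seeds).
- **Planted cohort.**  `generate_planted_cohort` builds an idealized
  recovery instrument: iid N(50, 10) features clipped to [0, 100], with
  exactly four planted features shifted 1.0 sd in the positive group
  (defaults 150 + 150 patients).  The sizes matter: the planted set is the
  *population* optimum of the mRMR difference criterion only when pairwise
  label-induced dependence among signal features stays second-order
  relative to relevance.  At very strong shifts the criterion genuinely
  prefers to swap one signal feature for noise, and at n ≈ 71 the plug-in
  MI estimates are too noisy to rank features stably — which is precisely
  why the repeated-run consensus protocol exists.

**What passing tests do not show.**  The generator reproduces printed
margins plus pair/block structure only; between-feature correlation beyond
that is not modelled (the study's correlation heatmap prints no values).
Because much of the real detection signal apparently lives in the joint
distribution, cross-validated AUC on the faithful synthetic cohort
(~0.6-0.65 for the signature panel) is expected to sit well below the
published ~0.82, and the pipeline's published headline numbers are not
reproduction targets here.  Null calibration, oracle equivalence and
recovery experiments are the meaningful checks.

## Numerical choices and degenerate inputs

- Quartile convention for IQR: linear interpolation between order
  statistics (numpy's default), recorded in the output metadata.
- Descriptive std is the sample (n−1) standard deviation; the diff column
  is mean(benign) − mean(cancer).
- Equal-frequency discretization places edges at order statistics
  ⌊jn/bins⌋; tied values share a code, a constant vector maps to one code.
- MI is the plug-in estimate in nats; no bias correction (the mRMR
  comparison is between subsets estimated on the same sample, so the
  plug-in bias largely cancels).
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are `master + index` reduced mod 2^31.
- Generation fails loudly when a spec's bounds exclude its location by
  more than 6 scales; constant features are flagged and skipped by the
  normality screen; empty-class rates are reported as NaN.

## Problem sizes in the packaged experiments

The shipped defaults (30 + 41 detection cohort, 30 CV runs, 30 GA runs,
30 risk iterations, 150 + 150 planted cohort, 1000 null replicates for the
type-I calibration) match the study protocol's shapes and keep the full
suite and the acceptance script each under a couple of minutes on one core.

## Known limitations

- Feature independence given group (beyond pairs/blocks) is a simplifying
  assumption; a correlated generator is an extension point.
- The published Friedman mean ranks are on an unexplained scale
  (3.07-20.28 for 5 conditions over 30 runs, where within-run ranks span
  1-5); the standard within-run construction is implemented and the
  discrepancy left unmimicked.
- Under an exact null the out-of-fold 1-NN ensemble's accuracy sits
  slightly *below* chance (a positive probe's training pool has one fewer
  positive — the usual leave-one-out anti-bias), so null accuracy is not
  expected to equal the majority-class rate.
- The optional SVM comparators of the original study are not implemented;
  the baseline set is plain kNN and Gaussian naive Bayes.
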