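# Methods

This note documents the statistical model behind `uromarker`, the
choices made where the procedure admits more than one reasonable
implementation, and what the synthetic-data generator does and does
not emulate.

## Data model and preprocessing

A feature table holds non-negative peak areas for every injection
(study samples, pooled-QC injections, blanks) over features defined by
molecular weight and retention time.  The preprocessing chain is fixed
in this order:

1. **Conditioning QCs dropped.**  The QC injections run at the start of
   a batch equilibrate the column; they monitor nothing and are
   excluded from every QC-based statistic.
2. **Blank / carry-over filter.**  A feature is removed when its mean
   blank area exceeds 10 % of its mean monitoring-QC area.  The QC
   mean is the reference because the pooled QC is the best available
   proxy for a typical sample; the threshold is configurable
   (`PreprocessConfig.carryover_threshold`).
3. **Drift correction.**  Per feature, OLS of monitoring-QC area on
   injection order gives slope b; every row is corrected additively by
   `area − b·(order − ō)` with ō the mean QC injection order, flooring
   at zero.  Anchoring at ō keeps the QC mean unchanged and makes the
   correction idempotent.  A multiplicative variant (division by the
   fitted line normalised to its value at ō) is available via
   `drift_mode="multiplicative"`; additive is the default because it
   is exact for any linear trend regardless of the feature's scale and
   degenerates gracefully when the intercept is near zero.
4. **QC presence / stability filter.**  Features with a zero area in
   any monitoring QC, or with QC RSD (sd/mean) above 25 %, are
   removed.  RSD uses the n−1 sample standard deviation — with only
   ~8 monitoring QCs the bias of the population formula is material,
   and the n−1 convention is the usual one in metabolomics QA.
   Zero-area values in *sample* rows are not a removal criterion; only
   QC presence is.
5. **Creatinine normalization.**  Sample rows are divided by the
   sample's urinary creatinine (mg/dL); QC rows are untouched (the
   pool has no single-donor creatinine).  Plain division is used; any
   alternative that rescales by a global reference concentration
   differs only by a constant that autoscaling absorbs.
6. **Autoscaling** (mean-centering, unit variance per feature) is
   *not* part of the chain: it is refitted on calibration rows inside
   every cross-validation loop so that held-out rows never influence
   the scaling that transforms them.

Re-running filters 2–4 on their own output removes nothing further.

## PLS-DA

Classes are coded BPH → −1, PCa → +1, making the signed canonical
score directly readable (negative = benign, positive = carcinoma).
The fit is standard NIPALS PLS1 with X-only deflation; y is centered
at fit time and the training mean added back at prediction, so the
zero threshold stays calibrated under mildly unbalanced calibration
folds.  An exact zero score resolves to the negative class — a
deterministic tie rule, not a statistical statement.

Two notions of "variable weight" exist: the first-latent-variable
weight vector w₁ and the regression vector b.  Reports use b (one
sign-interpretable value per variable, and the quantity the
rank-product filter ranks); w₁ is kept on the model object.

VIP_j = √( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ), with SSY_a the
y-variance captured by component a.  The mean squared VIP over
variables is exactly 1 for any fitted model, which the tests assert as
an identity.

## Repeated double cross-validation

Defaults: 10 outer deletion groups, 8 inner groups, 30 runs,
stratified splits.  Stratification is the package's choice: with a
balanced 20 + 20 design every outer group holds exactly 2 + 2 samples,
which keeps every fold's figures of merit defined.  The
latent-variable count is chosen per outer fold by minimizing inner-CV
misclassification error over 1..max_lv (default ceiling 5), ties
breaking to the smaller count.  The candidate ceiling is truncated
when small folds cannot support it.

Every quantity is retained as a distribution: per-run figures of
merit, per-sample held-out scores (one per run), per-variable
coefficients.  Confidence intervals are nearest-rank percentiles —
the bounds are always observed values and no interpolation rule has to
be agreed on.

**Leakage contract.**  Validation rows never influence autoscaling,
block scaling, latent-variable selection, or the coefficients of the
model that predicts them.  The test suite enforces this by corrupting
the held-out rows of each outer group in turn and asserting the
corresponding sub-model is bit-identical.

**Sub-model harvesting.**  Variable selection aggregates
runs × inner_groups coefficient vectors (240 at defaults): per run,
the 8 inner-fold calibration models of the first outer fold, refitted
at the selected latent-variable count.  A `harvest="nested"` mode
collects runs × outer × inner vectors instead for sensitivity
analysis.  VIPs are averaged over the same harvested sub-models.

**Permutation test.**  Evaluating a full r-dCV per permutation is
needlessly expensive for a null that only has to be exchangeable; by
default each of the B label permutations is evaluated with a single
dCV pass at the modal latent-variable count of the unpermuted model.
A `full_rdcv=True` flag restores the complete procedure per
permutation.  p-values use the add-one rule, so they live in
[1/(B+1), 1].

## Variable selection

Within each harvested sub-model, variables are ranked by descending
|b| with average ranks on ties.  RP_j is computed as
exp(mean(log rank)) — 240 products of ranks up to a few thousand
overflow double precision, the log form does not.  The selection
threshold is the geometric mean of all RPs with strict inequality,
guarded by a 10⁻⁹ log-space tolerance so that a degenerate all-equal
vector selects nothing.  The surviving set is intersected with
variables whose mean VIP exceeds 1 (the conventional relevance rule).

## Evaluation

ROC curves are computed per run from that run's held-out scores
(threshold sweep; AUROC by trapezoid rule, equal to the normalized
Mann–Whitney U).  Curves are averaged vertically on a fixed 101-point
false-positive-rate grid; the AUROC CI is the nearest-rank interval
over runs.  Univariate marker benchmarks run the same r-dCV engine on
a single column with one latent variable, so model and marker numbers
are directly comparable.  t-tests are pooled-variance Student by
default (Welch behind a flag); no multiplicity correction is applied.

Multi-block fusion scales each autoscaled block to unit Frobenius norm
before concatenation, equalizing the influence of blocks of different
width; inside cross-validation the norms come from calibration rows
only.  Blocks are aligned by sample id, not by each block's own
injection order — the acquisition sequences of two ionization modes
are unrelated.

## Synthetic data

The generator emulates a 20 + 20 urine study acquired in one batch:

- **Abundances** are log-normal (log-mean 11.5, between-feature log-sd
  1.0, within-class biological log-sd 0.4).  Peak areas are positive
  and right-skewed, and autoscaling makes the absolute scale
  immaterial.
- **Class effects** are additive on the log scale on a planted subset
  (default 22 of 200 features), sized so the class separation is
  `effect_size` (default 1.5) pooled SDs on the autoscaled axis, with
  half the features overexpressed in each class.
- **Urinary dilution**: each sample's areas are multiplied by a
  dilution factor proportional to its drawn creatinine (log-normal,
  median 100 mg/dL, log-sd 0.5; optionally one outlier fixed at
  5 mg/dL).  Metabolite concentrations and creatinine scale together
  with urine concentration, so downstream creatinine division removes
  this nuisance — which is the point of the normalization step.
- **QC injections** follow the batch template: 10 conditioning QCs,
  then blocks of 5 randomized samples each closed by a monitoring QC.
  QC areas are the per-feature mean of the (diluted) sample areas —
  pooled-QC semantics — times log-normal technical noise with RSD
  0.10.  The true technical RSD of such systems is rarely published;
  0.10 is a modeling choice comfortably below the 0.25 filter.
- **Planted artefacts**: blank-contaminated features carry blank areas
  at 20 % of the QC mean (safely above the 10 % rule); QC-unstable
  features oscillate deterministically by ±50 % across monitoring QCs
  (RSD ≈ 0.5, so the stability filter removes them even in noise-free
  settings); QC-missing features are zeroed in the first monitoring
  QC.  These sets are disjoint from the discriminant set, and drift is
  planted only outside them, so the preprocessing filters remove
  exactly the planted `filtered_indices` and the truth file is an
  exact oracle.
- **Drift** is multiplicative and linear in injection order (default:
  30 % of features at 0.5 %/injection), matching the linear detrend
  the correction applies; no nonlinear drift is generated by default.

One `numpy` generator seeded once drives every draw, so a seed
reproduces the table bit-for-bit.

What the generator does **not** emulate: raw chromatograms or spectra,
retention-time misalignment, missing values in sample rows,
heavy-tailed or correlated biological variation, nonlinear or stepwise
drift, and batch-to-batch effects.  Passing tests therefore show that
the machinery is correct and well-calibrated under the stated
statistical model, not that real urinary cohorts will reach the same
figures of merit.

## Problem sizes

The default synthetic study is 40 samples × 200 features with 22
planted biomarkers.  The test suite and the acceptance script use this
size (scaling the feature count up to a few thousand changes nothing
structurally; 200 keeps a full 30-run r-dCV at a few seconds).  The
permutation stage defaults to the reduced single-pass scheme with
200–1000 randomizations.

## Known limitations

- PLS1 two-class only; no multi-class, orthogonal or kernel variants.
- Single-batch QC correction; multi-batch alignment is out of scope.
- The null accuracy of cross-validated classifiers is known to sit
  slightly below 50 % on finite exchangeable data (each fold's model
  anti-learns noise); the permutation null mean reflects this by a
  fraction of a percentage point.
- Percentile CIs from 30 runs are coarse (nearest-rank at n = 30); for
  tighter intervals increase `runs`.
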