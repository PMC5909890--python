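# Methods

This note records the statistical methods implemented in `mzpanel` and the
rationale behind each design decision.

## Feature annotation

Untargeted features carry an observed m/z and an ESI polarity (NEG/POS).
Annotation assumes singly charged `[M−H]⁻` / `[M+H]⁺` adducts, so the expected
m/z of a compound with monoisotopic mass M is `M − 1.007276` (NEG) or
`M + 1.007276` (POS). A feature/compound pair is a candidate when
`|observed − expected| ≤ threshold` (default 0.01 Da).

Candidates are resolved greedily, best first: sorted by absolute mass error,
then m/z, then compound name (full determinism). Each feature receives at most
one primary annotation and each (compound, mode) pair annotates at most one
feature; later candidates that conflict with an assigned primary are kept as
flagged *secondary* matches for manual review. Unannotated features are dropped
— annotation doubles as data reduction, shrinking a few thousand raw features
to a few hundred named analytes. The greedy assignment is verified in the test
suite against an independent brute-force oracle.

Monoisotopic masses come from `pyteomics.mass` rather than a hand-rolled
isotope table: formula parsing and mass bookkeeping are standard, error-prone
primitives best delegated to an established library. Every library record that
stores both a formula and a mass must agree within 0.005 Da or it is rejected.

## Normalization

The chain is half-minimum imputation of non-detects (zeros/NaNs become half
the feature's minimum positive abundance), the generalized logarithm
`glog(x) = log2((x + sqrt(x² + a²))/2)` with `a = 1` (strictly increasing,
finite at zero, asymptotically `log2 x`), and per-feature autoscaling to mean
0, sample (n−1) standard deviation 1. Zero-variance features cannot be scaled
and are dropped with a warning. Fitted centring/scaling parameters can be
reused on held-out data.

Batch adjustment is a transparent per-feature location-scale map on the glog
scale: each batch's values are sent to the pooled grand mean and pooled
standard deviation, so per-batch feature means are *exactly* equal afterwards.
Population (ddof=0) standard deviations are used for both the batch and pooled
scale so that identical batches are an exact fixed point of the correction.
An SVD-based PCA (component signs fixed by making the largest-magnitude
loading positive) serves as the before/after diagnostic.

## Panel selection

All selectors consume an annotated, autoscaled table with a binary
case/control outcome and return a ranked analyte list; the top-k (default 10)
becomes a candidate panel, which is then restricted to analytes present in
both cohorts (`intersect_common`) before evaluation.

- **Univariate**: per-feature Mann-Whitney ROC AUC folded to ≥ 0.5 (so up- and
  down-regulated analytes rank comparably), |Welch t|, and |log2 fold change|
  (fold change from raw abundances when available).
- **LASSO selection frequency** (stability selection): 100 stratified 80%
  subsamples; in each, an L1 logistic regression with the penalty chosen by
  3-fold cross-validation and the 1-SE rule (strongest penalty within one
  standard error of the best accuracy); the score is the percentage of
  subsamples in which the analyte's coefficient is nonzero.
- **Linear-SVM RFE, ensembled**: the SVM cost parameter is fixed once by
  3-fold cross-validation; recursive feature elimination then removes 10% of
  the *remaining* features per step (elimination grows finer toward the end,
  fully resolving the top ranks) and is repeated on 15 stratified 80%
  subsamples; the score is the negated mean elimination rank. A single RFE run
  is dominated by multivariate overfitting noise when features outnumber
  samples several-fold; aggregating ranks across subsamples applies the same
  variance-reduction idea as stability selection and makes marker recovery
  reliable at the default study scale (63 samples, ~274 analytes).
- **PLS-DA VIP**: two-component PLS regression on the 0/1 outcome;
  `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, which satisfies
  `mean(VIP²) = 1` (asserted in tests).
- **Random forest**: impurity importance from 500 seeded trees.

## Evaluation

`PanelLogit` follows the model/results convention: the model holds the data
and panel; `fit()` returns a `PanelEvaluation` with coefficients, Wald
standard errors, fitted probabilities, and a discovery `ROCResult`. The
logistic fit is a statsmodels maximum-likelihood fit; if the MLE shows
(quasi-)separation — non-finite estimates/SEs or |coefficient| > 50 — a weakly
ridge-penalized fit (scikit-learn, C = 100) keeps the scores defined and the
result is flagged `ridge_stabilized` with no Wald SEs reported. Separation is
expected rather than exceptional here: ten analytes with standardized effects
around 1.5 can separate 63 samples perfectly.

Internal validation (`fit_cv10`) refits the model in each of 10 stratified
folds and pools the out-of-fold probabilities into a single ROC, matching the
usual "10-fold cross-validated AUC" reporting. External replication refits the
panel's coefficients on the independent cohort by default; applying the frozen
discovery model is available as a sensitivity analysis.

ROC AUCs are Mann-Whitney statistics with ties counted 1/2. The operating
point maximizes Youden's J with ties resolved toward higher specificity. AUC
standard errors use the Hanley-McNeil closed form

    SE(A) = sqrt[(A(1−A) + (n_c−1)(Q1−A²) + (n_n−1)(Q2−A²)) / (n_c·n_n)],
    Q1 = A/(2−A),  Q2 = 2A²/(1+A),

with 95% CIs `A ± 1.96·SE` clipped to [0, 1]; a stratified-bootstrap
percentile CI is available as an option and the closed form is tested to agree
with the bootstrap within 15% on binormal data. Two AUCs from *independent*
samples are compared with `z = (A1−A2)/sqrt(SE1²+SE2²)`, two-tailed p from the
standard normal, α = 0.05.

One embedded worked example deserves a note: for the 6-analyte linear-SVM
panel comparison (AUC 0.851 at 27/36 vs 0.830 at 31/53) the exact z is
0.29248, which rounds to 0.292 while the published table prints 0.293 — one
unit in the last printed digit, presumably from upstream rounding. Tests and
the `reference-stats` command therefore allow one printed ulp on that value;
the other two comparisons (0.502, 0.616; 0.633, 0.527) reproduce exactly at
3 dp.

## Synthetic two-cohort generator

`SyntheticConfig` defaults describe the study conditions: a discovery cohort
of 27 cases / 36 controls and a replication cohort of 31 cases / 53 controls,
each with every matchable library compound (~274) plus 1400 unannotatable
noise features per ionization mode. Compound features sit at their
adduct-expected m/z plus N(0, 0.002 Da) error; noise m/z are uniform on the
50–1200 scan range, rejection-sampled to lie at least 3 × 0.01 Da from any
library expected m/z in either mode, so they cannot annotate at the default
threshold by construction. Abundances are log2-normal (per-compound baselines
uniform on [10, 20] log2 units, σ = 1); the six marker analytes are shifted by
±1.5σ in cases, and four decoy analytes by ±1.2σ. The decoys are absent from
cohort 2, so a data-driven top-10 discovery panel shrinks on cross-cohort
intersection — reproducing the panel-refinement phenomenon. Cohort 2 carries a
2× multiplicative batch shift. A single-feature binormal effect d has
theoretical AUC Φ(d/√2), which the generator reproduces within sampling error
(tested at n = 500/500 within 0.02).

Known realism limit: marker effects are generated independently across
analytes, so a 6-analyte logistic panel at |d| = 1.5 attains near-perfect
AUCs (≈ 0.99–1.0) instead of the 0.75–0.90 range typical of correlated
metabolomes. The generator is built to test the machinery (recovery,
intersection, batch correction, H₀ acceptance between internal validation and
replication), not to mimic panel AUC magnitudes; introducing a realistic
correlation structure would be the natural extension.

## Determinism and test scaling

Every stochastic routine takes an explicit seed and uses
`numpy.random.default_rng` (the simulator keys streams as
`[seed, cohort_index]` so cohorts are independently reproducible).
scikit-learn components with internal randomness (liblinear, forests,
fold shuffling) receive derived seeds. Simulation-scale tests run at
package-chosen reduced sizes — e.g. an 8-seed end-to-end sweep, 30 LASSO
subsamples in the workflow tests, and a few hundred bootstrap replicates —
with tolerances set to match those sample sizes; the library defaults remain
at the full study scale (100 subsamples, 50-seed-capable workflow).
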