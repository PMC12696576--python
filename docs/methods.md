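# Methods

## Scope and model

`rcads_ml` implements a screening-analysis pipeline for RCADS-47
questionnaire cohorts: scoring and three-class labeling, internal
consistency analysis, consensus feature screening, copula-based
multinomial data augmentation, and multi-class classifier development.
Because clinical questionnaire datasets of this kind are small and not
publicly shareable, the package ships a first-class synthetic cohort
generator that reproduces the relevant structure of such a sample and
serves as the ground-truth oracle for every downstream stage.

## Scoring and labeling

Raw totals are the sum of the 47 item levels (0–3). T-scores are
computed against a normative table keyed by (grade band, sex):

    T = 50 + 10 · (raw_total − mean) / sd

and labeled Normal (T < 65), Borderline (65 ≤ T < 70) or Clinical
(T ≥ 70). The Borderline band is read as the half-open interval so the
three labels partition the real line (a T of 69.4 is Borderline).
Official published norm tables are deliberately not reproduced;
`build_norms` constructs a synthetic normative table as the mean/SD of
raw totals in a large simulated Normal-class reference sample (default
10 000 records, pooled across demographic cells because the generator's
items do not depend on demographics; a per-cell mode exists and
requires ≥ 1000 reference records per cell). External tables can be
supplied as JSON.

The item–subscale key (MDD 10, GAD 6, OCD 6, PD 9, SAD 7, SP 9 items)
ships as an editable YAML resource; any partition of the 47 items into
the six subscales is accepted.

## Synthetic cohort generator

One latent severity factor per subject: class c ∈ {Normal, Borderline,
Clinical} is drawn from the configured mix, θ ~ N(shift_c, 1), and each
item's latent value is a·θ + √(1−a²)·ε with per-subscale loading a,
discretized at per-item cutpoints into levels 0–3. Item latents are
unit-variance by construction, so category probabilities have the
closed form of normal-CDF differences mixed over classes; these are the
`GroundTruth.item_probs`. True within-subscale mean Spearman
correlations are estimated on a large internal sample (default
n = 50 000).

Defaults are the emulated study conditions: n = 138 with missingness
injected completely at random into demographics only (12 missing sex,
46 missing grade, 9 both — hence listwise deletion retains 89), class
mix (0.55, 0.07, 0.38), 62% girls, grade distribution proportional to
the sample's grade margin (grades 2–12), loading 0.5 per subscale
(within-subscale Spearman ≈ 0.35, in the weak-to-moderate range
typical for such scales), class shifts (0, 1.2, 2.0), shared cutpoints
(0.5, 1.4, 2.3) giving right-skewed Likert marginals. The generator
does not emulate informative missingness, response styles
(acquiescence, extreme responding), cross-subscale comorbidity beyond
the single factor, or demographic dependence of item responses —
passing tests therefore demonstrate correctness of the pipeline's
mechanics and calibration under an idealized one-factor regime, not
performance on real clinical data.

Drawn classes and score-derived labels are both exposed: they need not
agree (the scored mix is shifted toward Normal relative to the drawn
mix because the Borderline/Clinical shifts translate to less than
1.5/2 SD of the Normal-class raw-total distribution), and the
agreement itself is testable.

## Reliability

Cronbach's alpha uses the variance form α = k/(k−1)·(1 − Σ var_i /
var_total) with n−1 denominators; tests cross-check it against the
independent covariance-matrix form k/(k−1)·(1 − tr(C)/ΣC) to 1e-12.
Alpha-if-item-deleted recomputes α on the remaining k−1 items.
Inter-item summaries use Spearman correlations with average ranks
(ordinal data); pairs involving constant items are excluded and
counted. The report covers the 47-item internalizing scale, the
anxiety scale (all items outside the depression subscale) and the six
subscales.

## Consensus feature screening

Three screens per item against the class label: Pearson chi-square test
of independence on the observed contingency table (no continuity
correction; expected-count < 5 warnings are logged, not silently
switched), Spearman rank correlation with the t-approximation p-value,
and recursive feature elimination ranked by random-forest impurity
importance (one feature removed per step, subset size chosen to
maximize mean stratified 5-fold CV accuracy, ties to the smaller set;
backed by scikit-learn's RFECV). An item is eliminated only if both
p-values exceed α (default 0.05, configurable) *and* RFE leaves it
out — unanimity across all three methods.

## Augmentation model

Fitted from a complete cohort: per-item multinomial category
frequencies, empirical sex/grade marginals, and per-subscale target
correlation. The "correlation of a subscale's questions" is read as
the mean pairwise inter-item Spearman within the subscale — the
exchangeable reading that directly parameterizes an equicorrelated
copula; an item-to-subscale-total mode is available behind
`rho_mode="item_total"`.

Sampling discretizes an equicorrelated multivariate normal through
each item's categorical CDF, so marginals are exact by construction.
Discretization attenuates rank correlation, so the latent Gaussian
correlation is calibrated: the induced pairwise Spearman at a given
latent ρ is computed deterministically via bivariate-normal rectangle
probabilities (96-node Gauss–Legendre quadrature of the conditional
CDF, abs. error ~1e-10) and the mid-distribution representation of
Spearman's ρ with ties, then inverted by monotone bisection on
ρ ∈ [0, 0.9995] to within 0.01 (≤ 40 steps; unattainable targets are
clamped with a warning). A fixed-seed Monte-Carlo path would also
satisfy the interface but its ~0.005 noise would consume half of the
0.01 calibration tolerance, so the quadrature is the default and only
path.

Subscale blocks are sampled independently (no cross-subscale
correlation), mirroring the per-subscale generation procedure; this is
a known structural simplification — the synthetic raw-total
distribution has lighter tails than the original because all
cross-subscale covariance terms are zeroed. Demographics are drawn
independently from their marginals. Synthetic records receive labels
by deterministic scoring against the norm table (labels are never
sampled). Hybrid datasets concatenate original + synthetic at ratios
1:4–1:20, original records first.

Fidelity is assessed per item by two-sided Mann–Whitney U
(tie-corrected normal approximation) and total-variation distance
between level distributions, and per subscale by the achieved-vs-target
mean Spearman gap. The multinomial goodness-of-fit helper tests counts
against supplied reference probabilities with df = (nonzero-reference
categories − 1); it cannot "confirm" a distribution family, only fail
to reject the given reference.

## Model development

SMOTE is hand-implemented to its textbook definition (synthetic point
= x + u·(x_nn − x), u ~ U(0,1), k = 5 nearest same-class Euclidean
neighbors, originals preserved verbatim); interpolated values remain
continuous by default (a rounding mode is not provided because the
balanced data is used only for model fitting). The historical protocol
balances the full dataset and then splits 80/20 stratified (test size
= ⌈0.2n⌉) — with class counts 49/6/34 this yields exactly 147 = 3×49
balanced records and a 117/30 split. Balancing before splitting leaks
interpolated copies of test information into training; the package
reproduces that order by default with a prominent warning and offers
`order="split_first"` as the sound alternative.

Six families are tuned by exhaustive grid search (stratified 5-fold CV
on accuracy, ties broken by grid order): RF (n_estimators 50/100/200 ×
max_depth None/10/20/30 × min_samples_split 2/5/10 × min_samples_leaf
1/2/4 = 108 candidates), SVM (C 0.1/1/10/100 × kernel linear/rbf ×
gamma scale/auto), LR (C 0.01–100 × penalty l1/l2, liblinear solver —
the l1/l2 grid is the natural reading of the protocol's LR penalty
options), DT (as RF minus n_estimators, plus criterion gini/entropy),
KNN (k 3/5/7/9 × weights uniform/distance × metric
euclidean/manhattan), NB (no tuned hyperparameters). Reports give
per-class precision/recall/F1 with supports, accuracy, macro and
weighted averages, the 3×3 confusion matrix, fold scores and best
parameters. Models are compared by paired two-sided t-tests on fold
accuracies (identical folds → p = 1; constant nonzero differences are
degenerate and raise). An external-validation harness scores a frozen
model on any complete cohort.

## Pipeline and reproducibility

`run_pipeline` derives one seed per stage from the master seed by
SHA-256 of "master:stage" (mod 2³¹), executes the enabled stages in
order and writes a manifest with per-stage seeds, library versions and
SHA-256 hashes of every output; reruns with the same config + seed
reproduce identical hashes.

## Suite problem sizes

The default test suite uses scaled problem sizes chosen as the
package's own verification budget: generator checks at n = 10⁴–10⁵,
copula calibration checked against 10⁶-sample brute-force oracles,
augmentation fidelity over 20 seeded runs at ratio 1:4, planted-null
consensus recovery over 50 seeded runs at n = 356 with 30-tree forests
inside RFE (the 100-tree default is used for single-run analyses), and
the end-to-end screening property over 20 seeds with 10⁴-record
normative references.

## Known limitations

- The independent-block copula under-disperses raw totals; Clinical
  and low-Normal ranges are under-represented in synthetic data. This
  is faithful to the per-subscale generation procedure, and is the main
  reason classifiers trained on hybrid data lose a few points of
  macro-F1 relative to training on native cohorts.
- The Borderline class occupies a five-T-point band; with realistic
  cohort sizes its support is ~6 records and per-class F1 for it is
  intrinsically unstable. Axis-aligned tree ensembles approximate the
  underlying sum-threshold rule imperfectly, capping Borderline F1
  well below the other classes.
- The balance-first protocol overstates test metrics; use
  `split_first` for honest estimates.
- Chi-square screens on 4×3 tables at n ≈ 89 have many expected counts
  below 5; p-values are approximate and flagged.
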