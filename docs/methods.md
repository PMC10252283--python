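# Methods

## The measurement and its quality gate

One sample is eight RT-qPCR reactions: six marker miRNAs and two controls.
Ct (cycle threshold) is log2-scaled abundance — one cycle is roughly a
two-fold difference, and lower Ct means more template. Ct values are
accepted in the window (0, 45]; 45 covers standard protocol cycle counts,
and values outside the window are a data error, not a missing value.

The QC gate operationalizes the assay's two control reactions:

* **ACTB** (conserved non-translated β-actin region) tracks the quantity
  and quality of input material; a sample fails when Ct(ACTB) is *strictly
  above* 34.
* **cel-miR-39** spike-in (a *C. elegans* miRNA added at fixed
  concentration before processing) monitors enzymatic efficiency; a sample
  passes only when its Ct is *strictly under* 18.5.

The two bounds deliberately have opposite inclusivity (34.0 passes, 18.5
fails); both are configurable. Samples missing any of the six marker Cts
are excluded rather than imputed: the predictor stage needs all six
values, and a cap-at-max-cycles imputation would silently bias the ratios.
The spectrophotometric criteria (RNA ≥ 100 ng/µL, A260/280 ≥ 1.7) apply
before the assay in the wet-lab workflow, so they are off by default and
enforced only via `enforce_wetlab_fields`. QC never raises — it partitions
the cohort and attaches reason codes (`ACTB_HIGH`, `SPIKEIN_HIGH`,
`MISSING_CONTROL`, `MISSING_MARKER`, `LOW_RNA`, `LOW_PURITY`) so cohort
attrition is auditable.

## Reciprocal-pair predictors

There is no accepted reference gene for normalizing miRNA RT-qPCR in
cervical epithelium. The panel sidesteps the problem by pairing miRNAs
that move in opposite directions with disease: each of the three
HSIL-up-regulated markers (miR-145, miR-1246, miR-1290) against each of
the three stable/down-regulated references (miR-21, miR-29b, miR-451a),

    χᵢ = 2^(Ct_marker − Ct_reference),   i = 1…9 (marker-major order).

Any per-sample factor that shifts all Cts equally — input quantity,
extraction efficiency — cancels in the difference, so χ is exactly
shift-invariant (a tested, exact property). The orientation convention
(marker Ct first) means up-regulation in HSIL *lowers* χ; the classifier
is orientation-agnostic, but the convention and the marker-major index
order are fixed so feature importances are reproducible across runs.
Amplification efficiency is assumed to be perfect (base 2), as in the
assay's own read-out.

## The ensemble score

The classifier is bootstrap aggregation of binary Gini decision trees:

* each of `n_trees` (default 100) trees is grown on a bootstrap resample
  of the training samples;
* at every node `features_per_split` (default 3 = ⌊√9⌋) predictor indices
  are drawn without replacement and the axis-aligned split minimizing
  weighted Gini impurity is taken, thresholds at midpoints between
  adjacent distinct values, first minimum winning (deterministic
  tie-break);
* growth stops at purity, fewer than `2·min_leaf` samples, exhausted
  depth (`max_depth`, unlimited by default), or when no split reduces
  impurity; leaves store class counts.

A sample's **miR-CERVIX value** is the mean over trees of the leaf HSIL
frequency — soft voting, in [0, 1] by construction. Hard majority voting
is available behind `hard_voting` for sensitivity analysis. Feature
importances are normalized mean impurity decrease, summing to one; when a
degenerate fit leaves nothing to attribute (every bootstrap resample
single-class), the importances fall back to uniform rather than 0/0.

Scores are produced by k-fold cross-validation (default k = 20): folds
are a random partition, stratified by class by default so every training
split retains both classes even at k = 20 with unbalanced groups; each
sample is scored exactly once by the ensemble trained without its fold.
The alternative reading of "average all results" — averaging all k fold
models' predictions — is provided as `score_external` for samples outside
the training cohort. All randomness derives from one integer seed through
`numpy.random.SeedSequence`, making whole runs byte-reproducible.

Standard steps go through standard libraries: fold assignment uses
scikit-learn's `StratifiedKFold`/`KFold`, the ROC sweep and trapezoidal
AUC use `sklearn.metrics`, and the rank tests use `scipy.stats`. The tree
and bagging code itself is implemented here, and is cross-checked in the
test suite against scikit-learn's independent random-forest implementation
as well as against a brute-force tree-walking oracle.

## Interpretation and evaluation

A score at or above the cut-off is called positive (the inclusive
convention favours sensitivity at the screening cut-off; it is flippable
via `positive_at_cutoff`). Two cut-offs span the clinical uses: 0.49
distinguishes normal from pathological (screening), 0.77 confirms HSIL
with high specificity (surgery decisions). The three-band read-out
(normal-leaning < 0.49 ≤ elevated < 0.77 ≤ HSIL-confirming) mirrors the
kit's green–yellow–red colour ramp.

With HSIL as condition-positive, the report contains confusion counts and
sensitivity, specificity, PPV, NPV, accuracy (precision ≡ PPV) as
percentages, rounded to two decimals for presentation while the exact
values are kept internally. Zero-denominator rates are reported as
undefined (None), never as 0. The ROC is swept over all distinct score
thresholds plus sentinels; its trapezoidal AUC equals the concordance
probability with ties counted half (tested exactly against an O(n²)
pair-counting oracle). Group differences use the Mann–Whitney test (exact
enumeration when the smaller group has ≤ 8 observations and no ties,
otherwise tie-corrected normal approximation with continuity correction)
for NILM vs HSIL, and the tie-corrected Kruskal–Wallis test across
NILM/HPV(−), HSIL/HPV(−), HSIL/HPV(+).

## The synthetic cohort generator

The generator emulates the two-group study cohort at Ct level:

* group sizes 114 NILM / 112 HSIL; HPV positivity 72/101 within HSIL and
  1/87 within NILM;
* baseline marker Cts in the 23–29 cycle range, ACTB at 28, spike-in at
  17.5 — plausible qPCR magnitudes, documented as arbitrary;
* HSIL shifts the markers by fixed ΔCt effects: miR-145 −1.2, miR-1246
  −1.0, miR-1290 −0.8 (up-regulated, lower Ct), miR-29b +0.8, miR-451a
  +1.0 (down-regulated), miR-21 0 (the stable normalizer). No per-miRNA
  fold changes are published for this panel, so these effect sizes are
  calibration choices, set once so the default pipeline shows clear but
  imperfect separation — overlapping score distributions rather than a
  perfect classifier;
* HSIL/HPV(−) samples receive effects attenuated by `effect_hpvneg_scale`
  (default 0.6), reproducing the intermediate position of that group
  between NILM and HSIL/HPV(+);
* noise is two-level Normal: a per-sample offset (sd 1.5 cycles) shared
  by all eight reactions models input-quantity variation — exactly the
  nuisance that reciprocal pairs cancel — plus independent per-reaction
  noise (sd 1.25 cycles). Control reactions get a smaller own noise
  (sd 0.3 cycles): ACTB shares the sample offset because it tracks
  material quantity, while the spike-in does not, since it is added at
  fixed concentration after isolation;
* QC failures are injected through the control reactions only, with
  probability 38/226 per sample, split evenly between an inflated ACTB Ct
  (> 34) and an inflated spike-in Ct (≥ 18.5).

What the generator does **not** model: two-tailed RT chemistry and primer
efficiency, plate position effects, non-Normal Ct error (e.g. stochastic
late-cycle amplification), missing-at-random marker dropout correlated
with abundance, and any real biological covariance structure among the six
miRNAs beyond the shared offset. Consequently, passing tests demonstrate
the pipeline's correctness and its statistical behaviour under the assumed
noise model — not the clinical performance of the panel on patient
material, which cannot be reproduced without the original cohort.

## Problem sizes and numerical choices

The default end-to-end run (226 simulated samples, 100 trees, 20 folds)
takes a few seconds. Statistical properties that need replication use
reduced sizes chosen for quick, stable estimates: the label-permutation
null (expected cross-validated AUC 0.5) uses 20 seeds × 60 samples ×
25 trees × 5 folds and checks the mean against its own Monte-Carlo
standard error; importance recovery (a single informative predictor should
top the importances) uses 20 seeds × 100 samples × 50 trees and requires a
90% hit rate. Exact properties — χ shift invariance, AUC vs pair counting,
the enumerated Mann–Whitney p of 0.1 for {1,2,3} vs {4,5,6} — are asserted
to floating-point precision.

Known limitations: the ensemble's probability calibration is whatever
bagging produces (no isotonic/Platt step, matching the assay's read-out);
the published cut-offs are treated as external configuration, not
re-derived (no Youden optimization); confidence intervals for AUC and
rates are out of scope; and the evaluation path treats an external binary
test (such as an HPV screen) as scores in {0, 1}, for which a ROC is not
meaningful.
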