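# Methods

`embryoscreen` implements an end-to-end analysis for classifying positively
implanted cleavage-stage embryos into first-trimester miscarriage (MC)
versus live-birth (LB) outcomes from time-lapse-derived measurements. The
clinical source data are private, so a first-class synthetic-data module
defines the study conditions under which every stage is exercised and
tested. This note records the model, the design choices that were genuinely
open, the numerical conventions, and what the synthetic experiments do and
do not demonstrate.

## The feature catalog (314 features)

Each embryo is described by exactly 314 named features in a frozen order
(`embryoscreen.catalog`, rendered in `docs/data_dictionary.md`):

* **Morphology (35)** — measured at the reference frame, the third frame
  before pronuclear fading (~1 h before tPNf), central focal plane:
  blastomere-size symmetry and fragmentation grades at the 2- and 4-cell
  stages (4), pronucleus size (7) and location (3), nucleolus-precursor-body
  (NPB) counts (4) and spatial arrangement (11), the first-cleavage-plane
  orientation angle (1, consumed as an annotation — it is measured from a
  z-stack, which this package does not process), and ooplasm / zona
  pellucida radii (5). The headline members are
  `f1 = max_{i,j} d_ij / R_PN` (maximal pairwise NPB distance in the
  *small* PN over its radius) and `f2` = ooplasm radius.
* **Morphokinetics (117)** — the nine annotated event times tPNa, tPNf,
  t2…t8 (hours post-ICSI), all C(9,2)=36 pairwise intervals
  `t_later − t_earlier`, 36 pairwise ratios `t_later / t_earlier`, and 36
  DLR values (below). Pairs are always taken in chronological catalog
  order, so intervals are non-negative whenever the chronology invariant
  holds.
* **PN dynamics (162)** — summaries of the two pronucleus trajectories,
  tracked forward (tPNa→tPNf) and in reverse: step-size and velocity
  statistics (72), inter-PN distance statistics (18), and PN-to-embryo-center
  distance statistics, raw and normalized by the ooplasm radius (72).
  `f5` is the ratio of the maximal step of the large PN to that of the small
  PN (forward episode), and `f6` the absolute difference of the two
  PN-to-center distances at the tPNf frame.

Only the group cardinalities and f1/f2/f5/f6 are externally pinned; the
remaining per-feature definitions inside each group (e.g. which nine step
statistics, which eleven NPB spatial measures) were an open choice. The
catalog fixes them once so the 314 total is testable; the choices favour
plain, interpretable summaries (min/max/mean/median/SD/first/last plus a
path-length or range term) and include the cf1/cf3-style "difference of the
smallest steps / slowest velocities" pair features that the redundancy
analysis expects to correlate with f5-type ratios.

Conventions: image origin top-left, x rightward, y downward, pixel units;
time in hours post-ICSI; frames indexed from 0. A single NPB yields a
maximal pairwise distance of 0 ("measurably compact"); zero NPBs yield a
missing value ("unmeasured") — the two are deliberately distinct. The ratio
of maximal steps is missing when the small PN never moves. Missingness is
data, never an error, and propagates as NaN.

## DLR — distance from linear regression

Event-time pairs of LB embryos are strongly linearly correlated. For each
of the 36 event pairs (i, j), an ordinary-least-squares line
`t_j = a·t_i + b` is fitted **on LB embryos only** (complete cases per
pair; pairs with fewer than two cases or a degenerate predictor yield no
line). An embryo's DLR for that pair is its perpendicular distance from
the line:

    DLR_ij = |a·t_i − t_j + b| / sqrt(a² + 1)   [hours]

DLR is reported unsigned ("shortest distance"); a signed variant exists
behind an explicit function but is excluded from the catalog. Within
cross-validation the package defaults to refitting the lines on the LB
members of each training split (`make_dlr_refit`), which is the
leakage-free rule; the single-pass "global" fit over all LB embryos
(`build_feature_table(..., dlr_fit="global")`) reproduces the simpler
one-shot behavior and is the default when building a static table.

## PN tracking

Pronuclei are tracked with a translation-only, iterative, pyramidal
Lucas-Kanade solver written in this package (`tracking.lk_track_points`):
15 mutually non-adjacent pixels (minimum spacing 2 px, fixed seed) are
sampled inside each PN disc at the episode's starting frame and followed
through consecutive frames with a 15×15 window (radius 7), two pyramid
levels, bilinear resampling, and up to 20 Gauss-Newton iterations
(convergence tolerance 0.01 px). The PN position per frame is the mean of
the surviving tracks; a track is dropped when its window's structure-tensor
minimum eigenvalue falls below 5 gray²/px (untextured window) or it leaves
the frame, and a trajectory with fewer than 8 of 15 survivors is flagged
unreliable. Positions are reported in the embryo frame of reference — the
per-frame ooplasm center (ground truth on synthetic data, intensity
centroid otherwise) is subtracted — making the dynamics features invariant
to global scene translation up to the solver tolerance. Both forward and
reverse episodes are computed and kept as separate feature groups
(direction is a catalog axis) rather than merged, since there is no
principled single way to average them.

Trajectories are classified from two thresholds: *stationary* when the
end-to-end distance is below `θ_s·R_PN` (default θ_s = 0.5), otherwise
*linear* when straightness (end-to-end over contour length) is at least
θ_l = 0.8, else *curved*. The thresholds are configurable; the defaults
were chosen so that a semicircular arc (straightness 2/π ≈ 0.64) is
curved and near-collinear paths are linear.

The tracker is cross-checked in the tests against scikit-image's dense
iterative Lucas-Kanade flow (`optical_flow_ilk`) and against ground-truth
kinematics; on the synthetic suite (mixed curved/linear/stationary motion,
additive noise SD 3 gray levels) the position error never exceeds one
quarter of the PN radius, most of it a constant offset between the
seed-point centroid and the disc center.

## Feature screening cascade

1. **Distances.** Per feature, the MC-vs-LB two-sample KS p-value and a
   histogram KL divergence estimate. The KL estimator (the literature
   leaves it open) uses a shared equal-width histogram over the pooled
   range, 20 bins, a Laplace pseudocount of 1, direction KL(MC‖LB), in
   nats. At clinical sample sizes this estimator carries an upward bias of
   roughly (bins−1)/(2·n_MC) ≈ 0.1 nat, which the threshold grid absorbs.
2. **Threshold grid.** Six KS thresholds spaced +0.05 from a base value and
   three KL thresholds spaced −0.1 define 18 qualified subsets
   (p < λ_KS and KL > λ_KL). The base values are configuration
   (defaults λ₁^KS = 0.05, λ₁^KL = 0.25), chosen so that roughly 1–30 % of
   features qualify across the grid on synthetic cohorts. Subsets are
   nested by construction; identical subsets are scored once.
3. **Monte-Carlo CV scoring.** Each subset is scored by the mean validation
   AUC of both model families over stratified 90/10 splits (100 by default),
   with per-fold median imputation fitted on the training split. The ten
   best subsets — ranked by the *sum* of the RF and GB mean AUCs, ties to
   the smaller subset — are united; features are ranked by each family's
   native importance averaged over all relevant CV fits, ranks averaged
   across families, ties by catalog order; the top 8 are kept together with
   their Pearson correlation matrix.
4. **Backward elimination** from 8 down to 1: at each step the feature
   whose removal least harms the combined AUC is dropped (all candidates in
   a step share fold splits — common random numbers); the best-scoring
   subset along the series is retained.
5. **Two-step forward selection**: feature *pairs* from a ranked pool are
   added jointly; the best pair's lower-catalog-index member is kept
   (documented arbitrary tie-break), for at most three cycles, stopping
   when the best pair no longer improves both families.

All screening operations see only the train/validation table; the held-out
test partition is constructed balanced (equal MC/LB) and disjoint, and a
hash-comparison guard test verifies that permuting test labels changes no
screening or training artifact.

## Prediction models and evaluation

Defaults: gradient boosting (XGBoost) with 6 trees of depth 1 and learning
rate 0.25; random forest (scikit-learn) with 65 trees of depth 3 and Gini
splits. These reflect the small-cohort regime (strong regularization via
tiny trees). Hyperparameter search, when requested, is seeded random search
over the documented ranges (RF: max_depth [1,3], max_features [0.1,0.5],
min_samples_leaf and min_samples_split [25,50], n_estimators [1,100]; GB:
learning rate [0.01,0.3], min_child_weight [25,40], max_depth [1,3],
subsample [0.1,1], colsample_bytree [0.1,0.4], n_estimators [1,50]) with
mean CV AUC as the objective. Note that GB's min_child_weight range is only
satisfiable at a few hundred training embryos and that a random draw may
fall below the fixed defaults — the search reports its full trace so this
is visible.

The Monte-Carlo ensemble predictor averages the predicted MC probabilities
of the 100 fold-models ("averaging the cross-validated model weights" is
operationalized as score averaging; averaging tree parameters is
ill-defined). The integrated classifier averages the RF and GB ensemble
scores. Validation AUC is reported from out-of-fold averaged scores (each
embryo's score averaged over the folds that held it out), which is the
validation-side counterpart of the fold-averaged test score; per-fold AUCs
provide the confidence band. AUC is computed by the Mann-Whitney rank
statistic with ties counted one half, and is verified against brute-force
concordant-pair counting. Confusion matrices are reported at two named
operating points — precision-favoring (high MC threshold) and
sensitivity-favoring (low MC threshold) — chosen by default to maximize
F(0.5) and F(2) on the supplied scores, or fixed explicitly from a
validation precision-sensitivity curve.

## Explanation

Attributions are exact additive per-feature decompositions of each
fold-model's output, averaged across folds: XGBoost's native TreeSHAP
(`pred_contribs`) for GB, in log-odds margin units, and additive tree-path
(Saabas) contributions for RF, in probability units — each split node
passes the change in positive-class fraction to its split feature, so
`base + Σ attributions = model output` holds exactly for both routes (this
identity is asserted to 1e-6 in the tests). Feature importance for
*accurate* prediction uses aSHAP: the mean absolute attribution per
feature, sign-flipped for embryos misclassified at the 0.5 ensemble-score
threshold (configurable). A cohort in which every embryo is misclassified
therefore has non-positive aSHAP everywhere.

## Synthetic data: what it emulates, and what it does not

`generate_cohort` draws morphokinetic profiles from a chain of
consecutive-event linear regressions (slopes ≈ 1, residual SDs 1.2–2.2 h)
anchored at tPNa ~ N(8, 1.5²) h with PN visibility tPNf − tPNa ~ N(17,
2.5²) h, and enforces strict chronology; geometry annotations (radii, PN
placement, NPB coordinates, grades) are drawn from ranges typical of
zygote imaging at ~0.3 µm/px scale. The default composition is 96 MC / 368
LB. With the default t2–t3 residual SD of 1.3 h the generated t2–t3
regression is tight (R² ≈ 0.88 at the defaults, asserted in the test
suite), matching the strength of morphokinetic correlations seen in
clinical cohorts. `generate_feature_table`
emits the feature-space analogue directly: 314 unit-normal columns with
class-conditional mean shifts (Cohen's d) planted on named features —
the simplest structure under which screening recovery is provable — plus
completely-at-random missingness and a day-3-transfer truncation of late
events in the annotation tables.

Movies render flat-intensity discs (background 30, ooplasm 120, PN 175,
NPB 60 gray levels) with smoothed edges (≈2 px), NPB spots placed by
non-overlap rejection sampling, rigid PN motion (translation, rotation
about the ooplasm center, or rest), and additive Gaussian noise — enough
texture for Lucas-Kanade, with exact ground truth, and deliberately not
photorealistic.

Consequently, passing tests show that the pipeline's machinery is correct
and that planted class differences of realistic size are recovered under
the study's sample sizes and imbalance. They do not show that real MC and
LB embryos differ on these features, nor reproduce clinical AUC values —
those depend on the private cohort. Feature distributions in the clinic are
neither normal nor independent, real microscopy has focus drift, occlusion
and intensity variation that the renderer omits, and morphokinetic
annotation error is not modeled.

## Problem sizes and numerical choices

Desk-scale runs use reduced Monte-Carlo settings chosen as this package's
own defaults for quick experiments: the screening-cascade recovery
experiments use 5-fold Monte-Carlo CV inside the cascade with a forward
pool of 5 and 96/368 cohorts (the planted effects d = 0.8, 0.7, 0.6, 0.5,
0.4 sit on the analogues of f1–f5); ensemble metrics use the full 100
folds. The acceptance script measures tracking error over 12 movies of 20
frames and screening recovery over 6 cascade seeds. Degenerate inputs are
handled explicitly: empty cohorts are valid, constant features get KS p = 1
and KL = 0, features with fewer than two values per class are skipped and
flagged, a constant-label table refuses to fit, and single-class partitions
make AUC an explicit error rather than a silent NaN. Ties in wrapper
selection are always resolved toward the lower catalog index, making every
cascade deterministic under a fixed seed.

## Known limitations

* The RF attribution route is the tree-path (Saabas) decomposition, not
  interventional Shapley values; it is exactly additive and fold-averaged,
  but can distribute credit differently from TreeSHAP for deep trees (at
  depth 3 the difference is small).
* The sparse Lucas-Kanade solver assumes locally rigid translation;
  strong rotation within a window or PN-PN occlusion would degrade it.
  Tracks the renderer produces never occlude.
* The aSHAP weighting (magnitude sign-flip at a fixed score threshold) is
  one documented choice among variants; it is isolated behind a single
  function (`modeling.ashap`).
* The forward-selection pool is capped (ranked by screening importance)
  rather than the full screened-out complement; exhaustive pair search over
  hundreds of features is not feasible and was not the intent.
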