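# Methods

This note documents the models and procedures the package implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Landmark features

A *landmark scheme* declares an ordered set of named anatomical points,
each midline or a member of a left/right pair. Features are built in
three steps:

1. **Pairwise distances.** Euclidean distances between all non-missing
   landmark pairs (mm). Invariant under rigid motion by construction.
2. **Symmetric averaging.** The mirror image of the unordered pair
   {a, b} is {mirror(a), mirror(b)}; the two members of each mirror
   class are replaced by their arithmetic mean under a canonical name
   (the class member whose labels sort first in scheme order — with the
   default numeric schemes, the left-side form). A scheme with m midline
   landmarks and p bilateral pairs yields
   `C(m,2) + m·p + p(p−1) + p` unique features: midline-midline pairs
   are self-mirrored, midline-side distances merge two-to-one, distances
   between two different bilateral pairs merge two-to-one both same-side
   and crossed, and each within-pair width is its own mirror. The
   default human scheme (m=8, p=8) gives 156; the rodent dorsal scheme
   (m=3, p=8) gives 91. These compositions are fixed as defaults because
   they are the unique ones reproducing those counts at 24 and 19
   landmarks; schemes are fully configurable.
3. **Geometric-mean normalization.** Each subject's distances are
   divided by the geometric mean of all their finite distance features,
   removing overall size: the result is unit-geometric-mean,
   dimensionless, and invariant to uniform scaling. Distances touching a
   missing landmark are carried as NaN, excluded from the geometric
   mean, and dropped per-feature downstream; when only one member of a
   mirror class is available it represents the merged feature alone.

Angles (degrees, interior, range (0, 180]) are triangulated from
landmark triples named in the scheme. The default triples put the
nasomental angle at the pronasale between nasion and pogonion and the
labiomental angle at the sublabiale between labiale inferius and
pogonion; the exact clinical triples belong to the acquisition protocol
and should be set in the scheme configuration when known. Human label
semantics follow the convention that left labels 1-8 pair with right
labels 9-16 (1/9 frontotemporale, 2/10 lateral brow, 4/12 medial brow,
5/13 exocanthion) and 17-24 are midline; this assignment reproduces the
standard feature naming ("2-4", "4-12", ...) used for facial CNV effect
maps.

Mandibular length and width come from three landmark-group centroids
(lower incisors, left ramus, right ramus): MW is the inter-ramus
centroid distance; ML is defined here as the mean of the two
incisor-to-ramus distances, the symmetric choice consistent with
averaging left and right forms elsewhere.

## Genotype association

Human cohorts: for each feature and each contrast (DEL vs CTRL, DUP vs
CTRL — two separate two-group models, not one three-level model), the
mean model is

    feature ~ genotype + age + head_circumference + bmi + sex + PCs
              (+ genotype:sex) + (1 | family)

fitted by maximum likelihood. The genotype-by-sex interaction is
screened per feature by its own ML likelihood-ratio test at 5% and
included only when significant; the genotype terms are then tested by a
likelihood-ratio test of nested ML fits (chi-squared reference, df = 1,
or 2 with the interaction). ML rather than REML is used throughout
because likelihood ratios on fixed effects require it. Two ancestry PCs
are used by default (configurable), and a sensitivity mode re-runs the
models without PCs.

**Mixed-model fitting.** The single-random-intercept model is fitted by
an exact profiled likelihood: for a variance ratio
θ = σ²_family/σ²_residual the marginal covariance inverts in closed form
per family (Sherman-Morrison), β and σ² profile out, and the remaining
1-D problem is solved by bounded Brent iteration on log θ with an
explicit check of the θ = 0 boundary (where the fit reduces exactly to
OLS). This guarantees that nested log-likelihoods are exactly
comparable; generic gradient optimizers on this surface frequently stop
short near the boundary, which produces negative LRT statistics and
inflates the test. The fitter is cross-checked in the test suite against
statsmodels MixedLM and R lme4 (agreement to ~1e-6 in log-likelihood
where they converge, with our profiled optimum never below theirs).
Standard errors are GLS (`σ̂² (XᵀV⁻¹X)⁻¹`), family effects are BLUPs
with the usual shrinkage `θn/(1+θn) · mean residual`.

Calibration: at n=200 subjects in 60 families the ML LRT's empirical
type-I error is ≈0.05-0.065 across simulation seeds — the small upward
bias expected of chi-squared references for ML fits at these sizes.

Rows with missing response or predictors are dropped per feature and
counted; fewer than two families triggers a fixed-effects-only fallback
with a warning; singular or non-convergent fits yield flagged rows that
are excluded from the multiplicity family (count logged), never crashes.

Multiplicity: Holm step-down (FWER) and Benjamini-Hochberg step-up
(FDR), both always reported, computed per contrast over all converged
features (the human family is the 158 features per contrast). The
implementations delegate to statsmodels and are pinned to brute-force
reference implementations in the tests.

Missing ancestry PCs are imputed by copying the PC vector of the sibling
(same two parents) nearest in age that has PCs, else of a parent chosen
uniformly at random under the run seed; subjects with no eligible
relative stay missing and are flagged rather than dropped.

Rodent cohorts use a univariate linear model per feature, identical to a
pooled-variance two-sample t-test.

## Mirror and concordance statistics

Given matched DEL and DUP effect vectors over an explicit feature subset
(the subset is always a caller decision — e.g. the FWER-significant set
for a human cohort, all features for a rat cohort):

* Pearson correlation with its two-sided t-based p-value (n−2 df);
* an exact one-sided binomial sign test on the number of strict
  sign disagreements, `p = P(X ≥ k)`, `X ~ Bin(n, ½)`; pairs containing
  an exact zero are excluded from n. A two-sided variant is reported
  alongside because published sign-test p-values are not always
  reconstructible as one-sided tails.

Cross-species concordance uses the same two statistics on the
name-matched feature intersection, with sign *agreement* as the success.

## Classification and selection

Features are first residualized on covariates only (genotype never
enters). A family random intercept is included per feature when its
boundary-corrected variance LRT (null = ½χ²₀ + ½χ²₁) is significant at
5%; residuals then also subtract the predicted family effect, so
within-family correlation is removed from the classifier's input. LDA
uses proportional priors and the maximum-posterior rule; accuracy is
reported by resubstitution and by leave-one-out cross-validation with
sensitivity(g) = TP/n_g and specificity(g) = TN/(n−n_g). A left-out fit
that becomes singular flags the subject as misclassified with a warning.

Lasso selection standardizes candidate features to unit variance, walks
a descending log-spaced penalty grid from just above the smallest
all-zero penalty (the KKT bound `max|Xᵀ(y−ȳ)|/n`), and picks the penalty
by mean held-out deviance over seeded stratified 10-folds
(`cv_min_deviance`) or by `AIC = deviance + 2·#nonzero` on the full-data
path (`aic`); ties break toward the sparser model. Both rules are
prediction-optimal criteria and, as expected for such criteria, recover
informative features reliably while also admitting substantial numbers
of noise features; the tests assert the recall property (all planted
features selected in ≥90% of runs) and treat the selection size as
descriptive.

## Larval statistics

Raw ceratohyal angles are anchored per batch: every larva's angle is
multiplied by 100/mean(uninjected controls), so the control mean is
exactly 100 and the operation is invariant to common rescaling. Group
comparisons are one-way ANOVA followed by Tukey HSD (studentized-range
distribution, pooled within-group variance; reporting focuses on
condition-vs-control rows, the full all-pairs table is retained). At two
groups the Tukey adjusted p equals the pooled two-sample t p, which the
tests verify to 1e-6. The across-gene direction pattern is the same
exact sign test as the mirror module with "lower mean CHA" as success.

Synergy: for a 2- or 3-gene combination experiment with all single and
combination conditions present, the additive model (gene main-effect
indicators) is compared to the fully parameterized cell-means model by
an F-test; interaction coefficients with t-tests come from the
full-factorial parameterization. Missing design cells are an error that
lists the absent conditions. The frontonasal area and interocular
distance run through the identical machinery via the `response`
argument; body-length growth controls use the generic pooled-t group
comparison.

## Synthetic cohorts

The generators define the study conditions for every test:

* **Human**: 45 DEL / 44 DUP / 139 CTRL in families of 2-5 (the two
  first members of a family act as parents, ages 28-50; children 3-18),
  both sexes; head circumference carries a log-age trend plus a ±1.5 cm
  genotype shift (macrocephaly with deletion, microcephaly with
  duplication); BMI an age trend; two ancestry PCs clustered by family,
  with 16.7% of subjects missing PCs (exercising the imputation rule).
  Facial geometry starts from a bilaterally symmetric 24-landmark
  template (mm); genotype effects are planted as signed fractions of
  feature means on 18 default features (1-12%, reciprocal at 80%
  magnitude for 13 of 18 and concordant at 40% for 5 — the mirror
  proportion the analysis should recover). Per-subject size scales with
  age and sex plus lognormal noise, families share a landmark offset
  field (SD 0.8 mm), landmarks get iid placement noise (SD 0.6 mm), and
  each configuration receives a random rigid motion, as acquired images
  would.
* **Effect planting** is geometric: because planted effects are defined
  on *normalized* features, a displacement field over the template
  landmarks is solved so that the normalized targets are met exactly
  (residual < 1e-8). The solver uses the exact Jacobian of normalized
  features — including the geometric-mean term, without which a scale
  direction is unconstrained — with mirror-class constraints entering
  jointly to preserve bilateral symmetry, and Levenberg-Marquardt with
  homotopy staging for robustness at large fractions. A geometrically
  unattainable effect map raises rather than silently under-delivering.
  Untargeted features shift too (median ~3-4%), as genuinely correlated
  anatomy would.
* **Rodent**: 23 DEL / 26 DUP / 26 CTRL (the rat design), 19-landmark
  dorsal template plus mandible landmark groups; reciprocal effects on
  15 dorsal features plus a ∓3% mandibular-length stretch; smaller
  landmark noise (0.15 mm) appropriate to CT landmarking.
* **Larvae**: per-condition normal draws around an 85° control mean
  (SD 6°) with planted shifts; the default screen covers 30 interval
  genes with 24 negative shifts (strongest −4° and −3°), matching the
  3°-16° scale of larval group effects; interaction terms add degrees
  beyond additivity in combination conditions.

All draws derive from one seed through `numpy.random.SeedSequence`
spawning (separate streams for family assignment, covariates and
geometry), so cohorts are byte-reproducible. Every generator returns a
truth record of all planted parameters sufficient to score recovery.

What the generators do **not** emulate: real facial variation is not
Gaussian landmark jitter around one template (no allometry beyond a
scalar size trend, no population shape axes, no landmarking error
structure); family resemblance is a shared offset, not genetic
inheritance; larval batches lack clutch effects and dose-response
structure. Passing tests therefore demonstrate that the statistical
machinery recovers what was planted under its own model assumptions —
they do not certify performance on consortium imaging data.

## Problem sizes and runtime choices

Null-calibration simulations use 1000 replicates (type-I error bands
[0.035, 0.065] at α=0.05); recovery properties use 10 cohort seeds at
the full study sizes; the Tukey familywise-error simulation (2000
replicates) applies the rejection rule in its equivalent
critical-value form after verifying that equivalence against the
package's adjusted p-values, since exact studentized-range tail
evaluation is much slower than the test statistic itself. Tolerances:
exact identities at 1e-12, geometric invariances at 1e-9, cross-library
likelihood agreement at 1e-6.

## Known limitations

* The LRT's chi-squared reference is mildly anticonservative at small
  cohort sizes (see calibration above); no Bartlett or Kenward-Roger
  correction is applied.
* One random intercept only; no nested or crossed random effects, no
  random slopes.
* Lasso selection sizes are prediction-optimal, not support-recovery
  optimal; interpret the selected-set size descriptively.
* The sign convention treats exact-zero effects by exclusion; with
  coarsely rounded inputs this can shrink n noticeably.
* Angles are computed in the ambient dimension of the stored
  coordinates (3D for faces and skulls, 2D for ventral larval images).
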