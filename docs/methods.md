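# Methods

## Classifier

The core estimator is classical multi-class linear discriminant analysis
with a pooled within-class covariance: class means µ_k are sample means,
S = Σ_k (n_k − 1) S_k / (n − K), and a subject is scored by the Bayes
posterior P(k | x) ∝ π_k · exp(−½ d_k²) with d_k² the squared
Mahalanobis distance under S. The model assumes multivariate normality
with a covariance shared across classes; with equal priors the rule
reduces to the Mahalanobis-nearest centroid, which is also what the
decision-region map draws. Discriminant axes are the eigenvectors of the
generalized problem S_b v = λ S v (between-class scatter weighted by
class size), normalized to unit within-class variance, ordered by
decreasing λ, with each axis's largest-magnitude loading made positive so
signs are reproducible. For K classes there are min(K − 1, p) axes; with
three groups the LD1/LD2 plane is exhaustive, so classifying in the plane
equals classifying in the ambient space.

**Priors.** Default `proportional` (class sample fractions), matching the
convention of standard LDA implementations; `equal` is a first-class
alternative and every report records which was used. With a 31/8/7
cohort the choice matters near boundaries.

**Raw scale.** Features are never centered or standardized: stage-2
loadings must apply to literal concentration products, so everything is
computed in µM (and powers thereof). The numerical cost of that choice is
handled by the ridge policy below.

**Ridge policy.** Monomial columns at n = 46 can be collinear. The
pooled covariance receives an escalating ridge ε·tr(S)/p with
ε = 10⁻⁸ … 10⁻², but only when the matrix is *numerically singular*
(Cholesky failure, or a pivot ratio at float64 machine precision). A
condition-number threshold was deliberately rejected: merely
ill-conditioned term designs (condition ~10⁸) are routine and benign,
and ridging them washes out genuinely tiny within-class variances that
carry the product-coded signal. `ridge_used` is recorded on the model
and surfaced in run manifests whenever non-zero.

**Ties.** Equal posteriors resolve to the first class in declared order;
subset-search ties resolve to the smaller panel, then the
lexicographically smallest index set. All results are independent of
subject order and execution order.

## Leave-one-out evaluation

Every subject is classified by a model fit on the other n − 1 subjects;
the report aggregates the n held-out predictions. The implementation
downdates per-class sufficient statistics (an exact rank-1 update of the
held-out class's scatter) and factorizes all fold covariances in one
batched call; this is algebraically identical to refitting from scratch
per fold, and the test suite verifies prediction- and posterior-level
agreement with an independent naive refit and with scikit-learn fitted
per fold. Folds that would leave a class with fewer than two subjects
raise a degenerate-fold error.

A deliberate property inherited from the study design: the subset search
*optimizes* the same LOO accuracy it reports, so reported accuracies for
searched panels are selection-biased upward and are not estimates of
generalization error. The package reproduces this design and documents
it rather than nesting the cross-validation.

## Subset search (stages 1 and 2)

For each size k the search maximizes overall LOO accuracy (secondary
metrics are reported, never optimized). `exhaustive` enumerates C(M, k)
subsets in lexicographic order under an explicit evaluation budget and
raises if the budget would be exceeded; `forward` grows the single best
subset greedily; `beam` (width 20 by default) keeps the best partial
subsets per size. Search stops after 2 consecutive sizes (the
`patience`) without cumulative improvement, mirroring a plateau where a
fifth or sixth metabolite no longer helps. The reported "selected size"
is the smallest k attaining the cumulative maximum.

Exhaustive search over C(188, 4) ≈ 4.9·10⁷ subsets × 46 folds is beyond
desk scale; forward is the default for wide panels and the exhaustive
mode is the oracle on small instances in tests.

**Stage-2 universe.** Terms are built over the *largest* stage-1 panel
explored (`max_k` metabolites, default 4), not the plateau-minimal
panel. Rationale: monomials can extract signal from a metabolite that
added nothing linearly, and the plateau rule would otherwise drop exactly
those metabolites; when stage-1 accuracy genuinely peaks at `max_k` the
two panels coincide. The term universe for m metabolites at degree ≤ d
contains C(m+d, d) − 1 monomials, ordered by degree then lexicographic
exponent multiset; labels use `^` for powers and `*` for products
(`C3^2*Ac-Orn`).

## Synthetic cohorts

The generator defines the study conditions under which everything is
tested; defaults emulate a 46-subject ophthalmic cohort (31 controls, 8
glaucoma, 7 diabetes; 188 metabolites).

- **Baseline.** Log-normal concentrations: per-metabolite log-location
  drawn once from the seed as N(ln 5, 1.5²) — panel medians spanning
  roughly 0.05–500 µM — and subject scatter with common log-SD
  `noise_sigma` (default 0.3 ≈ 30% biological CV; the study-condition
  recipe uses 0.25).
- **Markers** multiply a class's mean concentration; a shift of e^(6σ)
  is the "unambiguous marker" used in recovery tests.
- **Correlation blocks** share a latent Gaussian factor giving pairwise
  latent correlation ρ; realized Pearson correlations on the log-normal
  scale are slightly attenuated (≈0.69 realized at ρ = 0.7, σ = 0.3),
  converging with n.
- **Product-coded signal** (`nonlinear_spec`): a two-point latent sign
  s = ±1 per subject displaces both pair columns by ±a on the log scale,
  *aligned* between the columns in designated classes and *anti-aligned*
  elsewhere, with tight jitter (`nonlinear_sigma`, default 0.1; 0.05 in
  the engineered recipes). Every marginal is then the same symmetric
  two-point mixture in every class — carrying no mean signal — while the
  quadratic combination (x·e^(−m₁) − y·e^(−m₂))², expressible in the
  degree-2 monomials x², y², xy, is ≈0 for aligned classes and ≈4·sinh²a
  for anti-aligned ones. Because the latent is discrete, the two
  populations are separated by construction rather than probabilistically,
  which is what makes "stage 2 reaches 100% where degree-1 cannot" a
  property that holds per seed rather than on average. The amplitude is
  parameterized per class as a multiplicative product shift δ_c
  (a = max|ln δ_c|/2; δ_c > 1 ⇒ aligned).
- **Ages** are Gaussian per class truncated at 18, defaulting to means
  56 / 67.5 / 72 with SDs 13 / 7.5 / 3 — used to exercise the one-way
  ANOVA and the age-filtered rerun, nothing else.

**The study-condition recipe** (`study_config`) plants a strong
diabetes marker (×4.5), two partially shifted glaucoma metabolites
(×2.5) that also carry an aligned product signal for glaucoma, a mild
fourth marker, and a ρ = 0.45 block. On these conditions the linear
stage plateaus around 93–96% LOO accuracy and the polynomial stage
recovers part of the remainder. A limitation chosen deliberately and
not revisited: with only 8 glaucoma subjects among 188 metabolites,
greedy selection cannot reliably admit *both* members of the product
pair over lucky noise metabolites, so the flagship emulation does not
always reach 100%; the two-stage completion property is instead
demonstrated (and tested) on eight-metabolite cohorts where the pair
members are the strongest marginals.

**What the generator does not emulate:** assay artefacts (limits of
detection, batch effects, heteroscedastic technical noise), realistic
inter-metabolite correlation networks beyond the planted blocks, and
covariate confounding between age and metabolite levels. Passing tests
therefore certify the *machinery* — search, estimator, evaluation,
geometry — under the stated statistical structure, not performance on
real aqueous-humour data, whose separability cannot be established from
synthetic cohorts.

## Evaluation conventions

- Confusion matrices: rows = real class, columns = predicted; stated in
  every serialized header since the transposed convention is also common.
- Multi-class sensitivity/specificity/PPV/NPV: one-vs-rest per class,
  macro-averaged over classes where defined; 0/0 ratios are NaN with an
  explicit flag and excluded from macro averages.
- Pearson correlation: product-moment r with the two-sided t-transform
  p-value on n − 2 df, uncorrected for multiple testing (matching the
  pairwise-table convention); one-way ANOVA is the classical
  decomposition. Both are cross-checked against scipy to 1e-10.
- Posterior summary counts subjects whose true-class posterior *strictly*
  exceeds 0.5; an exact 0.5 does not count.
- Quartiles use linear interpolation (type 7); SD is the n − 1 estimate.
- Missing/below-LOD CSV cells are imputed as half the column's minimum
  positive value; metabolites missing in > 20% of subjects are dropped.
  Both behaviours are configurable in `CsvDialect`.
- Age filtering removes subjects only from the designated class (the
  young-control scenario) and refuses to shrink any class below 2.

## Decision-region map

Class centroids and the pooled covariance are projected onto the first
two axes; each cell centre of a rectangular raster (default 400×400,
bounds = data range + 10% per axis) is labelled by Mahalanobis-nearest
centroid (equal priors) or maximum posterior (proportional). Equal-prior
regions are convex; for three symmetric centroids the boundaries meet at
the symmetry centre. Grid labels agree with the full classifier at
subject coordinates because two axes are exhaustive for three classes.

## Reproducibility

All randomness flows from a single integer seed (`numpy`
`default_rng`); identical configs give bitwise-identical cohorts and
byte-identical pipeline outputs (floats serialized at 12 significant
digits, no timestamps). Manifests echo the full config, the seed, class
sizes before/after filtering, and any ridge events.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks run at the sizes stated in their docstrings — e.g.
1000 random instances for oracle equivalence, 100 seeds for marker
recovery, 50 seeds for product-signal necessity, 200 seeds for null
calibration, 3×1000 subjects for mean recovery — chosen as the package's
own measurement scales; the engineered end-to-end completion check runs
at 15 seeds with the beam strategy.
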