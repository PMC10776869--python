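# Methods

## Superimposition model

Input is a set of n configurations of k homologous 2-D landmarks
(k = 17 in the default wing design). Generalized Procrustes analysis
removes the nuisance parameters of digitization:

- every configuration is translated to a zero centroid and scaled to
  unit centroid size (CS, the root summed squared landmark distances to
  the centroid — the standard geometric-morphometric size measure,
  recorded in input units before rescaling);
- rotation of each configuration onto the running consensus alternates
  with consensus re-estimation (coordinate-wise mean, rescaled to unit
  CS) until the Procrustes distance between successive consensuses falls
  below `tol = 1e-10` or `max_iter = 100` iterations — far tighter than
  any biological signal and cheap at the package's intended problem
  sizes (n of a few hundred, k ≤ a few dozen);
- the initial consensus is the first configuration; after convergence
  the rotational gauge is fixed by aligning the consensus's principal
  axis with +x (180° ambiguity resolved by the sign of the third moment
  along x), so outputs are reproducible across runs and input orders.

Rotations come from the SVD of the 2×2 cross-covariance with a
determinant sign correction, so a reflection is never returned: the
package assumes a chirally consistent dataset (e.g. right wings only).
By default the superimposition is *partial* Procrustes — unit CS is
fixed, no per-shape scale optimization — which is the dominant
convention in the field; `scale="full"` optimizes per-shape scale
against the consensus instead. Aligned shapes are orthogonally projected
onto the tangent hyperplane at the consensus (`project=True` by
default), making ordinary multivariate statistics applicable; all
shipped outputs record both flags.

Degenerate inputs: a configuration with all landmarks coincident has
CS = 0 and is reported with a warning from `centroid_size` but cannot be
superimposed; a zero cross-covariance in the rotation step yields the
identity with a warning; non-convergence is flagged on the result, not
raised.

## Size and allometry

Centroid sizes are compared by one-way fixed-effects ANOVA; pairwise
t-tests use the pooled residual variance of the full model with
df = n − g (the convention of the common agricultural-statistics
routines this analysis style wraps), each raw p multiplied by the number
of pairs and capped at 1. A per-pair-variance option exists; pooled is
the default. Zero within-group variance is reported as an infinite-F
sentinel with p = 0 rather than an error.

Allometry is the fraction R² = SS_fit/SS_total of total Procrustes
variance explained by least-squares regression of the flattened aligned
coordinates on log CS (natural log — the morphometric convention for
allometry; a raw-CS flag exists), sums of squares accumulated over all
2k response columns. Significance comes from shuffling the size vector
across specimens (default 1000 permutations); p uses the add-one
convention (exceedances + 1)/(N + 1) and is therefore never 0. Constant
CS makes R² undefined and raises.

## Discriminant analysis and distances

Procrustes coordinates span at most 2k − 4 dimensions, so all
group-level statistics run in a principal-component basis retaining
every direction whose singular value exceeds 1e-8 × the largest. This
retains the full numerically nonzero shape space (rather than a
truncated PC subset) because truncation level affects borderline
classifications; the threshold only strips the superimposition-exact
degeneracies. If a jackknife fold or a degenerate draw still leaves the
pooled within-group covariance rank-deficient, an escalating relative
ridge (1e-8, 1e-4, 1 × mean diagonal) is added with a warning.

Discriminant axes solve B·a = λ·W·a (between- vs within-group scatter),
scaled so LD scores have unit pooled within-group variance — the
canonical-variate convention. Reported axis proportions are eigenvalue
fractions λⱼ/Σλ over min(g − 1, r) axes. Classification uses Gaussian
discriminant scores with the shared pooled covariance; priors default to
observed group frequencies (`"equal"` available); ties are broken toward
the lowest group index with a warning.

Leave-one-out cross-validation refits the discriminant model (including
the rank reduction) for every held-out specimen but does **not** rerun
the superimposition per fold: the jackknife operates on fixed Procrustes
coordinates, matching standard practice, since the consensus moves
negligibly when one of hundreds of specimens is dropped. A strict
`refit_gpa=True` mode re-superimposes each training fold and aligns the
held-out specimen to that fold's consensus, for sensitivity analysis.
Accuracies are displayed as percentages rounded half-up to one decimal;
raw fractions are always stored.

Mahalanobis distances between group means use the pooled within-group
covariance over *all* groups (denominator n − g; an n option exists) in
the same reduced basis as the discriminant model, so distances and
classifications live in one space — per-pair reductions would change the
values. The permutation null for a pair shuffles that pair's labels
jointly and recomputes the distance, including the pair's contribution
to the pooled covariance (a global multi-group shuffle is available
behind `mode="global"`). With a shared metric, D satisfies the triangle
inequality and is invariant to any affine map of the reduced
coordinates. No multiple-testing correction is applied to the pairwise
p-values by default; a Bonferroni accessor exists.

Convex hulls for ordination plots use Andrew's monotone chain with
explicit degeneracy policy (single point → point; collinear → the two
extremes), vertices in counter-clockwise order.

## Synthetic data generator

The generator emulates the statistical structure a six-taxon wing study
presumes, not wing images: a fixed stylized 17-landmark template (its
exact coordinates are arbitrary plumbing), per-taxon mean-shape offsets
in the template's tangent space, log-normal centroid sizes, one common
allometric direction, isotropic Gaussian landmark noise, and nuisance
rotation/translation/scale for the superimposition to remove.

Default design (groups SIN/PAL/MOL/PIP/TRI/ALB, n = 35/47/67/17/45/40,
251 specimens):

- **Noise**: per-coordinate sd 0.004 in unit-CS shape units — a
  realistic digitization-plus-individual dispersion that keeps the
  subgroup problem hard but solvable.
- **Offsets**: outgroups SIN and ALB displaced mainly at landmarks 1–2
  and 16–17 with magnitude ≈ 0.086 (≫ noise); TRI at landmarks 12–17,
  ≈ 0.049; subgroup taxa differ only at landmarks 16–17 by ≈ 3–4 noise
  sd, so their pairwise Mahalanobis separations land near 3–5 —
  reproducing the regime where outgroups classify perfectly and subgroup
  taxa at roughly 70–97%. Offsets are re-centered and re-scaled so each
  group mean keeps unit CS, giving "offset magnitude" a consistent
  Procrustes-distance meaning.
- **Sizes**: equal mean log CS for the three subgroup taxa (ln 2),
  strictly larger for SIN (ln 3), smaller for ALB (ln 1.4), intermediate
  for TRI (ln 2.4); sd(log CS) = 0.06 (≈ 6% size variation).
- **Allometry**: a single direction (an aspect-ratio change with size)
  of magnitude 0.046 per unit log CS. The magnitude comes from the
  design's variance budget: with predictor variance
  Sxx ≈ 13 (between-group size spread plus within-group 0.06² over 251
  specimens), offset between-group shape variance ≈ 0.65 and noise
  variance ≈ 0.14, R² = |β|²Sxx/(SS_offsets + SS_noise + |β|²Sxx)
  lands in the low single-digit percent range (≈ 3–4% in generated
  draws). Because SIN/ALB pair large/small sizes with large opposite
  shape offsets, the raw offsets are orthogonalized against the
  between-group log-CS gradient before use; otherwise the size–offset
  correlation would masquerade as an order-of-magnitude larger
  allometric R².
- **Nuisance**: random rotation over [0, 2π), translation U(−5, 5) per
  axis, scale identity by default (a scale range can be enabled, e.g.
  to exercise nuisance removal; it corrupts measured CS by design, as
  unknown magnification would).

The generator draws with `numpy.random.default_rng(seed)` in a fixed
order, so a seed fully determines the dataset. What it does **not**
emulate: anisotropic or landmark-correlated digitization error, multiple
allometric directions, geographic/seasonal covariates, or outliers.
Passing tests on this generator therefore demonstrate the correctness
and calibration of the *machinery* (superimposition, tests, classifiers)
under the design's assumptions — not that any particular accuracy will
be attained on real wings.

## Numerical and design notes

- Permutation p-values everywhere use the add-one convention and record
  the seed in the result object.
- The TPS reader multiplies coordinates by `SCALE=` when present (the
  tpsDig convention); specimen ids resolve ID= → IMAGE= stem → record
  index; the y axis is taken as digitized (a `flip_y` option applies an
  image-row flip — all downstream statistics are invariant to a uniform
  reflection convention).
- The writer emits coordinates at full `repr` precision so read∘write is
  an exact identity, dividing scale back out and re-emitting `SCALE=`.
- The estimator classes follow scikit-learn conventions (`fit`,
  `transform`/`predict`, trailing-underscore attributes) and compose
  with its model-selection utilities, but all Procrustes/discriminant/
  distance computations are implemented here; scikit-learn's own
  discriminant classifier is used only as an independent cross-check in
  the test suite.
- Group order in every output follows first appearance in the dataset
  (the declared taxon order), never sorting.

## Known limitations

- 2-D landmarks only; no semilandmarks, sliding, or missing-landmark
  estimation.
- The LOOCV default (fixed superimposition across folds) slightly
  optimistically couples folds through the consensus; the effect is
  negligible at n in the hundreds but `refit_gpa=True` exists to check.
- Pairwise Mahalanobis permutation tests recompute the pooled covariance
  only through the shuffled pair's contribution; with very many groups
  of very unequal dispersion the global mode may be preferable.
- The allometric R² mixes within- and between-group size–shape
  covariance, as in the classical pooled regression; no size correction
  is applied to shapes before classification.
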