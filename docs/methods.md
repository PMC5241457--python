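# Methods

This note documents the models, conventions and design choices behind
`eigenlife`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions,
which knobs matter, and what the synthetic evidence does and does not
show.

## 1. From diary text to behavior matrices

A diary entry is a timestamped free-text annotation in one of two
categories, *activity* (interval events, start–end times) or *diet*
(point events). Preprocessing is deliberately simple, matching the
shortness of diary language:

- tokenization to lowercase alphabetic tokens; punctuation and digits
  dropped;
- removal of a built-in English stop-word list (which also contains
  generic diary verbs such as "ate", "went", "drink" that carry no
  class information);
- rule-based lemmatization (suffix stripping for plurals, *-ing*,
  *-ed*, plus a small irregular table), preferring candidate base forms
  that occur in the class lexicon and leaving lexicon words untouched
  (so stored inflected vocabulary like "fries" or "noodles" survives);
- spell correction of out-of-vocabulary tokens to the nearest lexicon
  word within Levenshtein distance 2 (computed with `edlib`), ties
  broken lexicographically. Aggressive correction of very short tokens
  is a known limitation — a stray three-letter token can be pulled onto
  an unrelated lexicon word two edits away — but diary vocabulary is
  dominated by content nouns where the rule behaves well.

Recognized tokens map to 9 activity classes and 12 diet classes; the
day is partitioned into 3 activity periods (morning 00:00–12:00,
afternoon 12:00–17:00, evening 17:00–24:00) and 6 diet periods
(breakfast 00:00–09:00, morning, lunch, afternoon, dinner, evening
19:00–24:00). Period intervals are **half-open** `[start, end)`: a
12:00 diet event is lunch, not morning, and nothing is double-counted.
Point events land in the unique period containing their time; interval
events mark **every** period they overlap, since an activity spanning
11:00–13:00 genuinely occupies both morning and afternoon. Entries are
assumed to lie within one day; overnight activities are not modelled.

The binary behavior matrix has one row per *annotated* day and one
column per (class, period) pair, class-major in lexicon order, giving
exactly 27 activity and 72 diet columns regardless of which classes
occur. A cell is 1 iff at least one matching annotation exists, so
duplicates are idempotent and construction is invariant to entry order.
Days with no annotations are dropped rather than zero-filled — an
unannotated day is missing data, not an empty routine; the "none"
activity class is set only by an explicit "none" annotation. Group
matrices stack per-subject *average behaviors* Ψ (column means, values
in [0, 1]).

## 2. Eigenbehavior decomposition

For a matrix B with D rows and H columns, the model is classical PCA:
Ψ is the row mean, and the eigenbehaviors u_i and eigenvalues λ_i are
the eigenvectors/eigenvalues of the sample covariance of the centered
rows with 1/(D−1) normalization. Numerically the decomposition is done
through the thin SVD of the centered matrix — the H × H covariance is
never formed — and eigenvalues are singular values squared over D−1;
the test suite checks equivalence with a dense eigensolver on the
explicit covariance to 1e-8. Components with λ < 1e-12·λ_1 are treated
as numerical rank deficiency and dropped, so r ≤ min(D−1, H). Because
eigenvectors are sign-ambiguous, each is flipped so its
largest-magnitude entry is positive, making outputs reproducible. A
matrix of identical rows yields a valid rank-0 model (Ψ only).

Projection and reconstruction are the usual eigenface-style operations
ω_i = u_i·(Γ − Ψ) and Γ̂ = Ψ + Σ ω_i u_i. The **primary eigenbehavior
count** is the smallest k whose cumulative explained-variance fraction
reaches the variability threshold (default 0.9); it is the package's
scalar notion of routine regularity, and it is non-increasing as the
threshold is relaxed.

### Partial-day prediction

To predict the rest of a day from its beginning, the weights are
estimated by least squares restricted to the observed columns: solve
`min_ω ‖U_obs ω − (Γ_obs − Ψ_obs)‖²` over the rows of the eigenvector
matrix corresponding to observed columns, then evaluate Ψ + U ω on the
target columns. Conventions:

- the number of components used is the training fold's primary count at
  the 0.9 threshold (not the full rank r, which would interpolate noise),
  further truncated to the number of observed columns so the system
  stays determined;
- the continuous reconstruction is clipped to [0, 1] and thresholded at
  0.5 (values ≥ 0.5 become 1) since the ground truth is binary;
  accuracy is the fraction of matching target cells. The raw residual
  is also available via `residual_norm2` for continuous scoring;
- a degenerate training fold (identical rows, rank 0) predicts the
  thresholded Ψ.

Evaluation uses leave-one-day cross-validation; the per-category
splits are fixed by the period structure (activity: P0–P1 observed,
P2 predicted; diet: P0–P2 observed, P3–P5 predicted). Because most
cells of a sparse space are 0, the all-zero predictor is a strong
baseline; accuracies must be read against it, which is precisely why
sparse diet matrices score higher than activity without being more
"informative". On i.i.d. Bernoulli(0.5) matrices the target cells are
independent of everything the predictor sees, so expected accuracy is
exactly 1/2 — a useful calibration checked in the acceptance tests.

## 3. Distances, membership, dartboard

All similarity analytics operate on weight vectors with k defaulting to
the space's primary count at 0.9. Day–day and subject–subject
similarities are squared Euclidean distances between weight vectors;
with k = r this equals the squared distance between mean-adjusted rows
(orthonormal projections are isometric on the row space), a property
under test. The day-index vector records, per day, the 1-based index of
its most similar other day, ties broken toward the smallest index; the
overlap between the diet and activity index vectors measures how
intertwined the two routines are. For D days of unrelated behavior the
expected overlap is 1/(D−1) by exchangeability.

The residual distance of a subject from a group is
ε² = ‖φ − φ_b‖² with φ = Ψ_subject − Ψ_group and φ_b the orthogonal
projection of φ onto the span of the group's k leading eigenbehaviors
(for a rank-0 group space, ε² = ‖φ‖²). Group-membership classification
uses the ε² features for every (space, group) pair — 2 spaces × 2
groups = 4 features — under leave-one-subject-out cross-validation in
which the group eigenmodels are refit per fold *excluding the held-out
subject*; fitting them once on everyone would leak the test subject
into its own group subspace and bias accuracy upward. Classifiers are a
decision tree, a 101-tree random forest (max_depth searched over
{2, 3, 5, None}) and an rbf SVM (C over {0.1, 1, 10}, gamma over the
scale heuristic × {0.5, 1, 2}), tuned by grid search with inner
stratified CV on each training fold. A group reduced to a single
subject in a training fold is an error: no subspace can be fit.

The dartboard layout places a reference subject at the center and every
other subject at an angle assigned in subject order (equally spaced)
and a radius proportional to its distance, rescaled so the farthest
subject sits on the outer of five equally spaced reference rings; the
nearest same-group and other-group subjects are highlighted. The layout
is invariant to rescaling all distances.

## 4. Shuffle-null validation

Whether the indicator-based grouping is *behaviorally* meaningful is
tested against a permutation null: labels are shuffled 100 times
(sampling without replacement, so group sizes are preserved exactly),
and for every shuffle the group eigenmodels — including their primary
dimensionality — are refit before computing the four mean residual
distances d⁰⁰, d¹¹ (within-group) and d⁰¹, d¹⁰ (group-g subjects
projected into group g′) per behavior space. Refitting k per shuffle
keeps the null and observed statistics on exactly the same code path.
The "bulk" of the null is quantified as the central 95% interval, with
tail probabilities computed by the add-one Monte-Carlo convention
p = (1 + #{null at least as extreme}) / (1 + n_shuffles): with 100
shuffles the naive strict-percentile rule would flag ~5.9% of truly
null statistics, whereas the add-one rule keeps the nominal 5% level.
Empirical percentiles are reported alongside the flags; no further
p-value machinery is provided.

## 5. The synthetic cohort generator

No diary data ship with the package; the generator produces cohorts
with exactly the structure the method assumes, at the study scale of
21 subjects × 10 annotated days with groups of 13 and 8.

**Indicators.** Each of the 11 indicators is drawn from a
group-conditional Gaussian. The defaults reproduce the pooled cohort
moments (e.g. VO2max 3009 ± 679 ml/min, BEE 1567 ± 215 kcal/day), and
the group contrast follows a gender-like physiological profile — one
group higher in VO2max, BEE, height, weight, fat-free mass and RMR,
lower in fat mass and fat percentage — scaled by a single effect size
(`group_shift_sd`, default 2.0 pooled SD on VO2max and BEE, the two
indicators that should dominate the importance ranking; all other
shifts scale proportionally, so effect size 0 makes the groups
identical in distribution). Within-group variances are shrunk so the
*mixture* matches the nominal pooled SD; a cohort whose pooled spread
already includes the group gap would otherwise be over-dispersed. A
profile across many correlated indicators is essential: two informative
dimensions against nine independent unit-variance nuisance dimensions
would be unrecoverable by silhouette-selected k-means at this sample
size, and real anthropometric indicators are strongly mutually
dependent. Non-positive draws are redrawn (all indicators are
physically positive).

**Routines.** Daily rows are drawn from Bernoulli day-type templates:
a day first samples a day type, then each of the H cells independently
from that type's probability vector, and finally every cell is flipped
with `noise_flip_prob` (default 0.005, rare annotation errors). The
low-rank-mean-plus-noise structure is exactly the regime
eigendecomposition assumes, which makes primary counts predictable.
Defaults:

- *activity*, group 0: two day types (office weekday / free day),
  ~7 active cells each at probabilities 0.3–0.9, background 0.06;
- *activity*, group 1: a single tight day type (bike commute, work,
  evening training), background 0.06 — one group variable, one group
  very regular;
- *diet*, both groups: one shared template pair (typical day / meat-
  dinner variant) with few high-traffic meal cells (0.5–0.95) and very
  low background (0.002), multiplied by `diet_sparsity` (default 0.9,
  mild under-reporting of food items).

Activity templates are group-specific while diet is group-independent,
so the grouping is visible in activity behavior and invisible in diet —
the discrimination the shuffle-null validation is meant to detect. An
auxiliary sampler turns any binary row back into timestamped free-text
entries using lexicon vocabulary, to exercise the ingest pipeline end
to end.

**What passing tests show — and don't.** The generator produces
independent Bernoulli cells around a day-type mean; real diaries have
correlated annotations, systematic recall bias, missing days and
vocabulary outside the lexicon. Results on synthetic cohorts therefore
validate the *machinery* (algebra, cross-validation hygiene, null
calibration, qualitative orderings such as "sparser space ⇒ fewer
primary eigenbehaviors and higher thresholded accuracy"), not the
empirical effect sizes to be expected on real diaries.

## 6. Numerical and procedural conventions

- Indicators are z-scored before clustering by default (units range
  from kcal/day to kg; raw-scale clustering is available via
  `standardize=False` for sensitivity analysis).
- Spectral clustering uses a cosine-similarity affinity shifted to
  [0, 1] (z-scored data produce negative cosines, which the spectral
  solver cannot take); silhouette is computed with Euclidean distance
  for both methods so the model-selection scores are comparable. Ties
  prefer k-means, then the smaller k. The default k range is
  2..min(8, N−1). All stochastic components (k-means init, forests,
  shuffles, generator) take explicit seeds.
- The extra-trees importance ranking uses 101 trees, seed 0, mean
  impurity decrease normalized to sum 1.
- Cumulative-variance thresholds are compared with a 1e-12 slack so a
  component explaining exactly the threshold counts.
- Simulation sizes in tests and in `scripts/acceptance.py` (20
  replicate cohorts, 100 shuffles, 200 noise matrices, 500 overlap
  pairs) are the package's chosen trade-off between statistical
  resolution and a test suite that runs in minutes on one core.

## 7. Known limitations

- Eigendecomposition of sparse binary data conflates "sparse" with
  "regular": a mostly-empty matrix needs few components and thresholded
  predictions of mostly-zero targets score high. The primary count and
  accuracy should always be compared against density-matched baselines
  (the package reports both per space for this reason).
- Spell correction can misfire on very short tokens; unrecognized
  tokens are silently ignored (logged at debug level).
- Multi-day or overnight diary entries are out of scope, as are
  nutritional quantities, multilingual lexicons, probabilistic
  membership scores, and autoregressive/neural routine models.
- The membership classifier is evaluated on 21 subjects; a single
  subject is ~4.8 accuracy points, so reported accuracies are coarse.
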