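# Methods

This note documents the models, estimation choices, and synthetic-data
conditions implemented in `emometrics`, and what the test suite does and
does not establish.

## Stimulus validation

A stimulus's *hit rate* is the fraction of judgements choosing the
intended emotion; for concealed displays a hit requires both the displayed
and the hidden emotion to be labeled correctly. Hit rates are converted to
the proportion index pi = P(k−1)/(1+P(k−2)), where k is the number of
response options actually offered. The conversion is exact at the
endpoints, maps chance P = 1/k to 0.50 for every k, reduces to the
identity at k = 2, and is strictly increasing in P. For concealed
stimuli the default k is the joint space k₁ × k₂ of the two judgements
(two 18-label menus give 324 cells; two 6-option keyed menus give 36); a
per-judgement mode is available. No response-bias correction is applied;
a hook exists but ships empty.

Confusion matrices pool judgements by intended emotion within a modality.
Row-stochastic raw proportions sit beside their elementwise pi conversion;
the diagonal is the per-emotion hit rate and off-diagonal mass identifies
plausible distractors. Distractor keys rank off-target labels by
descending confusion pi with alphabetical tie-breaks (determinism), taking
the top label(s) as partial-credit distractors and the next ones as
incorrect distractors.

Selection thresholds: pi strictly above 0.50; mean intensity within
[2.0, 4.0] and mean believability ≥ 3.0 on the 1–5 scales. The numeric
bands operationalize "moderately intense" and "at least moderately
believable" and are configurable; the defaults bracket typical observed
means near 2.7 and 3.1. Believability is not applied to concealed
displays, which look unnatural by design. A single rating yields SD = 0
with a degenerate-sample flag rather than an error.

## Graded scoring

Single-judgement items: 2 = target, 1 = partial-credit distractor,
0 = other. Concealed items: 3 = both targets placed correctly, 2 = both
target labels chosen but swapped, 1 = exactly one target label present in
either slot, 0 = neither. The full swap is the only placement exception;
a target label in the wrong slot alongside an unrelated label counts as
"one correct label" (score 1). This reading is flagged for sensitivity
analysis since the boundary between 1 and 0 could be drawn by placement
instead; the swap-symmetry of the rule is property-tested. Off-menu
choices are rejected — a forced-choice instrument cannot receive them.
Unadministered cells carry a dedicated MISSING sentinel (−1), never 0:
"wrong" and "not administered" must not be conflated.

## Graded response model and estimation

Boundary curves are logistic in the slope–threshold parameterization,
P\*ⱼ(θ) = σ(a(θ−bⱼ)) with b₁ < … < b_{m−1}; category probabilities are
adjacent differences; the expected item score Σⱼ P\*ⱼ(θ) is the item
characteristic curve. Parameters are carried in the logistic metric; the
1.702 constant enters only the conversion to normal-ogive standardized
loadings λ = (a/1.702)/√(1+(a/1.702)²).

Calibration is marginal maximum likelihood EM:

- **Quadrature**: 61 equally spaced nodes on [−6, 6], standard-normal
  weights renormalized to sum to one. The fixed N(0,1) prior identifies
  the scale; no anchoring inside a single-group fit.
- **E-step**: each respondent's posterior over nodes from their observed
  (non-missing) responses; the marginal log-likelihood is recorded every
  cycle and is non-decreasing (asserted to 1e−8).
- **M-step**: per item, one Newton step on the expected complete-data
  log-likelihood with an analytic gradient, a forward-difference Hessian
  of that gradient, ridge fallback, and step-halving that rejects any
  proposal breaking a > 0 or threshold ordering — so the step never
  decreases the objective (a generalized-EM update).
- **Start values**: a = 1; thresholds from logits of observed cumulative
  category proportions (scale-consistent with the logistic metric),
  pushed to a minimal gap.
- **Convergence**: max |Δ parameter| < 1e−4, cap 500 cycles; the cap is
  reported, not hidden. Discriminations are capped at 6 and flagged.
  Categories never observed are merged out before fitting and recorded in
  the fit. Estimation is fully deterministic.
- **Floor**: 100 respondents by default; deliberately loosenable for toy
  problems.

EAP person scores are posterior means/SDs over the same grid. The m = 2
special case is the two-parameter logistic model used to score
conventional right/wrong comparison tests.

## Item and test diagnostics

*Item information* is Samejima's Σₖ (P′ₖ)²/Pₖ, which collapses to
a²P(1−P) at m = 2. The one-number "item information" reported in tables is
the prior-weighted average ∫I(θ)φ(θ)dθ over the fit's quadrature;
information at θ = 0 is available by flag. The test information function
is the pointwise sum; its area on [−3, 3] is a trapezoidal integral
(601-point default; agreement with adaptive quadrature is tested to
1e−3). Two tests are compared by evaluating both TIFs on a shared
60-point grid and forming the paired t (df = 59) and Cohen's d of the
differences; identical curves are reported as degenerate rather than
producing an infinite t.

*Item fit* is a summed-score statistic: respondents are grouped by total
score (complete cases over the fitted items), observed category counts per
group are compared with model-expected counts obtained from the item's
curves and the Lord–Wingersky rest-score distribution under the prior.
Adjacent score groups (and, if needed, categories within a group) are
merged until every expected cell reaches 1; df = free cells minus the m
item parameters. Type-I calibration is verified empirically: refitting
model-true data 200 times rejects ≈5% of items at α = .05. The statistic
needs complete cases, so it is unavailable under very sparse designs and
reported as such. The χ²/df ratio ≥ 3 is read as poor fit (boundary
inclusive).

*Reliability*: Cronbach's α from the item covariance matrix
(pairwise-complete by default, with a warning when fewer than half the
item pairs have 50% joint coverage); McDonald's ω from the GRM loadings
under the one-factor model, ω = (Σλ)²/((Σλ)² + Σ(1−λ²)). Zero total
variance yields NaN with a report, not a crash.

*Culling*: three flags — significant misfit (p < .05), loading < 0.30,
information below the candidate-pool mean. The default rule culls on two
of three (the "combination" reading); any-one and all-three variants are
exposed. The information reference is frozen into the result so re-running
on the survivors is idempotent. Final selection greedily maximizes scalar
information subject to per-cell minimum counts over valence-activation ×
actor gender × actor race, deterministic tie-breaks (information
descending, item id ascending), with unsatisfiable quota cells reported.

## Measurement equivalence (d-DIF)

Groups are calibrated independently (each identified by its own N(0,1)
prior), then the focal scale is linked to the reference scale by mean/mean
anchoring over all common items: A = mean(a_F)/mean(a_R),
B = mean(b_R) − A·mean(b_F), mapping b → Ab + B and a → a/A. An iterative
purification mode (drop items with d ≥ 0.5, relink, at most 3 rounds) is
not enabled by default; one-step all-anchor linking favors simplicity and
determinism.

The default d-DIF is DMACS-style: the square root of the
standard-normal-weighted integral of the squared expected-score difference
between the linked groups, divided by the pooled observed item-score SD
(pooled via the usual (n−1)-weighted variance average). The literal
"integrated squared difference / SD" variant and focal-density weighting
are available by flag, and each result labels its variant. With
standard-normal weights the statistic is symmetric in group order.
Classification bins are left-closed: [0, 0.2) negligible, [0.2, 0.5)
small, [0.5, 0.8) medium, [0.8, ∞) large. Zero pooled SD marks the item
undefined rather than infinite.

## Synthetic data: what it emulates, what it does not

The generator mirrors the structure of a large norming study: 4
self-identified race groups × 2 genders (400 per cell at full scale;
drivers use 50 per cell for desk-scale runs), 31 nonverbal + 20 verbal
(m = 3) and 13 concealed (m = 4) items with a ~ U[0.8, 2.5] and
thresholds in [−2, 2] at a minimum gap of 0.3, sparse assignment of
16/12/4 items per respondent, six-option keys, concealed displays built
from the four opposite-valence masking patterns (content/anger and
joy/sadness in both directions), and 1–5 ratings discretized around
moderate latent means (intensity ≈ 2.7, believability ≈ 3.1, pinned to
1.2 for concealed displays). The default seed is 20230719; every output
is a pure function of (spec, seed).

Crucially, graded categories are drawn through the engine's own
`category_probs` — one probability implementation for simulation and
estimation — and raw label choices are constructed so that re-scoring them
reproduces the drawn categories exactly. This makes the end-to-end
recovery tests sharp, but it also means passing tests show internal
consistency and estimator correctness under the model, not robustness to
real-data features the generator omits: multidimensionality, rater
response styles and biases, label-menu effects, unequal cell sizes,
missingness that is not random, or confusion gradients (a
confusion-gradient choice mode exists for stress-testing distractor
selection but is off by default). Simulated demographic groups are
exchangeable by construction unless a threshold shift is planted, so
group differences in unplanted runs are pure sampling noise.

## Problem sizes and numerical conventions

Parameter recovery is benchmarked at n = 2000 respondents × 31
trichotomous items (discrimination correlation ≥ 0.90, threshold RMSE
≤ 0.2); likelihood-oracle checks use ≤ 3 items and n ≤ 50 against direct
summation (1e−10) and exhaustive coarse grids; DIF behavior is checked at
n = 1000 per group with a planted threshold shift of 0.75; item-fit
calibration uses 200 replicates of 5 items × 500 respondents. The
analysis drivers run the whole chain at 400 respondents with sparse
assignment and slightly looser EM settings (tol 1e−3, cap 300), chosen as
a desk-scale configuration whose statistics are honest about their own
sampling noise. Probabilities are clipped at 1e−300 before logs and 1e−12
in M-step ratios; category probabilities are clipped into [0, 1] against
floating-point underflow.

## Known limitations

- The summed-score item-fit statistic requires complete cases; under the
  sparse default design it is reported unavailable per item instead of
  being computed on incomparable totals.
- Mean/mean linking assumes the anchor set is DIF-free; with many strongly
  biased anchors the d-DIF of unbiased items inflates (purification
  mitigates, at the cost of a data-dependent anchor set).
- The d-DIF sampling floor rises quickly as per-group item exposure
  falls; desk-scale sparse runs show means near 0.2 under the null, as
  the drivers' output notes.
- Unidimensional calibration per modality is assumed, not tested;
  multidimensional IRT and MCMC estimation are out of scope.
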