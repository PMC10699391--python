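# Methods

## Measurement model

Dichotomous responses are scaled with the Rasch model: the probability that
person *n* answers item *i* correctly is `exp(θ_n − δ_i) / (1 + exp(θ_n −
δ_i))`, with ability θ and difficulty δ in logits on one latent scale. The
model's two structural properties drive the whole design: the raw score *r*
is sufficient for θ, and the item totals are sufficient for δ given the raw
scores.

### Item calibration (CML)

Difficulties are estimated by conditional maximum likelihood. Conditioning
on each person's raw score eliminates the person parameters, so the
estimates assume nothing about the ability distribution. The conditional
likelihood of the item totals `s_i` given raw-score counts `n_r` is

    log L(δ) = −Σ_i s_i δ_i − Σ_r n_r log γ_r(ε),

where `γ_r` is the r-th elementary symmetric function (ESF) of the
easiness terms `ε_i = exp(−δ_i)`. ESFs are computed by the one-item-at-a-
time summation recursion (never subset enumeration). The first- and
second-order quantities needed for Newton steps — the ESFs of the item set
with one or two items removed — are built by merging *prefix* and *suffix*
ESF vectors with a positive-term convolution. This split-and-merge form is
cancellation-free, unlike the classical deflation recursion, whose
alternating signs lose all significant digits by the 60-item scale (a
convenience deflation routine is still exported for small vectors, with
this caveat documented).

Newton iteration uses the exact conditional information matrix
`H = Σ_r n_r Cov(x | r)`. H is singular along the all-ones direction (the
scale-origin gauge); the step is computed from `H + 11ᵀ/n` and re-centred,
which pins the mean-zero identification constraint. Iterations stop when
the gradient's maximum absolute entry falls below 1e−8 (default) or after
100 iterations, with a halving line search far from the optimum and plain
Newton steps once `max|g| < 1e−4`, where the objective's floating-point
resolution can no longer certify descent but quadratic convergence is
guaranteed. On the simulated 60-item/2000-person cohorts used in the tests
the solver converges in about 5 iterations.

Persons with zero or perfect raw scores carry no conditional information
and are excluded from calibration; items answered all-correct or
all-incorrect by the retained persons have no finite estimate and are
likewise excluded. Exclusion alternates until stable (dropping a degenerate
item can turn a person extreme, and vice versa) and both lists are reported
explicitly — nothing is silently dropped. Standard errors come from the
diagonal of the inverse pinned information matrix.

### Person measurement (WLE)

Abilities use Warm's weighted likelihood estimator: θ̂ solves
`r − Σ p_i + J/(2I) = 0` with `I = Σ p_i(1−p_i)` and
`J = Σ p_i(1−p_i)(1−2p_i)`, found by safeguarded Newton/bisection to a
residual below 1e−10. WLE is finite at r = 0 and r = n, so every candidate
— including perfect scorers — can receive a map; plain ML cannot do this.
Because the estimator depends on the data only through r, equal raw scores
on the same item set give bitwise-identical estimates (the solver is run
once per distinct raw score). SE = 1/√I at the estimate.

Calibration and measurement are deliberately decoupled: in operational use
the bank difficulties are anchored from prior calibrations (assumed
invariant across administrations) and person measurement runs against them
directly.

### Pass standards and fit

A percentage pass mark is converted to logits by inverting the test
characteristic curve `T(θ) = Σ_i p_i(θ)` (strictly increasing; bisection to
1e−8). Targets at or beyond 0 or n have no finite solution and are
rejected. Item quality is screened with infit (information-weighted) and
outfit (unweighted) mean-square residual statistics; both have expectation
1 under the model, and cells with numerically degenerate probabilities are
excluded from the sums with a logged count.

## Map construction

Four inputs make the map: the items, their subject clusters, their
difficulties, and the candidate's correct/incorrect pattern.

- **Placement**: each administered item goes left (correct) or right
  (incorrect) of the central axis at height δ.
- **Co-location**: within each (cluster, side) cell, items are merged by
  single linkage with a 0.15-logit window — on a one-dimensional axis this
  is exactly the transitive closure of the pairwise within-window relation,
  so chains merge even when their end-to-end span exceeds the window. The
  group label carries the member count, "DECEL (2)". The 0.15 default is
  roughly the difficulty standard error at realistic cohort sizes, so items
  closer than the data can distinguish are shown as one cluster;
  it is configurable, and zero tolerance degenerates to singletons except
  exact ties.
- **Quadrants**: when a pass line is set, (above/below pass) × (left/right)
  partitions the items. Items exactly on the line fall in the lower
  quadrants; a difficulty exactly at the ability line counts as "at or
  below" for flagging. Both closed-below conventions keep revision guidance
  conservative.
- **Flags**: a cluster is a *weakness* when ≥ 2 of its items are incorrect
  at or below the candidate's ability (easy misses), and a *strength* when
  it has ≥ 3 items, no easy misses and at least one correct item above the
  ability line; weakness wins if both fire. The published reports mark
  these regions with hand-drawn ellipses; this deterministic counting rule
  operationalises them and both thresholds are configurable.

The polytomous extension maps each score category of a partial-credit item
at its own adjacent-category threshold δ_ik: categories 1..x on the left
for attained score x, the rest on the right. Thresholds are anchored
inputs; PCM parameter estimation is out of scope, which keeps the module
verifiable against closed forms. Category probabilities are computed in log
space, so extreme abilities stay normalised. A one-threshold PCM item
reduces exactly to the dichotomous rules. Polytomous categories do not join
dichotomous co-location groups.

The CTT variant positions items at 100 − facility on a 0–100 axis (the
inversion makes "harder is higher" match the logit map). Practitioner
levels partition [0, 100]: level 0 below 55, level 1 the closed band
[55, 65], level 2 (65, 75], level 3 strictly above 75. The level-1 and
level-3 edges are fixed by the published bands; the closure of the
unstated level-2 boundaries follows the strict ">" printed for level 3 and
the requirement of a gapless partition.

## Rendering

SVG is produced by direct string templating with fixed 3-decimal
coordinates, so identical layouts give byte-identical documents — the
property the golden-file tests pin. Labels are anchor-positioned (no font
metrics), vertical position is affine in logits, and overlapping labels in
one column are separated by a fixed 0.1-logit nudge applied in document
order. Flagged clusters get a bounding ellipse (green strength, red
weakness) around their groups on the relevant side. The text renderer draws
one row per 0.25-logit band (an item in band [k·0.25, (k+1)·0.25) prints on
that band's row), with `=` fill on the ability row and `-` on the pass row.

## Synthetic data

No real candidate data or bank content is distributable, so all fixtures
are generated. The generator draws abilities Normal(μ, σ) and responses
Bernoulli at the ICC (or multinomial at the PCM category probabilities),
fully reproducible under a seed on one platform. The exam-shaped fixture
mirrors the assessment's structure: 60 dichotomous items across the 8
canonical subject clusters assigned round-robin, difficulties evenly
spaced on [−3, 3] (the span visible on operational maps), 200 candidates
with θ ~ Normal(0.5, 1). Test cohorts of 2000 persons are used where
parameter-recovery precision matters.

What the generator does **not** emulate: guessing and carelessness
(3PL-style misfit), multidimensionality across clusters, item drift over
administrations, speededness, or missing-by-design booklets. Passing tests
therefore demonstrate correctness of the estimators and map algebra under
the Rasch model, not robustness of the feedback to violations of it; the
miskeyed-item test shows only that gross misfit is detectable by outfit.

## Numerical choices

- ESF: summation recursion; derivative ESFs via prefix/suffix convolution
  (all positive terms). Verified against subset enumeration to < 1e−10
  relative error for n ≤ 12.
- CML: gradient tolerance 1e−8, ≤ 100 iterations, PROX-style start
  (centred logit of item facility), damped line search with an absolute-
  plus-relative acceptance band.
- WLE: residual < 1e−10, bracket expanded until sign change; the Newton
  slope uses the dominant −I term with bisection safeguards.
- TCC inversion: bisection to 1e−8 on an auto-expanded bracket.
- Ties: items with equal difficulty merge at any tolerance ≥ 0; group
  order within a column breaks ties by item id.

## Known limitations

- Calibration covers complete dichotomous matrices only; structurally
  missing responses are supported in scoring/facility but not in CML.
- No 2PL/3PL, marginal-ML, Bayesian estimation, or differential item
  functioning analysis.
- The co-location window and flag thresholds are conventions, not
  estimates; operational programmes should review them against their own
  item standard errors.
- Exact numeric agreement with any external production scaling (different
  estimator, different identification) is not expected; the common logit
  scale is identified here by the mean-zero constraint.
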