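# Methods

`grmsim` implements a complete Monte Carlo study of item-bank pruning and
severity-matched item selection for a three-category rating scale, built on
the graded response model (GRM). This note records the model, the generator
design, the numerical choices, and what the package's tests do and do not
establish.

## Model

For item *j* with discrimination *a<sub>j</sub>* > 0 and ordered thresholds
*b<sub>j1</sub>* < *b<sub>j2</sub>*, the boundary probabilities are logistic
in the latent ability θ:

p\*<sub>jc</sub>(θ) = 1 / (1 + exp[−D·a<sub>j</sub>(θ − b<sub>jc</sub>)]),  c = 1, 2

and category probabilities telescope: p<sub>0</sub> = 1 − p\*<sub>1</sub>,
p<sub>1</sub> = p\*<sub>1</sub> − p\*<sub>2</sub>, p<sub>2</sub> = p\*<sub>2</sub>.
Item information is the standard graded-model form

I<sub>j</sub>(θ) = D²a<sub>j</sub>² Σ<sub>c</sub> [p\*<sub>c</sub>q\*<sub>c</sub> − p\*<sub>c+1</sub>q\*<sub>c+1</sub>]² / p<sub>c</sub>(θ),

with p\*<sub>0</sub> ≡ 1, p\*<sub>3</sub> ≡ 0, q\* = 1 − p\*; the test
information function (TIF) is the sum over the bank.

**Scaling constant D.** The package uses a single D for generation and
estimation, so all results are internally consistent whatever its value; the
default is **D = 1.0**. With the calibrated mean discrimination ā ≈ 2.93,
D = 1.0 puts the effective slope D·ā ≈ 2.9. We examined D = 1.7 (the
normal-ogive approximation) and rejected it as a default for this study
design: at D·ā ≈ 5 the items are nearly Guttman-deterministic, so (i) the
most extreme simulated cases answer all items with 0 or 2 and are removed by
the degenerate-case rule (≈ 10 of 300 expected), truncating the ability
distribution and compressing all recovered parameters by ~8%; (ii) each
item is informative only in a narrow θ window, so residual correlations are
estimated from a handful of effective cases and Yen's Q3 becomes heavy-tailed
(even residuals formed from the *true* abilities and parameters produce ~10
spurious |Q3| > 0.2 flags); and (iii) dependence-injected pairs whose
difficulty midpoints are far apart share no stochastic window and cannot be
detected at all. D remains configurable for users who want the 1.7 metric.

## Estimation

Item parameters are estimated by marginal maximum likelihood with a standard
normal latent prior, via EM:

- **E step.** Posterior weights of fixed quadrature nodes per case
  (rectangular grid on [−5, 5] with normalized normal weights; 101 nodes by
  default). 101 nodes is the coarsest grid at which doubling the node count
  moves the fitted marginal log-likelihood by < 10⁻⁵ relative on the default
  bank; much coarser grids alias the narrow case posteriors and can pull the
  whole threshold set off location.
- **M step.** Per-item maximization of the expected complete-data
  log-likelihood with analytic gradients (L-BFGS-B, warm-started, a bounded
  number of inner iterations — a generalized-EM step that preserves the
  ascent property). Threshold order is structural: b₂ = b₁ + exp(γ).
- **Stopping.** Marginal log-likelihood improvement < 10⁻⁵ (absolute), at
  most 500 iterations; non-convergence is reported, never hidden. The
  marginal log-likelihood is asserted non-decreasing across iterations.
- **1PL variant.** One shared discrimination, free thresholds: 2J + 1
  parameters versus 3J for the 2PL. AIC = −2logL + 2k and
  BIC = −2logL + k·ln(n) use the number of analyzed cases.
- **Abilities.** EAP (posterior mean) under the standard normal prior on the
  same grid; EAP is finite for every response pattern, including constant
  rows, which maximum-likelihood scoring cannot handle.

An item with a never-observed category has an inestimable threshold; fitting
fails with an item-level diagnostic rather than silently collapsing
categories.

## Synthetic data generator

The generator emulates a 300-case, 71-item, three-category rating study in
which ability rises with case ID and difficulty rises with item ID:

- **Abilities.** Deterministic standard-normal quantiles
  θ<sub>i</sub> = Φ⁻¹((i − ½)/n) by default (stabilizes study-level
  quantities across seeds); options: an equally spaced grid on ±√3 with unit
  variance, or sorted normal draws.
- **Items.** Difficulty midpoints equally spaced on [−1.3, 1.3];
  thresholds at midpoint ± δ with δ = 0.44 (so mean b₁ = −0.44 and mean
  b₂ = +0.44 exactly); discriminations i.i.d. uniform on [2.43, 3.43]
  (mean 2.93). These values calibrate the generator so that the *fitted*
  2PL summaries reproduce the study's printed estimates, making parameter
  recovery a meaningful end-to-end check.
- **Responses.** Each response categorizes a uniform deviate against the
  item's boundary probabilities at the case's true θ.
- **Local dependence.** Ten designated item pairs share latent deviates
  through a Gaussian copula with correlation ρ = 0.8, which co-moves their
  responses while leaving every marginal category probability intact. Three
  items appear in two pairs each; a joint normal with ρ = 0.8 on both edges
  of such a star *requires* a leaf-to-leaf correlation of at least
  2ρ² − 1 = 0.28, so the generator completes each connected component with
  the smallest uniform cross-correlation that keeps the matrix positive
  semidefinite (found by bisection) and logs it. This is the closest
  realizable approximation to "dependence only within designated pairs".
- **Degenerate cases.** Rows scoring 0 on all items or 2 on all items are
  removed (all-1 rows are kept). Under the defaults the expected removal
  count is ≈ 2–5 of 300; the per-case removal probability has a closed form
  (product of extreme-category probabilities) that the tests use as an
  oracle.

What the generator does **not** emulate: rater behavior and rating drift,
case-mix heterogeneity beyond a unidimensional θ, missing responses, and any
kinematics of the underlying training device. Passing tests therefore show
that the *analysis chain* recovers known structure from data generated by the
fitted model family — not that real rating data satisfy that family.

## Local-independence screening

Q3 for items (j, k) is the Pearson correlation across cases of residuals
x<sub>ij</sub> − E[x<sub>j</sub> | θ̂<sub>i</sub>], with θ̂ the EAP scores
from the full-bank fit and E the model-expected item score Σ<sub>c</sub>
c·p<sub>jc</sub>(θ). Pairs with |Q3| > 0.2 (configurable) are flagged; items
whose residual variance is zero are excluded from pairing with a warning.

Three exclusion strategies resolve each flagged pair by dropping the member
with (a) the lower maximum of the category-1 probability curve over
θ ∈ [−4, 4] (step 0.01), (b) the lower maximum of the item information
function (optionally: information at the category-1 peak), or (c) the lower
discrimination. Ties drop the higher item ID. The excluded set is the
**union of per-pair losers**: a pair whose loser already lost another pair
contributes no new exclusion, which is why strategies can leave different
bank sizes when flagged pairs share items. (An alternative — skipping any
pair with an already-excluded member — cannot produce the reference study's
own excluded-ID list, which contains both members of one overlapping star.)

The strategy × model comparison grid refits each pruned bank under the same
model that produced its flags (2PL and 1PL branches are fully separate), and
marks a single winner only when the smallest AIC and smallest BIC agree;
exact ties resolve to the earlier row (2PL first, no-exclusion before
strategies in listed order).

**Known limitation.** At n = 300 the sampling noise of a residual
correlation is ≈ 0.06, so among 2,485 pairs a handful of spurious
|Q3| > 0.2 flags per run is *expected* even under exact local independence
(≈ 3–7 observed, concentrated among items with nearby difficulties), and
the leaf-to-leaf correlations forced inside shared-item stars occasionally
add one more. Consequently the flagged-pair count runs above the ten
injected pairs and the pruned bank below 61 items, and the second
polychoric eigenvalue of a 71-item bank estimated from 300 cases sits near
1.0–1.35 rather than well below 1. These are structural sample-size effects,
not estimator defects; they disappear at n ≈ 1000 (larger `n_cases` in
`GeneratorConfig`).

## Dimensionality and reliability

Polychoric correlations use the two-step estimator: thresholds from marginal
cumulative proportions via the inverse normal, then the pairwise correlation
maximizing the bivariate-normal contingency likelihood on (−0.999, 0.999)
(Brent; the bivariate normal CDF is evaluated through Owen's T function to
~10⁻¹⁴). Indefinite pairwise matrices are repaired by flooring negative
eigenvalues at zero and renormalizing the diagonal (logged). Parallel
analysis resamples every item independently from its observed margins
(preserving marginal distributions under a local-independence null),
computes replicate polychoric eigenvalues, and retains leading components
exceeding the 95th percentile; the Kaiser-style second-eigenvalue < 1 check
is reported alongside. Cronbach's α uses raw 0/1/2 scores with n−1
variances.

## Severity-banded selection

Severity bands partition θ: severe [−2.0, −0.5), moderate [−0.5, 0.5),
mild [0.5, 2.0), all [−2.0, 2.0). Within a band, items are scored by the
**mean** over the band grid (step 0.01) of either the category-1 probability
curve or the item information function; `max` aggregation is available. The
study reports one top-7 set per band, so a grid-to-set aggregation is
unavoidable; the mean is the default because it rewards items useful across
the whole band rather than at a single θ. Rankings sort descending with ties
broken by ascending item ID, making selection deterministic. Criterion
comparison refits the 2PL on each top-7 bank using **all** cases (the
single-n BIC behavior of the reference comparison), marks the per-band
winner when AIC and BIC agree, and recommends the criterion winning the
most bands.

Monotonicity is declared when Spearman's correlation between EAP ability and
per-case mean score exceeds 0.95 and a 20-bin binned-mean curve is
non-decreasing up to one inversion of at most 0.02.

## Pipeline, sizes and runtimes

`run_pipeline` chains: generate → eliminate degenerate cases → fit 2PL →
EAP → descriptives/dimensionality → Q3 → all strategies × both models →
winner refit → re-diagnosis (Q3, eigenvalues, monotonicity) → curves →
band × criterion selection → `StudyReport` (JSON + CSV artifacts, config
hash and versions recorded). Everything is deterministic given the seed;
substreams for parameters, abilities and responses are spawned from the
master seed.

Default problem sizes were chosen to keep a full study run at roughly a
minute (one 300 × 71 2PL fit ≈ 2 s at 101 nodes; the 8-cell strategy/model
grid ≈ 1 min; parallel analysis at 100 replicates on 71 items is the one
expensive diagnostic, ≈ 2–4 min, and is configurable via `parallel_reps`).
Property tests that need replication (detection power, false-positive
control) use 50 seeds of the default study.
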