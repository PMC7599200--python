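# Methods

## The model

`cbschoice` estimates binary-choice utility models of the discounting form

    U = A · f(X)

where `A` is a monetary amount and `X` is either a delay `D` in days
(intertemporal choice, ITC) or a win probability `p` (risky choice, RC).
Choices follow a binary logit on the utility difference,

    log[ p(choice = 1) / p(choice = 2) ] = σ (U₁ − U₂),

with `σ ≥ 0` the inverse choice noise.  Because `σ` multiplies the utility
difference, it absorbs monetary units: scaling all amounts by `c` and `σ` by
`1/c` leaves the likelihood unchanged.  This identifiability fact is what
lets the weighting function `f` live on a normalized [0, 1] × [0, 1] box.

The package's contribution is the structured non-parametric estimator of
`f`: a chain of one or two cubic Bezier pieces whose control points are the
free parameters, constrained to be monotone (decreasing in delay, increasing
in probability).  Alongside it the package implements the standard
parametric zoo in discounting form (exponential, hyperbolic, generalized
hyperbolic, log-time power, quasi-hyperbolic, double exponential for ITC;
power expected utility, probability hyperbolas and the
Goldstein–Einhorn / Tversky–Kahneman / Prelec weighting families for RC,
plus the non-discounting risk–return, linear-attribute and
coefficient-of-variation forms) so the spline can be benchmarked against
them on equal footing.

## Bezier geometry

A piece is four control points; its x- and y-coordinates are independent
cubic Bernstein polynomials `m(t)`, `n(t)` of an internal parameter
`t ∈ [0, 1]`, and the function value at `x` is `y = n(m⁻¹(x))`.  Keeping
both handles inside the endpoints' bounding box (closed intervals, so
handles may touch edges and flat segments are allowed) is sufficient for
monotonicity; this is the only shape assumption.

* **Inversion.** `m(t) = x` is solved by a safeguarded Newton iteration on
  the bracket [0, 1]: any step that leaves the bracket, or a vanishing
  derivative, falls back to bisection, so convergence is guaranteed for
  monotone `m`.  Closed-form cubic roots are never used (radicals are
  numerically fragile here).  The internal solver targets an x-residual of
  1e−13 so that even steep curves are reproduced to ~1e−11 in y; the public
  `invert_x` documents a 1e−10 tolerance.  Exact endpoint queries are pinned
  to `t = 0` or `t = 1`, making endpoint values exact.  An `x` exactly at a
  shared joint belongs to the left piece (continuity makes the value
  identical either way).
* **Evaluation** is in Bernstein form, which interpolates the endpoints
  exactly and is verified against a de Casteljau evaluator to 1e−12.
* **Subdivision** is exact de Casteljau splitting.  A subtlety that matters:
  subdivision preserves the traced curve (hence monotonicity) but *not
  necessarily* the handle-box certificate — the box condition is sufficient,
  not necessary, and a parent with handles on opposite box edges can produce
  a child whose handle leaves the child's endpoint box.  Where a certified
  2-piece representation of a 1-piece curve is needed (warm starts, nesting),
  a ladder of split points starting at `t = 0.5` is searched for one whose
  children keep the certificate.
* **Area under the curve.** `∫ y dx = Σ ∫₀¹ n(t) m′(t) dt` per piece, a
  degree-5 polynomial integrated in closed form from the power-basis
  coefficients; no quadrature is used in the production path.  The closed
  form is validated against adaptive quadrature of the evaluated curve to
  1e−8 in the tests.

## CBS parameterizations

Anchors (fixed control coordinates):

* ITC: `f(0) = 1` — the immediate option is undiscounted — and the last
  x-coordinate is the normalized maximum delay; the terminal value
  `f(x_scale)` is free in [0, 1].  Delays are divided by `x_scale` (default
  180 days, the design maximum) identically at fit and evaluation time, and
  the curve never extrapolates beyond it.
* RC: `f(0) = 0` and `f(1) = 1` — impossible and certain outcomes anchor
  the weighting function, as every parametric RC weighting family obeys.

These anchors are identified because `σ` carries the overall utility scale.
Free parameters: 1-piece ITC has 5 (two handles and the terminal value),
1-piece RC has 4.  The 2-piece chain adds the joint, a second-piece handle
and an extension scalar `s ≥ 0` that places the outgoing handle at
`P₄ = joint + s · (joint − P₂)`; collinearity of the smooth join is thereby
enforced by construction rather than as an optimizer equality constraint,
and the chain has exactly one fewer free coordinate than raw control points.
The remaining constraints (handle boxes, joint ordering and the bilinear
caps that keep `P₄` inside the second piece's box) enter the optimizer as
linear/bilinear inequality constraints.

## Maximum-likelihood fitting

The log-likelihood sums log choice probabilities with probabilities clipped
at 1e−12 so boundary fits stay finite.  `σ` is optimized on the log scale in
[1e−6, 1e6].  Optimizers: SLSQP for CBS (bounds + inequality constraints),
L-BFGS-B for box-bounded parametric families; gradients are numerical.
Convergence: relative tolerance 1e−9 on the objective, at most 500
iterations per start (the recovery grid uses a capped desk-scale
configuration, below).  During line search a constrained optimizer may probe
mildly infeasible points; the objective evaluates a coordinate-wise
projection onto the feasible set so the curve is always defined, and the
final answer is projected once and re-validated.  The public likelihood
function, by contrast, rejects infeasible parameters outright.

Starts: one deterministic "diagonal" start (the straight line through the
anchors; for 2-piece, its exact midpoint subdivision), a seeded pool of
random feasible draws (per-start seeds are `seed + i`), plus any
caller-supplied warm starts.  For parametric families a coarse deterministic
grid over the parameter box (5–8 points per parameter, log-spaced for
positive parameters, at σ = 1) is screened by likelihood as well.  The
screening matters: in a misfit parameter region the σ = 1 likelihood
saturates trial-wise and becomes cliff-like, and a local optimizer started
there reliably slides into a small-σ basin far above the global optimum;
screening the grid first keeps the searched region covered at negligible
cost.  The best candidates (and every warm start) are polished; a start is
never made worse — if polishing fails or diverges, the start's own
likelihood remains a candidate — which also makes the 2-piece fit provably
no worse than a supplied subdivided 1-piece optimum.

Datasets with entirely one-sided choices fit to a boundary and are flagged
(`separation`), as are active box constraints at the optimum.

## Predictive metrics

* **Accuracy**: hit rate of the modal predicted choice, with a predicted
  probability of exactly 0.5 scoring 0.5 (an unbiased tie rule).
* **Tjur's D**: mean predicted probability among option-1 choices minus the
  mean among option-2 choices; 0 for a random model, 1 for a perfect one,
  invariant to which option the probabilities refer to.
* **LOOCV**: n refits, each excluding one trial and predicting it.
  Eligibility requires at least two trials of each choice type (otherwise
  some training folds would be entirely one-sided).  Folds deliberately do
  not reuse the full-data fit as a warm start: with a multimodal likelihood
  the warm start — which saw the held-out trial — can steer which local
  optimum a fold converges to, leaking the held-out choice into its own
  prediction.  Each fold therefore uses only the fixed start set, making its
  prediction a deterministic function of the other n − 1 trials alone (this
  is asserted by a choice-flipping test).

## Interpretive measures

* **AUC** of the fitted curve over the normalized domain: a model-agnostic
  index of patience (ITC) or risk tolerance (RC).  Its standard error is the
  delete-one jackknife over n leave-one-trial-out refits,
  `SE = sqrt[(n−1)/n · Σ (AUC₍ᵢ₎ − mean)²]`; these refits keep the full-fit
  warm start (an SE computation has no hold-out contract).
* **Delay-specific discount rate** `h(D) = ln(−ln f(D) / D)`, constant and
  equal to `ln k` under exponential discounting; undefined where `f` is 0 or
  1.
* **Average daily change in discount rate**: the endpoint slope of `h` over
  the daily grid `D = 1 … x_scale`, skipping undefined grid days.  The grid
  starts at one day to avoid the `D → 0` singularity; endpoint slope,
  regression slope and mean finite difference coincide in sign for monotone
  `h`, and the sign (decreasing / roughly constant / increasing impatience)
  is the quantity of interest.
* **Probability-specific risk aversion** `q(p) = ln(f(p)/p)`, the log odds
  of subjective to objective probability; **switches** are sign changes of
  `q` on the grid `p = 0.01 … 0.99` with a 1e−6 dead band so riding the
  identity line is not counted as crossings.

## Synthetic data

The factorial recovery design pits a fixed $20 option (immediate/certain)
against a larger option: amount `20 / ratio` with `ratio` stratified-uniform
on (0.05, 1) — the 0.05 floor keeps amounts bounded at $400 — and attribute
stratified-uniform on (0, 180] days or (0, 1), one draw per bin, crossed
factorially into `n_levels²` trials (49–400).  Stratified-uniform sampling
reproduces the squared trial counts while staying uniform marginally; an
exact even grid is available via `scheme="grid"`.  The delay domain is open
at zero because the log-time and quasi-hyperbolic families are defined there
only by the `f(0) = 1` convention.  Choices are Bernoulli draws from the
logit rule at σ = 1.  An "empirical-like" generator mirrors the ranges of a
typical 120-trial human session ($20 vs. $22–85 at 20–180 days; $20 vs.
$21–85 at p = .09–.98).

Twelve generating families (six per task) each carry four fixed parameter
sets in the registry.  Recovery is scored by the mean absolute error between
fitted and generating `f` on a fixed 1000-point grid over the attribute
domain — an out-of-sample function-estimation measure, so a flexible model
can lose to a simple one at small n through variance.

What the generator does *not* emulate: session-to-session retest structure,
heterogeneous per-trial attention or lapses, non-logit noise, amount
nonlinearity beyond what the discounting form absorbs.  Passing recovery
tests therefore shows estimator correctness and efficiency under the stated
noise model, not robustness to violations of it.

## Desk-scale defaults

The shipped test suite and the reproduction script run the recovery study at
desk scale: 20 replicates per condition (the library supports any count),
the two extreme design sizes (49 and 400 trials), and a fit configuration of
one random start plus the deterministic start and the screening grid, with a
60-iteration cap and 1e−7 objective tolerance (verified to reproduce the
heavier configuration's correct-fit errors before adoption).  These sizes
were chosen so the full ITC study fits comfortably in a coffee break on one
core; the orderings they test (correct parametric model as the error floor
at large n; 1-piece CBS beating the model-averaged parametric error at both
sizes; errors shrinking with n) are scale-free claims.  One caveat the study
itself surfaces: on nearly-nested generating conditions (e.g. mildly
discounted generalized-hyperbolic data) a parsimonious neighboring family
can undercut the correctly specified family's function error at finite n,
because the extra shape parameter costs variance — the "correct model as
floor" reading is exact in the family-averaged aggregate, not guaranteed
condition by condition.

## Design choices where the design was open

* The RC model list implements the nine standard forms named above; the
  estimator itself is agnostic to additions via the family registry.
* The ITC terminal value `f(x_scale)` is left free rather than anchored.
* Raw prospect-theory estimation (`U = f(A)·h(p)`) is out of scope: it is
  not identifiable from standard choice sets, which is exactly why the
  converted discounting forms are used.
* Ties at `p̂ = 0.5`, the daily trend grid, and the switch dead band are as
  documented above; none of these choices affects the sign-level claims they
  feed.

## Known limitations

* No extrapolation: a CBS fit is undefined beyond the attribute range it was
  configured for, and there is no default shape in data-sparse regions —
  heavily one-sided sessions yield boundary fits (flagged) and wide
  jackknife SEs.
* At most two pieces; more pieces would need a joint-placement scheme and
  stronger regularization.
* Individual-level fits only; no pooling or hierarchical estimation.
* Analytic gradients are not implemented; fitting cost is dominated by
  numerical differentiation of the spline likelihood.
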