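# Methods

## Model

A triad presents three achromatic patches: a standard at lightness `L*`
(CIELAB, 0–100), a darker test at `L* − d1`, and a lighter test at
`L* + d2`.  The observer reports which test differs more from the
standard.  Perception is modeled after Thurstone's comparative judgment:
the percept of stimulus `S_i` is normal, `N(ψ_i, σ_disc)`, with a single
discriminal dispersion for all stimuli (Case V).  Three nested choice
models map a triad to the probability of choosing the darker test:

* **baseline** — `ψ = a·L*`: `P(dark) = Φ(a(d1 − d2))`;
* **g** — a monotone perceptual function `ψ = g(L*)`:
  `P(dark) = Φ((g(m) − g(m−d1)) − (g(m+d2) − g(m)))`;
* **g + f** — a difference-scaling function applied to perceived
  differences: `P(dark) = Φ(f(g(m) − g(m−d1)) − f(g(m+d2) − g(m)))`.

The inverse-normal link has fixed unit SD; the constant `√2·σ_disc` that
scales the difference of two independent percepts is absorbed into the
estimated curves.  A concave `f` means a large perceived difference is
smaller than the sum of its perceived sub-intervals — diminishing
returns.

`g` and `f` are monotone piecewise-cubic interpolants (PCHIP,
Fritsch–Carlson derivatives) through an origin knot plus four control
points.  Knot abscissae are fixed — equally spaced over the observed
stimulus range for `g`, and over `[0, max perceived one-sided
difference]` for `f` — and only the ordinates are estimated, which
matches the "origin plus four estimated control points" convention and
keeps the parameter count at 1 / 4 / 8.  PCHIP is shape-preserving
(values between knots never overshoot the bracketing ordinates) and
commutes with positive affine maps of the ordinates, which makes the
presentation rescaling below exact.

### Crowdsourcing noise

On an uncalibrated display the rendered lightness deviates from the
intended one.  Because the three patches of a trial share one screen and
one viewing situation, the deviation is modeled as a single additive
offset `δ ~ N(0, σ_err)` applied to all three stimuli of a trial (drawn
at most once per trial; a per-participant-session variant is provided,
as the data cannot distinguish the two scopes here).  The effective
percept dispersion becomes `σ_cs = √(σ_disc² + σ_err²)`.  Since the
extra noise is zero-mean, the crowdsourced sample mean targets the same
perceived strength; equating the standard errors `σ_cs/√n_cs =
σ_disc/√n_in` yields `n_cs = n_in σ_cs²/σ_disc²`, the inversion
`σ_err/σ_disc = √(n_cs/n_in − 1)`, and the effect-size rescaling
`d_cs = d_in σ_disc/σ_cs`.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| standards | {30, 40, 50, 60, 70} | L* | the study grid (320 triads) |
| offset grid | 0–30 step 2.5, Δd ∈ {±2.5, ±5, ±10} | L* | ditto |
| gamut filter | standard ≥ 50 | L* | darkest displayed gray L* = 20 |
| σ_disc | 5 | L*-equivalent | the worked noise-budget example; gives ≈77% simulated accuracy, near the reported in-person level |
| σ_err (crowdsourced) | 12 | L* | the same worked example; ratio 2.4 sits under the inferred bound of ≈3 |
| participants | 33 in-person / 250–300 responses-per-triad crowdsourced | — | the two study regimes |
| link SD | 1 (fixed) | — | identifiability |
| likelihood clipping | 1e−9 | probability | numerical safety |
| optimizer | L-BFGS-B on log-increments, 5 restarts, ftol 1e−6 | — | monotonicity by construction; multi-start guards the joint fit |
| planner tails | one-tailed | — | the convention that reproduces both published planner sizes (10 and 50); explicit `tails` flag |

## Estimation choices

Free parameters are log-increments of the knot ordinates (and the log
slope), so every candidate curve is strictly increasing and the
optimization is unconstrained.  The likelihood is computed from
per-triad binomial counts, making cost independent of the number of
responses.  In the joint g+f model the scale of `g` and the domain of
`f` trade off exactly (`g → cg`, `f(x) → f(x/c)` leaves every
probability unchanged); tying `f`'s knot abscissae to the current
maximum perceived difference under `g` makes the likelihood flat along
that ray, and the optimizer simply stops somewhere on it.  The joint fit
is warm-started from the g-only solution, which is itself started from
the empirical probit slope.  `g` is refitted jointly when `f` is added
(the alternative — freezing `g` — was not adopted; the joint optimum
dominates by construction).

For presentation, `rescale_model` divides `g`'s ordinates by its rise
over the stimulus range (so ψ spans [0, 1]) and multiplies `f`'s
abscissae by the same factor; because PCHIP commutes with positive
affine ordinate maps this leaves all choice probabilities unchanged to
rounding (`< 1e−10` verified over the 192-triad design).  A `g`-only
model gains an explicit linear `f` carrying the compensation.  When two
studies' `f` curves are compared, both are taken through this transform
(affine on both axes); curves are evaluated with flat clamped
extrapolation outside their knot range, with a warning.

The `g` origin is anchored at the minimum presented stimulus (not
L* = 0): the likelihood only sees differences of `g`, so the anchor is a
pure convention; anchoring inside the observed range avoids estimating
unconstrained curve segments.

## Synthetic data

The generator emulates the stated study: each simulated participant
answers every triad; per trial a shared offset `δ` (truncated so all
three patches stay inside L* ∈ [0, 100]; the quadrature oracle
integrates over the same truncated law) and a decision noise
`ε ~ N(0, √2 σ_disc)` produce `chose_dark ⇔ D_dark(δ) − D_light(δ) + ε > 0`.
Truth presets: `linear` (unit-slope baseline), `concave_g` (compressive
`100(x/100)^0.7`), `diminishing_returns` (linear `g`, strictly concave
`f = 40(x/40)^0.6` with decreasing knot increments).

What the generator does **not** emulate: feedback-driven learning across
trials (the task gives right/wrong feedback), lapses and response
biases, per-participant dispersion differences, chromatic or
monitor-specific error structure, and the per-participant 70-triad
subsetting of the original crowdsourced deployment.  A green test
therefore establishes that the estimator and planner behave correctly
under the stated noise model — not that real observers satisfy it.

Two findings worth recording:

* With a *linear* perceptual function the shared offset cancels exactly
  in the decision variable, so presentation noise has no effect at all
  on triad choices — simulated frequencies at σ_err = 0 and 20 are
  exchangeable.  Sensitivity to σ_err enters only through curvature of
  `g` and the gamut truncation.
* "Presentation noise flattens responses" (mean |P − 0.5| non-increasing
  in σ_err) holds for a concave `g` pooled over the full 320-triad
  design, but *reverses* on the ≥ 50-filtered subset: near the gamut
  edge the truncated offset distribution pushes stimuli toward the
  steeper dark end of the concave curve, locally sharpening
  discrimination.  The property test asserts the claim on the full
  design.

## Validation

Cross-validation is leave-one-participant-out; each fold refits every
variant on the remaining participants and scores the fraction of
held-out responses whose observed choice matches the model's modal
prediction (exact `p = 0.5` ties score one half).  On synthetic data
from concave or linear truths all monotone variants make identical
modal predictions (concavity preserves the sign of the decision
variable), so fold accuracies tie and the expected ordering
`gf ≥ g ≥ baseline` holds with equality; differences emerge only when
fitted curves develop convex regions, as on real data.

The bootstrap resamples participants with replacement, refits, rescales,
and takes pointwise quantiles of the curves on a fixed 101-point grid
(the "middle 95% of learned models").  The coverage check uses a truth
inside the fitted knot family: for truths outside it (e.g. a smooth
power law), the four-knot approximation bias can exceed the narrow band
width at large samples, which is a statement about spline approximation,
not about the bootstrap.

Between-study agreement is summarized by the Pearson correlation of
per-triad lighter-choice proportions with `t = r√(df/(1−r²))`,
`df = n_shared − 2`.  Fold-accuracy comparisons are reported as
per-variant means/SDs and pairwise mean differences; formal ANOVA/post
hoc machinery on the original data is out of scope.

## Power planner

`required_sample_size_ttest` searches even totals `n = 4, 6, …` for the
smallest with power ≥ target, where power is the noncentral-t survival
probability at noncentrality `d√(n/4)` and df `n − 2` (equal
allocation).  One-tailed is the default because it reproduces both
published worked sizes (10 at d = 2.5; 50 at d = 0.96); the published
account names only "common values" and a planning tool, so the tail
convention is our inference and is exposed as an explicit flag.
`verify_clt_equivalence` checks the sample-size relation by simulation:
with `n_cs` from the formula, the ratio of the sampling SDs of the two
designs' mean estimates converges to 1.

## Numerical notes and limitations

* Probabilities are clipped at 1e−9 in the likelihood; fractional
  matched sample sizes are reported exactly and as ceiling integers.
* The f ordinates beyond the largest perceived difference actually
  induced by the design are weakly identified; bootstrap bands widen
  accordingly near the top of f's domain.
* Degenerate inputs (empty responses, unanimous single triad, flat g)
  raise explicit errors; non-converged fits are returned flagged, never
  silently dropped.
* Reproducing the original studies' printed statistics requires their
  public data and is deliberately outside the test surface; this package
  establishes the machinery on synthetic ground truth.
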