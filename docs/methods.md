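# Methods

## Generative frame

A causal scenario consists of independent binary exogenous variables with
marginal priors and one Boolean outcome rule; there are no intermediate
nodes (the graphs are flat, all arrows point from the variables to the
outcome).  The rule grammar supports `&`, `|`, `!`, parentheses and the
threshold form `count(v1,...,vk)>=m` with precedence `!` > `&` > `|`.
Threshold rules are first-class rather than expanded into disjunctions so
that additive games stay readable; both forms evaluate identically (tested
against each other over full truth tables).

A candidate cause is a non-empty conjunction of literals; negative literals
represent absent events ("drew a white ball"), and a cause's prior is the
product of its literal probabilities.  Empty conjunctions are rejected: the
trivially true event is never a meaningful candidate for selection.
Disjunctive candidates and multi-valued variables are out of scope.

## Counterfactual sampling

The two-stage sampling story — keep a variable at its actual value with
probability *s*, otherwise resample from the prior — is collapsed into a
single per-variable mixture propensity

    P(V = v) = s·1[v = v_actual] + (1 − s)·P0(v),

which is distributionally identical and makes the whole counterfactual
distribution a product measure.  That enables exact enumeration (the
default scoring path, guarded to n ≤ 20 variables), with Monte-Carlo
sampling retained to mirror the simulation procedure and as the stochastic
arm of property tests.  Seeds are explicit arguments everywhere; there is
no global random state.  Variables can be flagged *unanchored*, in which
case they ignore *s* and are always resampled — this is how the
loss-interpretation coin (below) is represented.

## Scores

**CESM.**  In these flat binary structures the counterfactual effect size
reduces to the probability-weighted Pearson correlation between the cause
indicator and the outcome; only the correlation form is implemented.  A
plural cause is one compound indicator (1 iff all literals hold).  If
either side is constant across worlds — at s = 1, or when a cause or the
outcome is degenerate — the correlation is undefined and the score is 0 by
convention, encoding "no counterfactual dependence".

**NSM.**  Necessity is the conditional probability that the outcome goes
away given that the cause does not hold.  Two modes govern the off-candidate
variables.  The default, `fixed_at_actual`, pins every anchored
off-candidate variable at its actual value while the cause's own variables
range over the complement of the cause, weighted by their sampling
propensities; this is the reading under which a singleton's necessity is
always 0 or 1 (flip the one variable with everything else pinned and see
whether the outcome flips).  The alternative `resampled` mode, closer to
the original necessity/sufficiency literature, marginalizes off-candidate
variables by their propensities; it is exposed as a switch for sensitivity
analysis because fitted data cannot disambiguate the two at the question-
mean level.  Sufficiency conditions the full product measure on
cause-absent *and* outcome-absent worlds, forces the cause's variables to
their required values, and reports the normalized mass whose
post-intervention outcome is present.  The combined score is the convex
combination `prior·sufficiency + (1 − prior)·necessity`: rare causes are
judged by necessity, common ones by sufficiency, and plurals — always
rarer than their conjuncts — tilt toward necessity.  Zero-mass
conditioning sets (e.g. the s = 1 boundary) return 0 with a logged
warning so that parameter grids remain total.  Full precision is kept
internally; two-decimal values only appear at display time.

## Loss semantics

Losing rounds are scored against a mixture of two representations of the
losing conditions.  The classical target is the logical negation of the
winning rule.  The non-classical target conjoins the negations of exactly
those variables that were actually absent — the strongest homogeneous
("none of them") negation that does not contradict established facts, so a
round with one colored ball actually drawn drops that variable from the
conjunction.  A per-world interpretation coin with bias *w* chooses between
the targets; worlds that are not losses are recorded as wins.  The coin is
an independent, never-anchored variable because the choice is made afresh
in each imagined world, not once per simulation run; it is treated as an
ordinary exogenous variable throughout the NSM's conditioning steps as
well, which is an interpretation choice (nothing at the question-mean level
distinguishes it from a once-per-run coin at w ∈ {0, 1}, and the mixture
semantics is only defined per world).  At w = 0 every score equals the
classical model's to machine precision; summing the coin out of the
augmented distribution recovers the base distribution exactly.  Candidate
causes in losing rounds are negative-literal conjunctions whose priors use
1 − P(V) per literal.

## Fitting

Observed per-question mean ratings on the 1–9 agreement scale are mapped
affinely onto [0, 1] via (m − 1)/8 — the unique affine map between the
scale endpoints and the models' score range that introduces no free
parameters.  Model scores pass through the response transform
`max(score, 0)^γ` (γ > 0); correlation scores can be slightly negative and
are clipped before exponentiation, with clipping logged.  The fit surface
is the Gaussian log-likelihood of the rescaled means around the transformed
predictions.  σ is profiled out in closed form (its ML value, the RMS
residual) at each grid point rather than gridded; a floor of 1e-9 keeps
the likelihood finite on interpolating fits.  The search is an exhaustive
grid — default s and w in {0, 0.01, …, 1} and γ in {0.05, 0.1, …, 3},
all overridable — with ties broken toward smaller s, then w, then γ.
Information criteria use AIC = 2k − 2ℓ and BIC = k·ln(Q) − 2ℓ with Q the
number of questions and k counting s, (w,) γ and σ.  Two baselines are
provided: a constant model predicting 0.5^γ for every question (k = 2;
its correlation with anything is undefined and reported as 0), and the
linear-combination null that predicts each pair as the arithmetic mean of
its constituent singulars' mean ratings on the raw scale.  This
question-mean likelihood is the canonical fit surface here;
participant-level mixed-effects criteria are not computed, as they require
individual-level data external to the package.

## Experiment fixtures

Two urn games ship as fixtures.  The three-urn additive game: priors
0.05/0.5/0.95, win on two or more colored balls, one all-colored round,
seven questions (three singulars, three pairs, the triple).  The four-urn
disjunctive game: priors A=0.7, B=0.1, C=0.2, D=0.9, rule `(A&B)|(C&D)`,
four rounds — overdetermined positive (1,1,1,1), triple positive
(1,1,0,1), triple negative (0,0,1,0) and overdetermined negative
(0,0,0,0).  Winning rounds query positive literals over drawn urns, losing
rounds negative literals over white urns.  Question sets default to the
exhaustive singulars + pairs + triples over the queried literals (never
the four-variable plural, which merely restates the whole round); the sets
are configuration-driven so sparser designs can be expressed.

## Synthetic participants

The generator emulates the statistical structure the fitting stage
assumes: latent response = transformed model score + participant intercept
(mean-zero normal, sd `intercept_sd`) + per-rating noise (mean-zero
normal, sd `noise_sd`), mapped to the 1–9 scale via r = 1 + 8·latent,
rounded and clipped.  Defaults are noise_sd = 0.25 and intercept_sd = 0.15
in latent units (about two and about one Likert points), realistic spreads
for single-item 1–9 agreement ratings.  Discretization is by
rounding + clipping rather than an ordered-categorical likelihood because
the fitting stage consumes means, for which rounding bias is small and
uniform.  The generator reproduces mean structure and participant-level
variance but none of the features real rating data also carry — ordinal
skew and ceiling effects, order-of-presentation effects, or participant
heterogeneity in s and w — so passing recovery tests demonstrate that the
estimation pipeline is consistent under its own assumptions, not that
those assumptions hold of human raters.

Recovery studies regenerate a dataset per replication, collapse to
question means, and refit on the default grids; model predictions are
memoized across replications (they do not depend on the data), so twenty
replications cost one grid of predictions plus twenty cheap likelihood
sweeps.  The standard recovery settings used in the acceptance tests are
300 participants and 20 replications, which run in seconds for the
three-urn game and under a minute for the four-urn losing rounds on one
core.

## Numerical choices and limitations

- Exact enumeration is the oracle for every Monte-Carlo path; probability
  vectors are validated to sum to 1 within 1e-12 in tests.
- Degenerate-input conventions (score 0 for zero-variance correlations and
  zero-mass conditioning sets) are deliberate and logged, keeping grid
  search total over the closed parameter ranges including s = 1.
- The tie-break toward smaller parameters makes grid fits deterministic
  even on likelihood plateaus (e.g. data with no w signal).
- One known edge of the NSM's behavior: in the triple-positive round of
  the four-urn game, adding the idle high-probability draw D to a cause
  can slightly *raise* the combined score at very small s (below about
  0.08), because the enlarged conjunction's higher prior shifts weight
  onto its near-ceiling sufficiency; for moderate-to-high stability the
  intuitive penalty for including idle variables holds and is asserted in
  tests over s ∈ {0.1, …, 0.9}.
- The CESM gives nearly equal scores to X and X∧Y when P(Y) is high —
  a structural property of correlation with a high-prior conjunct, worth
  keeping in mind when interpreting plural predictions.
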