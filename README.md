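# pluralcause

Counterfactual models of causal selection, extended to **plural
(conjunctive) causes**, for computational cognitive scientists studying
causal judgment.

When people explain an outcome they do not merely classify events as causes
— they *select*: "the forest burned because of the lightning," not "because
of the oxygen."  Counterfactual theories model this by imagining many
alternative worlds and measuring how strongly the outcome covaries with each
candidate cause.  This package scores not only singular events but
conjunctions of events ("John won because he drew colored balls from urns
A *and* B") treated holistically as one compound binary variable.

## The models

A scenario has independent binary variables V₁…Vₙ with priors P(Vᵢ), a
Boolean outcome rule, and an actual world.  Counterfactual worlds are
sampled per variable: with probability *s* (the **stability**) a variable
keeps its actual value, otherwise it is resampled from its prior —
equivalently `P(V=v) = s·1[v=v_actual] + (1−s)·P₀(v)`.  Two causal-strength
scores are computed over this distribution for a candidate cause **C** (a
conjunction of literals):

- **CESM** (counterfactual effect size): the Pearson correlation between
  the indicator of **C** and the outcome across counterfactual worlds.
- **NSM** (necessity–sufficiency):
  `P(C)·Sufficiency + (1−P(C))·Necessity`, where *Necessity* is the
  probability that removing **C** (holding other variables at their actual
  values) removes the outcome, *Sufficiency* the probability that forcing
  **C** in cause-absent, outcome-absent worlds produces the outcome, and
  P(C) is the prior of the conjunction.

For **losing rounds** the package implements a non-classical negation
mixture: with probability *w* a counterfactual world counts as a loss only
if *all* actually-absent events are absent (the homogeneous, language-like
negation, e.g. ¬A∧¬B∧¬C∧¬D), and with probability 1−w under the classical
negation of the winning rule.  `w = 0` recovers the classical model exactly.

Model parameters (*s*, *w*, γ — a power transform `score^γ` onto the
response scale) are fitted to per-question mean Likert ratings by
exhaustive grid search of a Gaussian likelihood with the residual σ
profiled out in closed form.  A synthetic-participant generator produces
1–9 ratings with participant-level intercepts and noise, supporting full
parameter-recovery studies without any behavioral data.

## Worked example

The bundled three-urn game (`experiment1`): urns with colored-ball
probabilities 0.05 / 0.5 / 0.95, a win needs two or more colored balls, and
the observed player drew all three.

```
pluralcause predict --experiment exp1 --model cesm --s 0.89 --gamma 0.26 \
    --out exp1.csv
```

produces (score = exact CESM correlation, scaled = `score^0.26`):

```
      round                 cause    score   scaled
all_colored                   low 0.226939 0.680043
all_colored          intermediate 0.307365 0.735852
all_colored                  high 0.135577 0.594797
all_colored      intermediate&low 0.190664 0.649935
all_colored              high&low 0.231851 0.683840
all_colored     high&intermediate 0.321115 0.744272
all_colored high&intermediate&low 0.187325 0.646956
```

Two signatures of holistic plural scoring are visible: among singulars the
intermediate urn dominates (its draw covaries most with winning), yet among
pairs it is **intermediate & high** — not the pair containing the
individually stronger `low` — that scores highest, because most
counterfactual wins run through those two urns.  A linear combination of
singular scores cannot produce this reversal.

The same machinery runs end to end on the four-urn disjunctive game
(`experiment2`, rule `(A&B)|(C&D)`), including its two losing rounds:

```
pluralcause simulate --experiment exp2 --model cesm --s 0.21 --w 0.77 \
    --gamma 0.41 --n 300 --seed 7 --out ratings.csv
pluralcause fit --experiment exp2 --model cesm --with-w \
    --ratings ratings.csv --out fit.json
```

The library API mirrors the CLI: `cesm_score`, `nsm_score`,
`strong_loss_rule`, `augment_with_interpretation`, `prediction_table`,
`grid_fit`, `generate_ratings`, `recovery_study`.

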