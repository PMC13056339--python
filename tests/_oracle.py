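"""Independent brute-force reference implementations.

Everything here is deliberately written from first principles — itertools
enumeration over assignments, rules as plain Python callables, math-module
arithmetic — and shares no code with the package's scoring paths.  Scenarios
are described by plain dicts of priors; anchoring is a name set.
"""

import itertools
import math


def propensity(prior, actual_value, value, s):
    base = prior if value == 1 else 1.0 - prior
    return s * (1.0 if value == actual_value else 0.0) + (1.0 - s) * base


def enumerate_worlds(names):
    for values in itertools.product((0, 1), repeat=len(names)):
        yield dict(zip(names, values))


def world_probability(world, priors, actual, s, unanchored=()):
    prob = 1.0
    for name, value in world.items():
        if name in unanchored:
            prob *= priors[name] if value == 1 else 1.0 - priors[name]
        else:
            prob *= propensity(priors[name], actual[name], value, s)
    return prob


def cause_holds(cause, world):
    return all(world[name] == value for name, value in cause.items())


def cause_prior(cause, priors):
    prob = 1.0
    for name, value in cause.items():
        prob *= priors[name] if value == 1 else 1.0 - priors[name]
    return prob


def cesm(names, priors, actual, s, cause, rule, unanchored=()):
    """Probability-weighted Pearson correlation of cause indicator vs outcome."""
    ex = ey = exy = exx = eyy = 0.0
    for world in enumerate_worlds(names):
        p = world_probability(world, priors, actual, s, unanchored)
        x = 1.0 if cause_holds(cause, world) else 0.0
        y = float(rule(world))
        ex += p * x
        ey += p * y
        exy += p * x * y
        exx += p * x * x
        eyy += p * y * y
    vx = exx - ex * ex
    vy = eyy - ey * ey
    if vx <= 1e-15 or vy <= 1e-15:
        return 0.0
    return (exy - ex * ey) / math.sqrt(vx * vy)


def necessity(names, priors, actual, s, cause, rule, mode="fixed_at_actual",
              unanchored=()):
    """P(outcome flips | cause absent) under the mode's measure."""
    actual_outcome = rule(actual)
    total = flipped = 0.0
    for world in enumerate_worlds(names):
        if cause_holds(cause, world):
            continue
        p = 1.0
        skip = False
        for name, value in world.items():
            if name in cause:
                p *= propensity(priors[name], actual[name], value, s)
            elif name in unanchored:
                p *= priors[name] if value == 1 else 1.0 - priors[name]
            elif mode == "fixed_at_actual":
                if value != actual[name]:
                    skip = True
                    break
            else:  # resampled
                p *= propensity(priors[name], actual[name], value, s)
        if skip:
            continue
        total += p
        if rule(world) != actual_outcome:
            flipped += p
    if total <= 0.0:
        return 0.0
    return flipped / total


def sufficiency(names, priors, actual, s, cause, rule, unanchored=()):
    """P(forcing the cause produces the outcome | cause absent, outcome absent)."""
    total = produced = 0.0
    for world in enumerate_worlds(names):
        if cause_holds(cause, world) or rule(world) == 1:
            continue
        p = world_probability(world, priors, actual, s, unanchored)
        total += p
        forced = dict(world)
        forced.update(cause)
        if rule(forced) == 1:
            produced += p
    if total <= 0.0:
        return 0.0
    return produced / total


def nsm(names, priors, actual, s, cause, rule, mode="fixed_at_actual",
        unanchored=()):
    prior = cause_prior(cause, priors)
    nec = necessity(names, priors, actual, s, cause, rule, mode, unanchored)
    suf = sufficiency(names, priors, actual, s, cause, rule, unanchored)
    return prior * suf + (1.0 - prior) * nec
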