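"""The nine popular confirmation measures D, M, R, C, Z, S, N, L, F.

Each measure scores a rule ``e -> h`` against a 2x2 sample.  The canonical
definitions (for e1 -> h1, with posterior P(h1|e1), prior P(h1), and the
likelihoods P(e1|h)) are:

    D = P(h1|e1) - P(h1)                       (difference of posteriors)
    M = P(e1|h1) - P(e1)
    R = log2[ P(h1|e1) / P(h1) ]
    C = P(e1,h1) - P(e1) P(h1)                 (covariance form)
    Z = [P(h1|e1) - P(h1)] / P(h0)  if P(h1|e1) >= P(h1), else / P(h1)
    S = P(h1|e1) - P(h1|e0)
    N = P(e1|h1) - P(e1|h0)
    L = log2[ P(e1|h1) / P(e1|h0) ]  = log2 LR+
    F = [P(e1|h1) - P(e1|h0)] / [P(e1|h1) + P(e1|h0)]  = (LR+ - 1)/(LR+ + 1)

For a test-negative rule (e0 -> h0) the same formula shapes apply with
e0/h0 substituted throughout; more generally any rule with an e-side
antecedent is handled by substituting its antecedent/consequent into the
canonical shape.  Logs are base 2.  ``R`` and ``L`` return signed-infinity
values on zero arguments (never clamped), so monotonicity checks remain
meaningful; a conditional with an empty conditioning event makes the
report undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional

from .contingency import ContingencyTable
from .outcomes import Rule, negate, variable

CLASSIC_MEASURES = ("D", "M", "R", "C", "Z", "S", "N", "L", "F")


@dataclass(frozen=True)
class MeasureReport:
    """A named measure value for one rule on one table."""

    measure: str
    rule: Rule
    value: float
    defined: bool = True

    def __float__(self) -> float:
        return float(self.value)


def _undefined(measure: str, rule: Rule) -> MeasureReport:
    return MeasureReport(measure, rule, math.nan, defined=False)


def _require_e_antecedent(rule: Rule) -> None:
    if variable(rule.antecedent) != "e":
        raise ValueError(
            f"classic measures are defined for e->h rules; got {rule} "
            "(use certainty_factor or the directional F/b*/c* forms for h->e)"
        )


def _log2_ratio(num: float, den: float) -> Optional[float]:
    """log2(num/den) with signed infinities; None when 0/0."""
    if num == 0 and den == 0:
        return None
    if den == 0:
        return math.inf
    if num == 0:
        return -math.inf
    return math.log2(num / den)


def _diff_over_sum(pos: float, neg: float) -> Optional[float]:
    if pos + neg == 0:
        return None
    return (pos - neg) / (pos + neg)


def classic_measure(name: str, table: ContingencyTable, rule: Rule) -> MeasureReport:
    """Evaluate one of D, M, R, C, Z, S, N, L, F on an ``e -> h`` rule."""
    if name not in _DISPATCH:
        raise KeyError(f"unknown measure {name!r}; choose from {CLASSIC_MEASURES}")
    _require_e_antecedent(rule)
    value = _DISPATCH[name](table, rule)
    if value is None:
        return _undefined(name, rule)
    return MeasureReport(name, rule, value)


# Each formula below reads the rule as ant (e-side) -> cons (h-side) and
# substitutes those outcomes into the canonical e1->h1 shape.


def _D(t: ContingencyTable, r: Rule) -> Optional[float]:
    post = t.cond(r.consequent, r.antecedent)
    if post is None:
        return None
    return post - t.prob(r.consequent)


def _M(t: ContingencyTable, r: Rule) -> Optional[float]:
    lik = t.cond(r.antecedent, r.consequent)
    if lik is None:
        return None
    return lik - t.prob(r.antecedent)


def _R(t: ContingencyTable, r: Rule) -> Optional[float]:
    post = t.cond(r.consequent, r.antecedent)
    if post is None:
        return None
    return _log2_ratio(post, t.prob(r.consequent))


def _C(t: ContingencyTable, r: Rule) -> Optional[float]:
    return t.joint(r.antecedent, r.consequent) - t.prob(r.antecedent) * t.prob(r.consequent)


def _Z(t: ContingencyTable, r: Rule) -> Optional[float]:
    post = t.cond(r.consequent, r.antecedent)
    if post is None:
        return None
    prior = t.prob(r.consequent)
    if post >= prior:  # ties take the confirmation branch
        denom = 1 - prior
    else:
        denom = prior
    if denom == 0:
        return None
    return (post - prior) / denom


def _S(t: ContingencyTable, r: Rule) -> Optional[float]:
    p1 = t.cond(r.consequent, r.antecedent)
    p0 = t.cond(r.consequent, negate(r.antecedent))
    if p1 is None or p0 is None:
        return None
    return p1 - p0


def _N(t: ContingencyTable, r: Rule) -> Optional[float]:
    p1 = t.cond(r.antecedent, r.consequent)
    p0 = t.cond(r.antecedent, negate(r.consequent))
    if p1 is None or p0 is None:
        return None
    return p1 - p0


def _L(t: ContingencyTable, r: Rule) -> Optional[float]:
    p1 = t.cond(r.antecedent, r.consequent)
    p0 = t.cond(r.antecedent, negate(r.consequent))
    if p1 is None or p0 is None:
        return None
    return _log2_ratio(p1, p0)


def _F(t: ContingencyTable, r: Rule) -> Optional[float]:
    p1 = t.cond(r.antecedent, r.consequent)
    p0 = t.cond(r.antecedent, negate(r.consequent))
    if p1 is None or p0 is None:
        return None
    return _diff_over_sum(p1, p0)


_DISPATCH: Dict[str, Callable[[ContingencyTable, Rule], Optional[float]]] = {
    "D": _D, "M": _M, "R": _R, "C": _C, "Z": _Z, "S": _S, "N": _N, "L": _L, "F": _F,
}


def F_directional(table: ContingencyTable, rule: Rule) -> MeasureReport:
    """Measure F for any of the eight directed rules.

    F(ant->cons) = [P(ant|cons) - P(ant|~cons)] / [P(ant|cons) + P(ant|~cons)].
    For the four same-index rules this equals the count identities
    (ad-bc)/(ad+bc+2ac), /(+2ab), /(+2bd), /(+2cd); negated-consequent
    rules follow by Consequent Symmetry (built into the formula).
    """
    p1 = table.cond(rule.antecedent, rule.consequent)
    p0 = table.cond(rule.antecedent, negate(rule.consequent))
    if p1 is None or p0 is None:
        return _undefined("F", rule)
    value = _diff_over_sum(p1, p0)
    if value is None:
        return _undefined("F", rule)
    return MeasureReport("F", rule, value)


def certainty_factor(table: ContingencyTable, rule: Rule) -> MeasureReport:
    """Certainty factor CF of an uncertain inference ``h -> e``.

    The expert-system certainty factor satisfies CF(h->e) = Z(e->h); the
    rule must therefore have an h-side antecedent, and its mirrored e->h
    rule is scored with Z.
    """
    if variable(rule.antecedent) != "h":
        raise ValueError(f"certainty factor applies to h->e rules, got {rule}")
    z = classic_measure("Z", table, rule.converse)
    return MeasureReport("CF", rule, z.value, z.defined)
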