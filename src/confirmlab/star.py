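"""Channel (b*) and prediction (c*) confirmation measures.

Both measures share the shape (positive - counter) / max(positive, counter),
differing in which proportions they compare:

* **b\\*** (channel confirmation) compares the two likelihoods of the
  antecedent given each value of the consequent variable:
  b*(ant->cons) = [P(ant|cons) - P(ant|~cons)] / max(...).
  For e1->h1 this is (LR+ - 1)/max(LR+, 1): a monotone transform of the
  likelihood ratio, scoring the *testing means* (the channel).
* **c\\*** (prediction confirmation) compares the two joint counts sharing
  the rule's antecedent: c*(ant->cons) = (n_pos - n_counter)/max(...),
  e.g. (a - c)/max(a, c) for e1->h1.  It is a transform of the correct
  rate, scoring the *probability prediction*, and depends only on the
  positive-example and counterexample counts — which is what makes it
  satisfy the Nicod-Fisher criterion.

``bF*`` and ``cF*`` replace max() with + in the denominator; bF* is
identical to measure F.  The disconfirmation quantities b'* and c'* are the
min/max ratios of the same pairs, with b* = 1 - b'* when b* >= 0 and
b* = b'* - 1 otherwise.

Consequent Symmetry (c(ant->~cons) = -c(ant->cons)) is built into every
formula, so all 16 (measure-family x directed-rule) combinations resolve
through a single conditional/count pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .contingency import ContingencyTable
from .outcomes import Rule, negate


@dataclass(frozen=True)
class StarValue:
    """A b*/c*-family value for one rule on one table."""

    measure: str
    rule: Optional[Rule]
    value: float
    defined: bool = True

    def __float__(self) -> float:
        return float(self.value)


def _undefined(measure: str, rule: Optional[Rule]) -> StarValue:
    return StarValue(measure, rule, math.nan, defined=False)


def _channel_pair(table: ContingencyTable, rule: Rule) -> Tuple[Optional[float], Optional[float]]:
    """(positive, counter) likelihoods for the channel direction.

    The antecedent is conditioned on the consequent variable: positive
    examples have the consequent true, counterexamples have it false.
    The same resolution covers the converse (h -> e) forms.
    """
    pos = table.cond(rule.antecedent, rule.consequent)
    neg = table.cond(rule.antecedent, negate(rule.consequent))
    return pos, neg


def _prediction_pair(table: ContingencyTable, rule: Rule) -> Tuple[float, float]:
    """(positive, counter) counts sharing the rule's antecedent."""
    pos = table.count(rule.antecedent, rule.consequent)
    neg = table.count(rule.antecedent, negate(rule.consequent))
    return pos, neg


def _diff_over_max(pos: float, neg: float) -> Optional[float]:
    m = max(pos, neg)
    if m == 0:
        return None  # 0/0 stays visibly undefined
    return (pos - neg) / m


def _diff_over_sum(pos: float, neg: float) -> Optional[float]:
    s = pos + neg
    if s == 0:
        return None
    return (pos - neg) / s


def b_star(table: ContingencyTable, rule: Rule) -> StarValue:
    """Channel confirmation b* for any directed rule."""
    pos, neg = _channel_pair(table, rule)
    if pos is None or neg is None:
        return _undefined("b*", rule)
    value = _diff_over_max(pos, neg)
    if value is None:
        return _undefined("b*", rule)
    return StarValue("b*", rule, value)


def c_star(table: ContingencyTable, rule: Rule) -> StarValue:
    """Prediction confirmation c* for any directed rule."""
    pos, neg = _prediction_pair(table, rule)
    value = _diff_over_max(pos, neg)
    if value is None:
        return _undefined("c*", rule)
    return StarValue("c*", rule, value)


def bF_star(table: ContingencyTable, rule: Rule) -> StarValue:
    """b* with a sum denominator; identical to measure F on every rule."""
    pos, neg = _channel_pair(table, rule)
    if pos is None or neg is None:
        return _undefined("bF*", rule)
    value = _diff_over_sum(pos, neg)
    if value is None:
        return _undefined("bF*", rule)
    return StarValue("bF*", rule, value)


def cF_star(table: ContingencyTable, rule: Rule) -> StarValue:
    """c* with a sum denominator, e.g. (a - c)/(a + c) for e1->h1."""
    pos, neg = _prediction_pair(table, rule)
    value = _diff_over_sum(pos, neg)
    if value is None:
        return _undefined("cF*", rule)
    return StarValue("cF*", rule, value)


def b_star_from_LR(lr: float) -> StarValue:
    """b* = (LR - 1)/max(LR, 1) from a likelihood ratio (inf maps to 1)."""
    if lr is None or math.isnan(lr) or lr < 0:
        return _undefined("b*", None)
    if math.isinf(lr):
        return StarValue("b*", None, 1.0)
    return StarValue("b*", None, (lr - 1) / max(lr, 1.0))


def b_prime_from_LR(lr: float) -> StarValue:
    """Disconfirmation b'* = min(LR, 1/LR) in [0, 1]."""
    if lr is None or math.isnan(lr) or lr < 0:
        return _undefined("b'*", None)
    if lr == 0 or math.isinf(lr):
        return StarValue("b'*", None, 0.0)
    return StarValue("b'*", None, min(lr, 1.0 / lr))


def disconfirmation(table: ContingencyTable, rule: Rule, kind: str = "b") -> StarValue:
    """b'* or c'* — the min/max ratio of the rule's (positive, counter) pair.

    ``kind="b"`` uses the channel likelihoods (b'* = 1/LR+ for e1->h1 with
    an informative test); ``kind="c"`` uses the prediction counts
    (c'* = P(~cons|ant)/P(cons|ant) capped at its reciprocal).
    """
    if kind == "b":
        pair = _channel_pair(table, rule)
        name = "b'*"
    elif kind == "c":
        pair = _prediction_pair(table, rule)
        name = "c'*"
    else:
        raise ValueError("kind must be 'b' or 'c'")
    pos, neg = pair
    if pos is None or neg is None or max(pos, neg) == 0:
        return _undefined(name, rule)
    return StarValue(name, rule, min(pos, neg) / max(pos, neg))


def star_measure(name: str, table: ContingencyTable, rule: Rule) -> StarValue:
    """Dispatch by name: one of b*, c*, bF*, cF*."""
    try:
        fn = {"b*": b_star, "c*": c_star, "bF*": bF_star, "cF*": cF_star}[name]
    except KeyError:
        raise KeyError(f"unknown star measure {name!r}") from None
    return fn(table, rule)


STAR_MEASURES = ("b*", "c*", "bF*", "cF*")
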