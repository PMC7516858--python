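"""Medical-test evaluation and the two-test decision engine.

A diagnostic test with known sensitivity and specificity supports two
rules: test-positive -> infected (e1 -> h1) and test-negative ->
uninfected (e0 -> h0).  Any confirmation measure assigns each rule a
degree of confirmation; when two tests disagree (say a low-sensitivity,
high-specificity assay reads negative while a high-sensitivity imaging
test reads positive), the result backed by the larger degree of
confirmation wins.  With measure b* this reproduces the clinical
practice of overriding a negative assay with a positive imaging result
when the imaging test's positive is better confirmed than the assay's
negative.

Also provides a seeded multinomial sampling simulator for convergence
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .contingency import ContingencyTable, TestProfile, from_test_profile
from .outcomes import E0, E1, H0, H1, Rule
from .properties import measure_value

RULE_POSITIVE = Rule(E1, H1)
RULE_NEGATIVE = Rule(E0, H0)

DEFAULT_MEASURES = ("D", "M", "Z", "S", "C", "N", "F", "b*", "c*")


@dataclass(frozen=True)
class TestEvaluation:
    """Degrees of confirmation of a test's positive and negative rules."""

    measure: str
    positive: float  # c(test+), rule e1 -> h1
    negative: float  # c(test-), rule e0 -> h0


def evaluate_test(
    profile: TestProfile,
    measures: Sequence[str] = DEFAULT_MEASURES,
) -> Dict[str, TestEvaluation]:
    """Score c(test+) and c(test-) for each measure on the implied table."""
    table = from_test_profile(profile)
    out: Dict[str, TestEvaluation] = {}
    for m in measures:
        pos, _ = measure_value(m, table, RULE_POSITIVE)
        neg, _ = measure_value(m, table, RULE_NEGATIVE)
        out[m] = TestEvaluation(m, positive=pos, negative=neg)
    return out


@dataclass(frozen=True)
class DiagnosisCell:
    """Final call for one combination of two test results."""

    result_a: str  # "+" or "-"
    result_b: str
    final: str  # "positive", "negative", or "undecided"
    support_for_positive: Optional[float] = None
    support_for_negative: Optional[float] = None
    changed: bool = False  # discordant cell resolved against test A's result


def two_test_decision(
    profile_a: TestProfile,
    profile_b: TestProfile,
    measure: str = "b*",
    belief_threshold: Optional[float] = None,
) -> Dict[tuple, DiagnosisCell]:
    """2x2 decision grid over the result combinations of two tests.

    Concordant cells keep the shared result.  A discordant cell compares
    the degree of confirmation of the positive-supporting rule of one
    test against the negative-supporting rule of the other; the strictly
    larger degree wins, a tie is reported as ``"undecided"``.  With
    ``belief_threshold`` set, a result only counts as believed when its
    degree exceeds the threshold; if exactly one side is believed it
    wins, and if neither is, the cell is undecided.
    """
    eval_a = evaluate_test(profile_a, [measure])[measure]
    eval_b = evaluate_test(profile_b, [measure])[measure]
    grid: Dict[tuple, DiagnosisCell] = {}
    for ra in ("+", "-"):
        for rb in ("+", "-"):
            if ra == rb:
                final = "positive" if ra == "+" else "negative"
                sup_a = eval_a.positive if ra == "+" else eval_a.negative
                sup_b = eval_b.positive if rb == "+" else eval_b.negative
                support = max(sup_a, sup_b)
                if belief_threshold is not None and support <= belief_threshold:
                    final = "undecided"  # concordant but neither result is believed
                grid[(ra, rb)] = DiagnosisCell(
                    ra, rb, final,
                    support_for_positive=support if ra == "+" else None,
                    support_for_negative=support if ra == "-" else None,
                )
                continue
            sup_pos = eval_a.positive if ra == "+" else eval_b.positive
            sup_neg = eval_a.negative if ra == "-" else eval_b.negative
            if belief_threshold is not None:
                pos_ok = sup_pos > belief_threshold
                neg_ok = sup_neg > belief_threshold
                if pos_ok != neg_ok:
                    final = "positive" if pos_ok else "negative"
                elif not pos_ok:
                    final = "undecided"
                else:
                    final = _compare(sup_pos, sup_neg)
            else:
                final = _compare(sup_pos, sup_neg)
            # "changed" relative to trusting test A alone
            changed = final != ("positive" if ra == "+" else "negative") and final != "undecided"
            grid[(ra, rb)] = DiagnosisCell(ra, rb, final, sup_pos, sup_neg, changed)
    return grid


def _compare(sup_pos: float, sup_neg: float) -> str:
    if math.isnan(sup_pos) or math.isnan(sup_neg) or sup_pos == sup_neg:
        return "undecided"
    return "positive" if sup_pos > sup_neg else "negative"


def joint_from_profile(profile: TestProfile) -> Dict[tuple, float]:
    """Joint P(e, h) implied by a test profile (keys are outcome pairs)."""
    t = from_test_profile(profile)
    return {
        (E1, H1): t.a, (E0, H1): t.b, (E1, H0): t.c, (E0, H0): t.d,
    }


def simulate_sample(
    joint: Mapping[tuple, float],
    n: int,
    seed: Optional[int] = None,
    exact: bool = False,
) -> ContingencyTable:
    """Draw n examples multinomially from a joint P(e, h) (seeded).

    ``exact=True`` skips sampling and returns the expected counts n * p.
    """
    keys = [(E1, H1), (E0, H1), (E1, H0), (E0, H0)]
    probs = np.array([float(joint[k]) for k in keys])
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("joint must be non-negative with positive total")
    probs = probs / probs.sum()
    if n < 1:
        raise ValueError("n must be >= 1")
    if exact:
        counts = n * probs
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, probs)
    return ContingencyTable(*(float(v) for v in counts))
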