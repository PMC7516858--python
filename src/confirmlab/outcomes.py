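"""Outcome labels and directed rules over the 2x2 evidence space.

The evidence variable ``e`` (e.g. a test result: ``e1`` positive, ``e0``
negative) and the hypothesis variable ``h`` (``h1`` the hypothesis, ``h0``
its negation) take two values each.  A :class:`Rule` is a directed
implication between one value of each variable, such as ``e1 -> h1``
("if the test is positive, the patient is infected").  All confirmation
measures in this package score rules against a 2x2 sample.
"""

from __future__ import annotations

from dataclasses import dataclass

E1 = "e1"
E0 = "e0"
H1 = "h1"
H0 = "h0"

OUTCOMES = (E1, E0, H1, H0)

_NEGATION = {E1: E0, E0: E1, H1: H0, H0: H1}


def negate(outcome: str) -> str:
    """Return the opposite value of the same variable (e1 <-> e0, h1 <-> h0)."""
    return _NEGATION[outcome]


def variable(outcome: str) -> str:
    """Return which variable an outcome belongs to: ``"e"`` or ``"h"``."""
    if outcome not in _NEGATION:
        raise ValueError(f"unknown outcome {outcome!r}")
    return outcome[0]


@dataclass(frozen=True)
class Rule:
    """A directed implication ``antecedent -> consequent``.

    The antecedent and the consequent must belong to different variables:
    one is an e-value, the other an h-value.  Rules with an e-side
    antecedent (``e -> h``) are scored in the prediction direction;
    rules with an h-side antecedent (``h -> e``) are the converse forms.
    """

    antecedent: str
    consequent: str

    def __post_init__(self) -> None:
        for o in (self.antecedent, self.consequent):
            if o not in _NEGATION:
                raise ValueError(f"unknown outcome {o!r}")
        if variable(self.antecedent) == variable(self.consequent):
            raise ValueError(
                "antecedent and consequent must belong to different variables, "
                f"got {self.antecedent} -> {self.consequent}"
            )

    @classmethod
    def parse(cls, text: str) -> "Rule":
        """Parse ``"e1->h1"`` (also accepts ``"e1→h1"``)."""
        s = text.replace("→", "->").replace(" ", "")
        ant, _, cons = s.partition("->")
        if not cons:
            raise ValueError(f"cannot parse rule {text!r}")
        return cls(ant, cons)

    @property
    def converse(self) -> "Rule":
        """The rule with antecedent and consequent swapped."""
        return Rule(self.consequent, self.antecedent)

    @property
    def negated_consequent(self) -> "Rule":
        """The rule predicting the opposite consequent (for Consequent Symmetry)."""
        return Rule(self.antecedent, negate(self.consequent))

    @property
    def negated_antecedent(self) -> "Rule":
        return Rule(negate(self.antecedent), self.consequent)

    @property
    def contrapositive(self) -> "Rule":
        """``e1->h1`` maps to ``h0->e0`` (the Equivalence Condition partner)."""
        return Rule(negate(self.consequent), negate(self.antecedent))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.antecedent}->{self.consequent}"


# The four rules whose antecedent and consequent indices agree; every other
# directed rule is one Consequent Symmetry step away from one of these.
RULE_E1_H1 = Rule(E1, H1)
RULE_E0_H0 = Rule(E0, H0)
RULE_H1_E1 = Rule(H1, E1)
RULE_H0_E0 = Rule(H0, E0)
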