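"""2x2 contingency tables, diagnostic-test profiles, and derived rates.

The evidential object every confirmation measure consumes is a 2x2 table of
example counts::

            e1 (positive)   e0 (negative)
    h1          a               b
    h0          c               d

``a`` counts positive examples of the rule e1->h1, ``c`` its counterexamples;
``b`` and ``d`` are the e0 column.  Counts are stored as non-negative reals so
that expected tables derived from a test profile (sensitivity, specificity,
prevalence) are exact; an integer-rounding view is available for export.

Undefined conditionals (zero denominators) are returned as ``None`` rather
than raised, so measure functions can apply their own limit conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .outcomes import E0, E1, H0, H1, variable


class InvalidProfileError(ValueError):
    """A test profile with a degenerate prior or out-of-range rates."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style half-up rounding (0.5 -> 1), unlike banker's ``round``."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of the four example types (a, b, c, d); see module docstring."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"count {name} must be finite and >= 0, got {v}")
        if self.n <= 0:
            raise ValueError("total count must be positive")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    # -- counts ---------------------------------------------------------

    def count(self, first: str, second: str) -> float:
        """Joint count of two outcomes, one per variable, in either order."""
        if variable(first) == variable(second):
            raise ValueError("need one e-outcome and one h-outcome")
        pair = {first, second}
        if pair == {E1, H1}:
            return self.a
        if pair == {E0, H1}:
            return self.b
        if pair == {E1, H0}:
            return self.c
        return self.d

    def marginal_count(self, outcome: str) -> float:
        if outcome == H1:
            return self.a + self.b
        if outcome == H0:
            return self.c + self.d
        if outcome == E1:
            return self.a + self.c
        return self.b + self.d

    # -- probabilities --------------------------------------------------

    def joint(self, first: str, second: str) -> float:
        return self.count(first, second) / self.n

    def prob(self, outcome: str) -> float:
        return self.marginal_count(outcome) / self.n

    def cond(self, target: str, given: str) -> Optional[float]:
        """P(target | given), or ``None`` when the conditioning count is 0."""
        denom = self.marginal_count(given)
        if denom == 0:
            return None
        return self.count(target, given) / denom

    # -- derived tables -------------------------------------------------

    def scaled(self, factor: float) -> "ContingencyTable":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ContingencyTable(self.a * factor, self.b * factor, self.c * factor, self.d * factor)

    def perturbed(self, da: float = 0, db: float = 0, dc: float = 0, dd: float = 0) -> "ContingencyTable":
        return ContingencyTable(self.a + da, self.b + db, self.c + dc, self.d + dd)

    def rounded(self) -> "ContingencyTable":
        """Integer counts via half-up rounding, for fixture export."""
        return ContingencyTable(*(round_half_up(v) for v in (self.a, self.b, self.c, self.d)))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class TestProfile:
    """A diagnostic test: sensitivity P(e1|h1), specificity P(e0|h0), prior P(h1)."""

    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest class

    sensitivity: float
    specificity: float
    prior: float

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise InvalidProfileError(f"sensitivity must be in [0,1], got {self.sensitivity}")
        if not 0 <= self.specificity <= 1:
            raise InvalidProfileError(f"specificity must be in [0,1], got {self.specificity}")
        if not 0 < self.prior < 1:
            raise InvalidProfileError(f"prior must be in (0,1), got {self.prior}")


def from_test_profile(profile: TestProfile, n: float = 1.0, integer: bool = False) -> ContingencyTable:
    """Expected 2x2 counts for ``n`` subjects under a test profile.

    Counts are exact reals (a = n * prior * sensitivity, etc.); pass
    ``integer=True`` for half-up rounded integer counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p, se, sp = profile.prior, profile.sensitivity, profile.specificity
    table = ContingencyTable(
        a=n * p * se,
        b=n * p * (1 - se),
        c=n * (1 - p) * (1 - sp),
        d=n * (1 - p) * sp,
    )
    return table.rounded() if integer else table


@dataclass(frozen=True)
class RateSet:
    """The eight conditionals of a 2x2 table plus their clinical-rate names.

    Any conditional whose denominator is zero is ``None``.  Complementary
    pairs sum to 1 when defined (PPV + FDR, TPR + FNR, ...).
    """

    p_e1_given_h1: Optional[float]
    p_e0_given_h1: Optional[float]
    p_e1_given_h0: Optional[float]
    p_e0_given_h0: Optional[float]
    p_h1_given_e1: Optional[float]
    p_h0_given_e1: Optional[float]
    p_h1_given_e0: Optional[float]
    p_h0_given_e0: Optional[float]

    # clinical aliases
    @property
    def sensitivity(self) -> Optional[float]:
        return self.p_e1_given_h1

    tpr = sensitivity

    @property
    def specificity(self) -> Optional[float]:
        return self.p_e0_given_h0

    tnr = specificity

    @property
    def fnr(self) -> Optional[float]:
        return self.p_e0_given_h1

    @property
    def fpr(self) -> Optional[float]:
        return self.p_e1_given_h0

    @property
    def ppv(self) -> Optional[float]:
        return self.p_h1_given_e1

    @property
    def fdr(self) -> Optional[float]:
        return self.p_h0_given_e1

    @property
    def npv(self) -> Optional[float]:
        return self.p_h0_given_e0

    @property
    def false_omission_rate(self) -> Optional[float]:
        return self.p_h1_given_e0


def rates(table: ContingencyTable) -> RateSet:
    """All eight conditionals of the table as a :class:`RateSet`."""
    return RateSet(
        p_e1_given_h1=table.cond(E1, H1),
        p_e0_given_h1=table.cond(E0, H1),
        p_e1_given_h0=table.cond(E1, H0),
        p_e0_given_h0=table.cond(E0, H0),
        p_h1_given_e1=table.cond(H1, E1),
        p_h0_given_e1=table.cond(H0, E1),
        p_h1_given_e0=table.cond(H1, E0),
        p_h0_given_e0=table.cond(H0, E0),
    )


def _ratio(num: Optional[float], den: Optional[float]) -> float:
    """num/den with infinity for x/0 and NaN when undefined (0/0 or None input)."""
    if num is None or den is None:
        return math.nan
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def likelihood_ratios(table: ContingencyTable) -> tuple[float, float]:
    """(LR+, LR-) of the table.

    LR+ = P(e1|h1)/P(e1|h0).  LR- here is P(e0|h0)/P(e0|h1) — the
    *reciprocal* of the clinical negative likelihood ratio — so that both
    ratios exceed 1 for an informative test and b* maps them symmetrically.
    Zero denominators yield ``inf``; 0/0 yields ``nan`` (undefined).
    """
    lr_plus = _ratio(table.cond(E1, H1), table.cond(E1, H0))
    lr_minus = _ratio(table.cond(E0, H0), table.cond(E0, H1))
    return lr_plus, lr_minus
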