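"""Machine-checkable desiderata for confirmation measures.

Checks the classical screening properties on collections of tables:

* symmetries — Hypothesis/Consequent Symmetry (HS), Evidence/Antecedent
  Symmetry (ES), Commutativity Symmetry (CS), Total Symmetry (TS); only
  HS is considered desirable,
* monotonicity — f(a,b,c,d) non-decreasing in a and d, non-increasing in
  b and c,
* normalization (values within [-1, 1]) and logicality (+1 with no
  counterexample, -1 with no positive example),
* the Nicod-Fisher criterion — a positive example raises the measure, a
  counterexample lowers it, and e0-examples are irrelevant,

plus the black-raven increment experiment: compare the effect of one more
positive example (da = 1) against one more irrelevant non-example
(dd = 1 — the "piece of white chalk").

Every ``False`` verdict carries a concrete witness table.  The checks are
empirical (grids and supplied table collections), not algebraic proofs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .classic import CLASSIC_MEASURES, F_directional, classic_measure
from .contingency import ContingencyTable
from .outcomes import E0, E1, H0, H1, Rule
from .star import STAR_MEASURES, star_measure

RULE = Rule(E1, H1)

#: measures that have well-defined values for h-side antecedents (needed by CS)
_CONVERSE_CAPABLE = {"F", "b*", "c*", "bF*", "cF*"}


def measure_value(name: str, table: ContingencyTable, rule: Rule = RULE) -> Tuple[float, bool]:
    """Uniform accessor over classic and star measures: (value, defined)."""
    if name in STAR_MEASURES:
        r = star_measure(name, table, rule)
        return r.value, r.defined
    if name == "F" and rule.antecedent in (H1, H0):
        r = F_directional(table, rule)
        return r.value, r.defined
    if name in CLASSIC_MEASURES:
        r = classic_measure(name, table, rule)
        return r.value, r.defined
    raise KeyError(f"unknown measure {name!r}")


ALL_MEASURES = CLASSIC_MEASURES + STAR_MEASURES


@dataclass
class CheckResult:
    """Outcome of a property check: a verdict plus a witness on failure."""

    measure: str
    property: str
    holds: bool
    witness: Optional[ContingencyTable] = None
    detail: str = ""
    skipped: int = 0  # tables where the measure was undefined


_SYMMETRY_PAIRS: Dict[str, Tuple[Rule, Rule, int]] = {
    # name -> (left rule, right rule, sign of the right side)
    "HS": (RULE, Rule(E1, H0), -1),
    "ES": (RULE, Rule(E0, H1), -1),
    "CS": (RULE, Rule(H1, E1), +1),
    "TS": (RULE, Rule(E0, H0), +1),
}


def check_symmetry(
    measure: str,
    kind: str,
    tables: Iterable[ContingencyTable],
    tol: float = 1e-9,
) -> CheckResult:
    """Does the symmetry identity hold (to ``tol``) on every table?

    Tables where either side is undefined are skipped and counted.
    """
    if kind not in _SYMMETRY_PAIRS:
        raise KeyError(f"unknown symmetry {kind!r}; choose from {sorted(_SYMMETRY_PAIRS)}")
    left_rule, right_rule, sign = _SYMMETRY_PAIRS[kind]
    if kind == "CS" and measure not in _CONVERSE_CAPABLE:
        raise ValueError(f"measure {measure} has no converse (h->e) form to compare for CS")
    skipped = 0
    for table in tables:
        lhs, ld = measure_value(measure, table, left_rule)
        rhs, rd = measure_value(measure, table, right_rule)
        if not (ld and rd):
            skipped += 1
            continue
        if math.isinf(lhs) or math.isinf(rhs):
            equal = lhs == sign * rhs
        else:
            equal = abs(lhs - sign * rhs) <= tol
        if not equal:
            return CheckResult(
                measure, kind, False, witness=table,
                detail=f"{lhs!r} != {sign:+d} * {rhs!r}", skipped=skipped,
            )
    return CheckResult(measure, kind, True, skipped=skipped)


def _grid_tables(lo: int, hi: int) -> Iterable[ContingencyTable]:
    rng = range(lo, hi + 1)
    for a, b, c, d in itertools.product(rng, rng, rng, rng):
        yield ContingencyTable(a, b, c, d)


def check_monotonicity(
    measure: str,
    lo: int = 1,
    hi: int = 10,
    rule: Rule = RULE,
    tol: float = 1e-12,
) -> CheckResult:
    """Exhaustive unit-increment check over the count grid {lo..hi}^4.

    The measure must not decrease with a or d and must not increase with
    b or c.  Infinite values compare in the usual order.
    """
    skipped = 0
    for table in _grid_tables(lo, hi):
        base, defined = measure_value(measure, table, rule)
        if not defined:
            skipped += 1
            continue
        for delta, direction in ((("da",), +1), (("db",), -1), (("dc",), -1), (("dd",), +1)):
            bumped = table.perturbed(**{delta[0]: 1})
            new, ndef = measure_value(measure, bumped, rule)
            if not ndef:
                skipped += 1
                continue
            change = (new - base) * direction
            if math.isnan(change):  # inf - inf: flat at infinity, allowed
                continue
            if change < -tol:
                return CheckResult(
                    measure, "monotonicity", False, witness=table,
                    detail=f"{delta[0]}=+1 moved value from {base!r} to {new!r}",
                    skipped=skipped,
                )
    return CheckResult(measure, "monotonicity", True, skipped=skipped)


def check_logicality_normalization(
    measure: str,
    tables: Iterable[ContingencyTable],
    rule: Rule = RULE,
    tol: float = 1e-9,
) -> Tuple[CheckResult, CheckResult]:
    """(logicality, normalization) verdicts over a table collection.

    Logicality: value +1 whenever the rule has no counterexample (c = 0
    here), -1 whenever it has no positive example (a = 0).  Normalization:
    every defined value lies in [-1, 1].
    """
    logicality = CheckResult(measure, "logicality", True)
    normalization = CheckResult(measure, "normalization", True)
    for table in tables:
        value, defined = measure_value(measure, table, rule)
        if not defined:
            logicality.skipped += 1
            continue
        if normalization.holds and not (-1 - tol <= value <= 1 + tol):
            normalization.holds = False
            normalization.witness = table
            normalization.detail = f"value {value!r} outside [-1, 1]"
        if logicality.holds:
            counter = table.count(rule.antecedent, H0 if rule.consequent == H1 else H1)
            positive = table.count(rule.antecedent, rule.consequent)
            if counter == 0 and positive > 0 and abs(value - 1) > tol:
                logicality.holds = False
                logicality.witness = table
                logicality.detail = f"no counterexamples but value {value!r} != 1"
            elif positive == 0 and counter > 0 and abs(value + 1) > tol:
                logicality.holds = False
                logicality.witness = table
                logicality.detail = f"no positive examples but value {value!r} != -1"
    return logicality, normalization


@dataclass
class IncrementResult:
    """Effect of a single-count increment on one measure."""

    measure: str
    base_table: ContingencyTable
    delta: str  # which count was incremented, e.g. "a"
    amount: float
    base_value: float
    new_value: float

    @property
    def increment(self) -> float:
        return self.new_value - self.base_value


def increment(
    measure: str, base: ContingencyTable, delta: str, amount: float = 1, rule: Rule = RULE
) -> IncrementResult:
    if delta not in "abcd":
        raise ValueError("delta must be one of 'a', 'b', 'c', 'd'")
    base_value, _ = measure_value(measure, base, rule)
    new_value, _ = measure_value(measure, base.perturbed(**{f"d{delta}": amount}), rule)
    return IncrementResult(measure, base, delta, amount, base_value, new_value)


def nicod_fisher_check(
    measure: str, base: ContingencyTable, rule: Rule = RULE, tol: float = 1e-9
) -> bool:
    """One more positive example raises the measure, one more counterexample
    lowers it, and e0-examples (db, dd) leave it unchanged."""
    da = increment(measure, base, "a", rule=rule).increment
    db = increment(measure, base, "b", rule=rule).increment
    dc = increment(measure, base, "c", rule=rule).increment
    dd = increment(measure, base, "d", rule=rule).increment
    return da > tol and dc < -tol and abs(db) <= tol and abs(dd) <= tol


@dataclass
class RavenRow:
    measure: str
    base_value: float
    after_da: float
    after_dd: float

    @property
    def advantage(self) -> float:
        """(df/da) - (df/dd): positive means a positive example counts more
        than an irrelevant non-example."""
        return (self.after_da - self.base_value) - (self.after_dd - self.base_value)


def raven_experiment(
    base: ContingencyTable,
    measures: Sequence[str],
    rule: Rule = RULE,
) -> Dict[str, RavenRow]:
    """Compare da=1 against dd=1 for each measure on a base table.

    Answers, per measure, whether one more black raven confirms "ravens
    are black" more than one more non-black non-raven does.
    """
    out: Dict[str, RavenRow] = {}
    for m in measures:
        base_value, _ = measure_value(m, base, rule)
        out[m] = RavenRow(
            measure=m,
            base_value=base_value,
            after_da=increment(m, base, "a", rule=rule).new_value,
            after_dd=increment(m, base, "d", rule=rule).new_value,
        )
    return out


@dataclass
class DesiderataReport:
    """Per-measure verdicts for the full desiderata battery."""

    measure: str
    symmetries: Dict[str, CheckResult] = field(default_factory=dict)
    monotonicity: Optional[CheckResult] = None
    logicality: Optional[CheckResult] = None
    normalization: Optional[CheckResult] = None
    nicod_fisher: Optional[bool] = None

    def as_dict(self) -> dict:
        def _flag(r):
            if r is None:
                return None
            out = {"holds": r.holds}
            if r.witness is not None:
                out["witness"] = list(r.witness.as_tuple())
                out["detail"] = r.detail
            return out

        return {
            "measure": self.measure,
            "symmetries": {k: _flag(v) for k, v in self.symmetries.items()},
            "monotonicity": _flag(self.monotonicity),
            "logicality": _flag(self.logicality),
            "normalization": _flag(self.normalization),
            "nicod_fisher": self.nicod_fisher,
        }


def random_tables(
    count: int,
    seed: int,
    max_count: float = 100.0,
    integer: bool = False,
) -> List[ContingencyTable]:
    """Deterministic random tables for sampling-based checks."""
    import numpy as np

    rng = np.random.default_rng(seed)
    tables: List[ContingencyTable] = []
    while len(tables) < count:
        if integer:
            counts = rng.integers(0, int(max_count) + 1, size=4)
        else:
            counts = rng.uniform(0, max_count, size=4)
        if counts.sum() <= 0:
            continue
        tables.append(ContingencyTable(*(float(v) for v in counts)))
    return tables


def desiderata_report(
    measure: str,
    tables: Optional[Sequence[ContingencyTable]] = None,
    nicod_base: Optional[ContingencyTable] = None,
    grid_hi: int = 10,
    seed: int = 0,
) -> DesiderataReport:
    """Run the whole battery for one measure."""
    if tables is None:
        tables = random_tables(500, seed)
    if nicod_base is None:
        nicod_base = ContingencyTable(20, 10, 10, 20)
    report = DesiderataReport(measure=measure)
    for kind in ("HS", "ES", "CS", "TS"):
        if kind == "CS" and measure not in _CONVERSE_CAPABLE:
            continue
        report.symmetries[kind] = check_symmetry(measure, kind, tables)
    report.monotonicity = check_monotonicity(measure, 1, grid_hi)
    edge_tables = list(tables) + [
        ContingencyTable(5, 3, 0, 7),
        ContingencyTable(0, 3, 5, 7),
        ContingencyTable(1, 0, 0, 1),
    ]
    report.logicality, report.normalization = check_logicality_normalization(measure, edge_tables)
    report.nicod_fisher = nicod_fisher_check(measure, nicod_base)
    return report
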