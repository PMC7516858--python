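"""Published worked examples, as machine-readable fixtures.

Each fixture bundles inputs (counts or test profiles), the published
expected values at their printed precision, and erratum flags for the
few printed cells that do not follow from the stated formulas.  The test
suite and the ``reproduce`` CLI subcommand consume these; nothing is ever
downloaded.

Erratum cells (excluded from reproduction checks, never tuned to):

* ``comparison_examples`` Ex. 1, column c*: printed 0.8, but
  (a - c)/max(a, c) = (20 - 8)/20 = 0.6.
* ``comparison_examples`` Ex. 3, column N: printed 0.091, but
  P(e1|h1) - P(e1|h0) = 1 - 90/990 = 0.909 (apparently the Z value
  repeated).
* ``raven_increments`` S and N at da = 1: printed 0.334, formulas give
  0.344 (consistent with the printed zero in the last column).
* ``prevalence_sweep`` priors 0.001 and 0.1: printed posteriors 0.002 and
  0.19 are not reproducible from b* = 0.9 (the formula gives 0.0099 and
  0.526); only the prior-0.25 cell is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .contingency import ContingencyTable, TestProfile

#: printed decimal places of each fixture's values
PRECISION = {
    "comparison_examples": 3,
    "test_measure_grid": 2,
    "raven_increments": 3,
    "prevalence_sweep": 2,
}


@dataclass(frozen=True)
class GridFixture:
    """A grid of expected measure values with erratum flags."""

    name: str
    rows: Dict[str, object]  # row label -> input (table or profile)
    expected: Dict[Tuple[str, str], float]  # (row, column) -> printed value
    errata: Dict[Tuple[str, str], str] = field(default_factory=dict)
    precision: int = 3

    def non_erratum_cells(self):
        for key, value in self.expected.items():
            if key not in self.errata:
                yield key, value


#: Three contrasting samples (prevalences 0.2, 0.2, 0.01; n = 1000) that
#: separate likelihood-ratio measures (L, F, b*) from posterior-difference
#: measures.  Ex. 1: rare positives, almost no counterexamples.  Ex. 2:
#: plentiful positives but many counterexamples.  Ex. 3: rare hypothesis.
COMPARISON_TABLES = {
    "ex1": ContingencyTable(20, 180, 8, 792),
    "ex2": ContingencyTable(200, 0, 720, 80),
    "ex3": ContingencyTable(10, 0, 90, 900),
}

_COMPARISON_COLUMNS = ("D", "M", "R", "C", "Z", "S", "N", "L", "F", "b*", "c*")

_COMPARISON_EXPECTED = {
    "ex1": (0.514, 0.072, 1.84, 0.014, 0.643, 0.529, 0.09, 3.32, 0.818, 0.9, 0.8),
    "ex2": (0.017, 0.08, 0.12, 0.016, 0.022, 0.217, 0.1, 0.152, 0.053, 0.1, -0.722),
    "ex3": (0.09, 0.9, 3.32, 0.009, 0.091, 0.1, 0.091, 3.46, 0.833, 0.91, -0.9),
}


def comparison_examples() -> GridFixture:
    expected = {
        (row, col): value
        for row, values in _COMPARISON_EXPECTED.items()
        for col, value in zip(_COMPARISON_COLUMNS, values)
    }
    return GridFixture(
        name="comparison_examples",
        rows=dict(COMPARISON_TABLES),
        expected=expected,
        errata={
            ("ex1", "c*"): "printed 0.8; (a-c)/max(a,c) = 0.6",
            ("ex3", "N"): "printed 0.091; P(e1|h1)-P(e1|h0) = 0.909",
        },
        precision=3,
    )


#: COVID-19 test profiles: the nucleic-acid assay (low sensitivity, high
#: specificity) and chest CT (higher sensitivity, lower specificity),
#: with the assumed infection prior 0.25.
NAT_PROFILE = TestProfile(sensitivity=0.5, specificity=0.95, prior=0.25)
CT_PROFILE = TestProfile(sensitivity=0.8, specificity=0.75, prior=0.25)


def covid_test_profiles() -> Dict[str, TestProfile]:
    return {"NAT": NAT_PROFILE, "CT": CT_PROFILE}


_TEST_GRID_COLUMNS = ("D", "M", "Z", "S", "C", "N", "F", "b*", "c*")

_TEST_GRID_EXPECTED = {
    "NAT-": (0.10, 0.11, 0.40, 0.62, 0.08, 0.45, 0.31, 0.47, 0.83),
    "NAT+": (0.52, 0.34, 0.69, 0.62, 0.08, 0.45, 0.82, 0.90, 0.70),
    "CT-": (0.17, 0.14, 0.67, 0.43, 0.10, 0.55, 0.58, 0.73, 0.91),
    "CT+": (0.27, 0.41, 0.36, 0.43, 0.10, 0.55, 0.52, 0.69, 0.06),
}


def test_measure_grid() -> GridFixture:
    """Expected degrees of confirmation for every measure on both tests."""
    expected = {
        (row, col): value
        for row, values in _TEST_GRID_EXPECTED.items()
        for col, value in zip(_TEST_GRID_COLUMNS, values)
    }
    return GridFixture(
        name="test_measure_grid",
        rows=dict(covid_test_profiles()),
        expected=expected,
        precision=2,
    )


#: Expected final calls of the improved two-test diagnosis, keyed by
#: (NAT result, CT result); the (-, +) cell is the one the second test
#: changes.
IMPROVED_DIAGNOSIS = {
    ("+", "+"): "positive",
    ("+", "-"): "positive",
    ("-", "+"): "positive",  # changed by CT
    ("-", "-"): "negative",
}

#: Measures whose plain comparison reproduces the improved diagnosis.
DIAGNOSIS_CONSISTENT_MEASURES = ("D", "M", "F", "b*")
#: Measures that flip at least one discordant cell.
DIAGNOSIS_INCONSISTENT_MEASURES = ("Z", "S", "C", "N", "c*")


#: Raven-increment base sample and expected rows: value at the base
#: (a = d = 20, b = c = 10), after da = 1, and after dd = 1.
RAVEN_BASE = ContingencyTable(20, 10, 10, 20)

_RAVEN_EXPECTED = {
    "D": (0.167, 0.169, 0.175),
    "M": (0.167, 0.169, 0.175),
    "C": (0.083, 0.086, 0.086),
    "Z": (0.333, 0.344, 0.344),
    "S": (0.333, 0.334, 0.344),
    "N": (0.333, 0.334, 0.344),
    "F": (0.333, 0.340, 0.348),
    "LR+": (2.0, 2.03, 2.07),
    "c*": (0.5, 0.524, 0.5),
}


def raven_increments() -> GridFixture:
    expected = {}
    for measure, (base, da, dd) in _RAVEN_EXPECTED.items():
        expected[(measure, "base")] = base
        expected[(measure, "da")] = da
        expected[(measure, "dd")] = dd
    return GridFixture(
        name="raven_increments",
        rows={"base": RAVEN_BASE},
        expected=expected,
        errata={
            ("S", "da"): "printed 0.334; formula gives 0.344",
            ("N", "da"): "printed 0.334; formula gives 0.344",
        },
        precision=3,
    )


#: Posterior P(h1|th_e1) under b* = 0.9 as the prior prevalence moves
#: across risk groups.
PREVALENCE_SWEEP_BSTAR = 0.9

_PREVALENCE_EXPECTED = {"0.001": 0.002, "0.1": 0.19, "0.25": 0.77}


def prevalence_sweep() -> GridFixture:
    return GridFixture(
        name="prevalence_sweep",
        rows={p: float(p) for p in _PREVALENCE_EXPECTED},
        expected={(p, "posterior"): v for p, v in _PREVALENCE_EXPECTED.items()},
        errata={
            ("0.001", "posterior"): "printed 0.002; formula gives 0.0099",
            ("0.1", "posterior"): "printed 0.19; formula gives 0.526",
        },
        precision=2,
    )


def fixtures() -> Dict[str, GridFixture]:
    """All worked-example fixtures, keyed by name."""
    return {
        "comparison_examples": comparison_examples(),
        "test_measure_grid": test_measure_grid(),
        "raven_increments": raven_increments(),
        "prevalence_sweep": prevalence_sweep(),
    }
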