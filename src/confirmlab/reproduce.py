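"""Recompute the worked-example grids from scratch and compare them.

Every value is produced by the measure implementations on the fixture
inputs; the published numbers enter only as the comparison side.  Values
are compared at each grid's printed precision (half-up) plus one unit in
the last place, and erratum-flagged cells are reported separately, never
forced to agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .contingency import ContingencyTable, likelihood_ratios, round_half_up
from .diagnosis import RULE_NEGATIVE, RULE_POSITIVE, evaluate_test
from .outcomes import Rule
from .prediction import predict_from_b
from .properties import measure_value
from .worked_examples import (
    COMPARISON_TABLES,
    PREVALENCE_SWEEP_BSTAR,
    RAVEN_BASE,
    GridFixture,
    covid_test_profiles,
    fixtures,
)


def _grid_value(measure: str, table: ContingencyTable, rule: Rule = RULE_POSITIVE) -> float:
    if measure == "LR+":
        return likelihood_ratios(table)[0]
    value, _ = measure_value(measure, table, rule)
    return value


def computed_comparison_grid() -> pd.DataFrame:
    """Measure grid for the three contrasting samples (rule e1 -> h1)."""
    columns = ("D", "M", "R", "C", "Z", "S", "N", "L", "F", "b*", "c*")
    data = {
        row: [_grid_value(m, table) for m in columns]
        for row, table in COMPARISON_TABLES.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(columns))


def computed_test_grid() -> pd.DataFrame:
    """c(test-) and c(test+) for the NAT and CT profiles, all measures."""
    columns = ("D", "M", "Z", "S", "C", "N", "F", "b*", "c*")
    rows = {}
    for name, profile in covid_test_profiles().items():
        evaluations = evaluate_test(profile, columns)
        rows[f"{name}-"] = [evaluations[m].negative for m in columns]
        rows[f"{name}+"] = [evaluations[m].positive for m in columns]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))


def computed_raven_grid(base: ContingencyTable = RAVEN_BASE) -> pd.DataFrame:
    """Base, da = 1, and dd = 1 values plus the positive-example advantage."""
    measures = ("D", "M", "C", "Z", "S", "N", "F", "LR+", "c*")
    rows = {}
    for m in measures:
        base_value = _grid_value(m, base)
        after_da = _grid_value(m, base.perturbed(da=1))
        after_dd = _grid_value(m, base.perturbed(dd=1))
        rows[m] = [base_value, after_da, after_dd, (after_da - base_value) - (after_dd - base_value)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["base", "da", "dd", "advantage"])


def computed_prevalence_sweep() -> pd.DataFrame:
    """P(h1|th_e1) under b* = 0.9 across the fixture's prior prevalences."""
    rows = {
        label: [predict_from_b(prior, PREVALENCE_SWEEP_BSTAR).p_h1]
        for label, prior in fixtures()["prevalence_sweep"].rows.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["posterior"])


_COMPUTERS = {
    "comparison_examples": computed_comparison_grid,
    "test_measure_grid": computed_test_grid,
    "raven_increments": computed_raven_grid,
    "prevalence_sweep": computed_prevalence_sweep,
}


def _printed_decimals(value: float) -> int:
    """Decimal places the published value was printed with (e.g. 2.03 -> 2)."""
    text = f"{value:g}"
    if "." not in text:
        return 0
    return len(text.split(".")[1])


@dataclass
class CellComparison:
    row: str
    column: str
    computed: float
    published: float
    matches: bool
    erratum: Optional[str] = None


def compare_fixture(name: str) -> List[CellComparison]:
    """Recompute one fixture grid and compare cell by cell.

    A cell matches when the computed value, half-up rounded to the grid's
    printed precision, is within one unit in the last place of the
    published value.  Erratum cells carry their note and are expected NOT
    to match.
    """
    fixture = fixtures()[name]
    grid = _COMPUTERS[name]()
    out: List[CellComparison] = []
    for (row, column), published in fixture.expected.items():
        computed = float(grid.loc[row, column])
        decimals = min(fixture.precision, _printed_decimals(published))
        ulp = 10.0**-decimals
        rounded = round_half_up(computed, decimals)
        matches = math.isfinite(computed) and abs(rounded - published) <= ulp + 1e-12
        out.append(
            CellComparison(
                row=row,
                column=column,
                computed=computed,
                published=published,
                matches=matches,
                erratum=fixture.errata.get((row, column)),
            )
        )
    return out


def mismatches(name: str, include_errata: bool = False) -> List[CellComparison]:
    """Non-matching cells of a fixture (erratum cells excluded by default)."""
    return [
        cell
        for cell in compare_fixture(name)
        if not cell.matches and (include_errata or cell.erratum is None)
    ]
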