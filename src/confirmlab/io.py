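"""Reading and writing tables, profiles, and measure grids.

CSV schema for contingency tables: header ``a,b,c,d`` with an optional
``label`` column, one table per row.  Test profiles are JSON objects with
keys ``sensitivity``, ``specificity``, ``prior``.  Measure grids export as
TSV (rows = examples or test results, columns = measures).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .contingency import ContingencyTable, TestProfile, round_half_up

PathLike = Union[str, Path]


def read_tables_csv(path: PathLike) -> Dict[str, ContingencyTable]:
    """Read labeled tables; unlabeled rows are keyed by row number."""
    frame = pd.read_csv(path)
    missing = {"a", "b", "c", "d"} - set(frame.columns)
    if missing:
        raise ValueError(f"CSV is missing count columns {sorted(missing)}")
    out: Dict[str, ContingencyTable] = {}
    for i, row in frame.iterrows():
        label = str(row["label"]) if "label" in frame.columns else str(i)
        out[label] = ContingencyTable(float(row.a), float(row.b), float(row.c), float(row.d))
    return out


def write_tables_csv(path: PathLike, tables: Dict[str, ContingencyTable]) -> None:
    frame = pd.DataFrame(
        [
            {"label": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for label, t in tables.items()
        ]
    )
    frame.to_csv(path, index=False)


def read_profile_json(path: PathLike) -> TestProfile:
    with open(path) as fh:
        obj = json.load(fh)
    return TestProfile(
        sensitivity=float(obj["sensitivity"]),
        specificity=float(obj["specificity"]),
        prior=float(obj["prior"]),
    )


def grid_to_tsv(
    grid: pd.DataFrame,
    path: Optional[PathLike] = None,
    decimals: Optional[int] = None,
) -> str:
    """Render a measure grid as TSV, optionally half-up rounded.

    Returns the TSV text; writes it to ``path`` when given.
    """
    if decimals is not None:
        grid = grid.map(
            lambda v: round_half_up(v, decimals) if isinstance(v, (int, float)) else v
        )
    text = grid.to_csv(sep="\t")
    if path is not None:
        Path(path).write_text(text)
    return text
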