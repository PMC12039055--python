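"""Per-cell metadata handling and sub-dataset extraction.

A cell table holds one row per cell with its discrete attributes (sex,
tissue, cell type, age in months, individual).  Combination tables are built
by counting cells per attribute combination and keeping only combinations
with *strictly more than* ``min_cells`` cells (the study defaults: >10 cells
for the 3-month tissue-effect analysis over individual x tissue x cell type,
>25 cells for the aging analysis over sex x tissue x cell type x age group).
Given a maximal solution, the corresponding sub-dataset contains exactly the
cells whose attribute tuple lies in the solution's cross-combination set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import pandas as pd

from .hypergraph import DiscreteTable, Solution

REQUIRED_COLUMNS = ("cell_id", "sex", "tissue", "cell_type", "age_months", "individual")

#: Attribute sets of the two study pipelines (both configurable).
TISSUE_PIPELINE_ATTRIBUTES = ("individual", "tissue", "cell_type")
AGING_PIPELINE_ATTRIBUTES = ("sex", "tissue", "cell_type", "age_group")

YOUNG_AGE = 3
OLD_MIN_AGE = 18
EXCLUDED_AGES = (1,)


def validate_cell_table(cells: pd.DataFrame, *, strip_whitespace: bool = False) -> pd.DataFrame:
    """Check required columns and cell-id uniqueness; optionally trim labels.

    Label matching elsewhere is exact and case-sensitive; the whitespace
    normalization hook is off by default.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required column(s): {', '.join(missing)}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id: {dup!r}")
    out = cells.copy()
    if strip_whitespace:
        for col in ("sex", "tissue", "cell_type", "individual"):
            out[col] = out[col].astype(str).str.strip()
    return out


def build_combination_table(
    cells: pd.DataFrame, attributes: Sequence[str], min_cells: int = 0
) -> DiscreteTable:
    """One row per attribute combination with strictly more than ``min_cells``
    cells (boundary counts are excluded)."""
    unknown = [a for a in attributes if a not in cells.columns]
    if unknown:
        raise ValueError(f"unknown attribute name(s): {', '.join(unknown)}")
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    counts = cells.groupby(list(attributes), observed=True).size()
    kept = counts[counts > min_cells]
    rows = [
        key if isinstance(key, tuple) else (key,) for key in kept.index.tolist()
    ]
    return DiscreteTable.from_records(attributes, rows)


def assign_age_groups(
    cells: pd.DataFrame,
    *,
    young_age: int = YOUNG_AGE,
    old_min_age: int = OLD_MIN_AGE,
    excluded_ages: Sequence[int] = EXCLUDED_AGES,
) -> pd.DataFrame:
    """Add an ``age_group`` column and drop excluded donors.

    Study rule: 3-month cells are "Young", cells aged >= 18 months are "Old",
    one-month donors are excluded.  Any other age is an error (unknown study
    design), as are negative or non-integer ages.
    """
    if "age_months" not in cells.columns:
        raise ValueError("cell table has no age_months column")
    ages = pd.to_numeric(cells["age_months"], errors="coerce")
    if ages.isna().any():
        bad = cells.loc[ages.isna(), "age_months"].iloc[0]
        raise ValueError(f"unparseable age: {bad!r}")
    if (ages % 1 != 0).any() or (ages < 0).any():
        bad = ages[(ages % 1 != 0) | (ages < 0)].iloc[0]
        raise ValueError(f"ages must be non-negative integers, got {bad!r}")
    ages = ages.astype(int)
    keep = ~ages.isin(list(excluded_ages))
    known = (ages == young_age) | (ages >= old_min_age) | ~keep
    if not known.all():
        bad = ages[~known].iloc[0]
        raise ValueError(
            f"age {bad} months is outside the declared study design "
            f"(young={young_age}, old>={old_min_age}, excluded={tuple(excluded_ages)})"
        )
    out = cells.loc[keep].copy()
    out["age_group"] = ["Young" if a == young_age else "Old" for a in ages[keep]]
    return out


@dataclass
class SubDataset:
    """Cells corresponding to one maximal solution's combinations."""

    labels: dict[str, tuple[str, ...]]
    cells: pd.DataFrame
    counts: pd.DataFrame  # one row per combination with its cell count

    @property
    def cell_ids(self) -> list[str]:
        return self.cells["cell_id"].tolist()

    def manifest(self) -> dict:
        return {
            "solution": {k: list(v) for k, v in self.labels.items()},
            "n_cells": len(self.cells),
            "cell_ids": self.cell_ids,
            "counts": self.counts.to_dict(orient="records"),
        }


def extract_subdataset(
    cells: pd.DataFrame,
    solution: Solution | Mapping[str, Sequence[str]],
    columns: Sequence[str] | None = None,
) -> SubDataset:
    """Extract exactly the cells whose attribute tuple is in ``Pi_k(S)``.

    ``solution`` may be a :class:`Solution` (then ``columns`` names its
    parts) or a ready attribute -> labels mapping.  A combination of the
    solution with no cells at all indicates mismatched inputs and is an
    error, since the solution's completeness guarantee would be violated.
    """
    if isinstance(solution, Solution):
        if columns is None:
            raise ValueError("columns are required to interpret a Solution's parts")
        labels = solution.labels(columns)
    else:
        labels = {k: tuple(v) for k, v in solution.items()}
    unknown = [a for a in labels if a not in cells.columns]
    if unknown:
        raise ValueError(f"solution attribute(s) not in cell table: {', '.join(unknown)}")
    mask = pd.Series(True, index=cells.index)
    for attr, labs in labels.items():
        mask &= cells[attr].isin(labs)
    sub = cells.loc[mask].copy()
    attrs = list(labels)
    counts = (
        sub.groupby(attrs, observed=True).size().rename("n_cells").reset_index()
        if len(sub)
        else pd.DataFrame(columns=attrs + ["n_cells"])
    )
    present = {tuple(rec[a] for a in attrs) for rec in counts.to_dict(orient="records")}
    for combo in product(*(labels[a] for a in attrs)):
        if combo not in present:
            raise ValueError(
                f"combination {combo!r} of the solution has no cells; "
                "the cell table does not match the enumerated table"
            )
    return SubDataset(labels=labels, cells=sub, counts=counts)
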