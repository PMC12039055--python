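"""File input/output: combination tables, cell metadata, expression
matrices (Matrix Market or dense CSV), solution JSON, DOT graphs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dag import EffectDAG
from .effects import ExpressionMatrix
from .hypergraph import DiscreteTable, GraphSummary, Solution
from .subdataset import REQUIRED_COLUMNS, validate_cell_table


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_combination_table(path: str | Path) -> DiscreteTable:
    """Read a k-column combination table from CSV/TSV (header row required)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.empty:
        raise ValueError(f"{path} contains no combinations")
    return DiscreteTable.from_dataframe(df)


def write_combination_table(table: DiscreteTable, path: str | Path) -> None:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index=False)


def read_cell_metadata(path: str | Path, *, strip_whitespace: bool = False) -> pd.DataFrame:
    """Read and validate per-cell metadata (CSV/TSV with required headers).

    Errors name the missing column or the 1-based file line of an
    unparseable age.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {', '.join(missing)}")
    ages = pd.to_numeric(df["age_months"], errors="coerce")
    if ages.isna().any():
        row = int(ages.index[ages.isna()][0])
        raise ValueError(
            f"{path}: unparseable age {df['age_months'].iloc[row]!r} on line {row + 2}"
        )
    df["age_months"] = ages.astype(int)
    return validate_cell_table(df, strip_whitespace=strip_whitespace)


def write_cell_metadata(cells: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    cells.to_csv(path, sep=_sep_for(path), index=False)


def solutions_to_json(
    solutions: Iterable[Solution], columns: Sequence[str], path: str | Path
) -> None:
    from .enumeration import solutions_to_records

    Path(path).write_text(
        json.dumps(solutions_to_records(solutions, columns), indent=2) + "\n"
    )


def read_solutions_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def solutions_to_tsv(
    solutions: Iterable[Solution], columns: Sequence[str], path: str | Path,
    name_prefix: str = "solution",
) -> None:
    """One-row-per-solution rendering: name, comma-joined labels per column."""
    rows = []
    for i, sol in enumerate(sorted(solutions, key=len, reverse=True), start=1):
        labels = sol.labels(columns)
        row = {"name": f"{name_prefix}{i}"}
        for col in columns:
            row[col] = ", ".join(labels[col])
        row["n_combinations"] = sol.n_combinations
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_csv(path: str | Path) -> ExpressionMatrix:
    """Dense genes x cells CSV with gene names in the first column."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_csv(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.genes, columns=expr.cells).to_csv(path)


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Matrix Market expression with row (gene) / column (cell) sidecars."""
    values = spio.mmread(str(mtx_path))
    if sparse.issparse(values):
        values = values.toarray()
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    return ExpressionMatrix(genes=genes, cells=cells, values=np.asarray(values, float))


def write_expression_mtx(
    expr: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(expr.values))
    Path(genes_path).write_text("\n".join(expr.genes) + "\n")
    Path(cells_path).write_text("\n".join(expr.cells) + "\n")


def write_summary_json(summary: GraphSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_json(), indent=2) + "\n")


def write_dot(dag: EffectDAG, path: str | Path, name: str = "effects") -> None:
    Path(path).write_text(dag.to_dot(name=name) + "\n")
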