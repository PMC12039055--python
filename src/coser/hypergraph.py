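"""Discrete-attribute tables as k-partite hypergraphs.

An attribute table — one row per combination of categorical values observed in
a dataset (e.g. the tissue x cell-type pairs present in a single-cell atlas) —
is modelled as a k-partite hypergraph: each column is a vertex part, each
category label a vertex, and each distinct row a hyperedge taking exactly one
vertex from every part.  A *solution* to an instance ``(H; theta_1..theta_k)``
is a vertex subset ``S`` whose per-part pieces ``S_i`` satisfy
``|S_i| >= theta_i`` and for which every cross-combination ``Pi_k(S)`` of one
vertex per part is a hyperedge.  Maximal solutions are the confounding-free
sub-dataset skeletons the rest of the package analyses.

This module holds the data model, the solution predicate, an exhaustive
brute-force enumerator used as an independent oracle, and bipartite-graph
summary statistics (degrees and realized combination fraction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: A vertex is identified by (column index, label) so that identical labels in
#: different columns never collide.
Vertex = tuple[int, str]


def canonical_key(obj):
    """Total-order sort key for nested tuples / frozensets / scalars.

    Used everywhere a deterministic output order is promised: sets become
    sorted tuples of their members' keys, scalars compare as strings.
    """
    if isinstance(obj, (frozenset, set)):
        return ("s", tuple(sorted(canonical_key(x) for x in obj)))
    if isinstance(obj, tuple):
        return ("t", tuple(canonical_key(x) for x in obj))
    return ("a", str(obj))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported
    percentages and mean degrees; full precision is kept internally)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class DiscreteTable:
    """A k-column table of observed attribute combinations.

    Rows are a *set* of k-tuples of category labels: duplicate input rows
    collapse silently because a hyperedge either exists or it does not.
    """

    columns: tuple[str, ...]
    rows: frozenset[tuple[str, ...]]

    def __post_init__(self):
        if len(self.columns) < 1:
            raise ValueError("a combination table needs at least one column")
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row {row!r} has {len(row)} entries, expected {len(self.columns)}"
                )

    @property
    def k(self) -> int:
        return len(self.columns)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @classmethod
    def from_records(
        cls, columns: Sequence[str], records: Iterable[Sequence]
    ) -> "DiscreteTable":
        """Build a table from row records, validating for missing values.

        A missing/blank entry is a hard error naming the offending row index:
        it has no hypergraph meaning and the caller must pre-filter.
        """
        columns = tuple(str(c) for c in columns)
        rows = []
        for idx, rec in enumerate(records):
            rec = tuple(rec)
            if len(rec) != len(columns):
                raise ValueError(
                    f"row {idx} has {len(rec)} entries, expected {len(columns)}"
                )
            for value in rec:
                if _is_missing(value):
                    raise ValueError(f"row {idx} contains a missing value: {rec!r}")
            rows.append(tuple(str(v) for v in rec))
        return cls(columns=columns, rows=frozenset(rows))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DiscreteTable":
        return cls.from_records(list(df.columns), df.itertuples(index=False, name=None))

    def permute_columns(self, order: Sequence[int]) -> "DiscreteTable":
        """Reorder columns (part indices are cosmetic; outputs use names)."""
        if sorted(order) != list(range(self.k)):
            raise ValueError(f"order {order!r} is not a permutation of 0..{self.k - 1}")
        return DiscreteTable(
            columns=tuple(self.columns[i] for i in order),
            rows=frozenset(tuple(row[i] for i in order) for row in self.rows),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.rows)
        return pd.DataFrame(rows, columns=list(self.columns))


@dataclass(frozen=True)
class KPartiteHypergraph:
    """Vertex parts ``V_1..V_k`` plus hyperedges, one per distinct table row.

    Invariant: every hyperedge intersects each part in exactly one vertex.
    """

    columns: tuple[str, ...]
    parts: tuple[frozenset[Vertex], ...]
    edges: frozenset[frozenset]

    @property
    def k(self) -> int:
        return len(self.parts)

    @property
    def n(self) -> int:
        return sum(len(p) for p in self.parts)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def vertices(self) -> frozenset[Vertex]:
        return frozenset(v for p in self.parts for v in p)


def table_to_hypergraph(table: DiscreteTable) -> KPartiteHypergraph:
    """Model a combination table by a k-partite hypergraph.

    Vertices are (column index, label) pairs; hyperedges are the distinct
    rows. An empty table is an error (no combinations to model).
    """
    if not table.rows:
        raise ValueError("cannot build a hypergraph from an empty table")
    parts = [set() for _ in range(table.k)]
    edges = set()
    for row in table.rows:
        edge = []
        for i, label in enumerate(row):
            v = (i, label)
            parts[i].add(v)
            edge.append(v)
        edges.add(frozenset(edge))
    return KPartiteHypergraph(
        columns=table.columns,
        parts=tuple(frozenset(p) for p in parts),
        edges=frozenset(edges),
    )


@dataclass(frozen=True)
class Instance:
    """A hypergraph together with per-part size thresholds ``theta_i >= 1``."""

    hypergraph: KPartiteHypergraph
    thetas: tuple[int, ...]

    def __post_init__(self):
        if len(self.thetas) != self.hypergraph.k:
            raise ValueError(
                f"{len(self.thetas)} thresholds for a {self.hypergraph.k}-partite hypergraph"
            )
        if any(t < 1 for t in self.thetas):
            raise ValueError("all thresholds must be positive integers")


def split_parts(members: Iterable[Vertex], k: int) -> list[frozenset]:
    """Split a vertex set into its per-part pieces ``S_i = S ∩ V_i``."""
    parts: list[set] = [set() for _ in range(k)]
    for v in members:
        parts[v[0]].add(v)
    return [frozenset(p) for p in parts]


@dataclass(frozen=True)
class Solution:
    """A complete-combination vertex subset (all cross-combinations present)."""

    members: frozenset

    def __len__(self) -> int:
        return len(self.members)

    def parts(self, k: int | None = None) -> list[frozenset]:
        if k is None:
            k = max(v[0] for v in self.members) + 1
        return split_parts(self.members, k)

    def labels(self, columns: Sequence[str]) -> dict[str, tuple[str, ...]]:
        """Render as attribute-name -> sorted label tuple."""
        parts = self.parts(len(columns))
        return {
            col: tuple(sorted(v[1] for v in part))
            for col, part in zip(columns, parts)
        }

    @property
    def n_combinations(self) -> int:
        return math.prod(len(p) for p in self.parts())


def sort_solutions(solutions: Iterable[Solution]) -> tuple[Solution, ...]:
    """Deterministic order: descending total size, then canonical form."""
    return tuple(
        sorted(set(solutions), key=lambda s: (-len(s), canonical_key(s.members)))
    )


def is_solution(members: Iterable[Vertex], inst: Instance) -> bool:
    """True iff the size thresholds and complete-combination condition hold."""
    members = frozenset(members)
    hg = inst.hypergraph
    if not members <= hg.vertices:
        return False
    parts = split_parts(members, hg.k)
    if any(len(p) < t for p, t in zip(parts, inst.thetas)):
        return False
    for combo in itertools.product(*parts):
        if frozenset(combo) not in hg.edges:
            return False
    return True


def brute_force_maximal_solutions(
    inst: Instance, *, max_vertices: int = 20
) -> tuple[Solution, ...]:
    """Exhaustively enumerate all inclusion-wise maximal solutions.

    Iterates every admissible per-part subset combination (2^n worst case);
    intended purely as a verification oracle on small instances and kept
    deliberately independent of the recursive enumeration machinery.
    """
    hg = inst.hypergraph
    if hg.n > max_vertices:
        raise ValueError(
            f"brute force is guarded at n <= {max_vertices} vertices (got {hg.n}); "
            "use enum_max_sol for larger instances"
        )
    per_part_choices = []
    for part, theta in zip(hg.parts, inst.thetas):
        elems = sorted(part, key=canonical_key)
        choices = [
            frozenset(c)
            for size in range(theta, len(elems) + 1)
            for c in itertools.combinations(elems, size)
        ]
        per_part_choices.append(choices)
    found: list[frozenset] = []
    for pick in itertools.product(*per_part_choices):
        ok = all(
            frozenset(combo) in hg.edges for combo in itertools.product(*pick)
        )
        if ok:
            found.append(frozenset().union(*pick))
    # independent pairwise maximality filter
    maximal = [
        s for s in found if not any(s < t for t in found)
    ]
    return sort_solutions(Solution(s) for s in maximal)


@dataclass(frozen=True)
class GraphSummary:
    """Degree and coverage statistics of a 2-column combination table."""

    columns: tuple[str, str]
    m: int
    part_sizes: dict
    degrees: dict
    mean_degree: dict
    mean_degree_rounded: dict
    realized_fraction_pct: float
    realized_fraction_pct_rounded: float

    def to_json(self) -> dict:
        return {
            "columns": list(self.columns),
            "n_combinations": self.m,
            "part_sizes": dict(self.part_sizes),
            "degrees": {c: dict(d) for c, d in self.degrees.items()},
            "mean_degree": dict(self.mean_degree),
            "mean_degree_rounded": dict(self.mean_degree_rounded),
            "realized_fraction_pct": self.realized_fraction_pct,
            "realized_fraction_pct_rounded": self.realized_fraction_pct_rounded,
        }


def graph_summary(table: DiscreteTable) -> GraphSummary:
    """Summarise a bipartite (k=2) combination table.

    Reports the edge count m, part sizes, per-vertex degrees, mean degree per
    part, and the realized fraction ``100 * m / (|V_1| * |V_2|)`` — the share
    of theoretically possible combinations actually observed.
    """
    if table.k != 2:
        raise ValueError(f"graph_summary requires exactly two columns, got {table.k}")
    degrees: dict[str, dict[str, int]] = {c: {} for c in table.columns}
    for a, b in table.rows:
        degrees[table.columns[0]][a] = degrees[table.columns[0]].get(a, 0) + 1
        degrees[table.columns[1]][b] = degrees[table.columns[1]].get(b, 0) + 1
    sizes = {c: len(d) for c, d in degrees.items()}
    m = table.n_rows
    mean = {c: m / sizes[c] for c in table.columns}
    frac = 100.0 * m / (sizes[table.columns[0]] * sizes[table.columns[1]])
    return GraphSummary(
        columns=table.columns,
        m=m,
        part_sizes=sizes,
        degrees=degrees,
        mean_degree=mean,
        mean_degree_rounded={c: round_half_up(v) for c, v in mean.items()},
        realized_fraction_pct=frac,
        realized_fraction_pct_rounded=round_half_up(frac),
    )
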