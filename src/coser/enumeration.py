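"""Recursive enumeration of all maximal complete-combination solutions.

The k-partite enumeration reduces to maximal biclique enumeration through an
auxiliary bipartite graph ``B_H = (V_k ∪ W_H, E_H)``: the left side is the
last vertex part, the right side is the set of hyperedge *remainders*
``Ê(v) = {H \\ {v} : v ∈ H ∈ E}``, and (v, Ĥ) is an edge iff the recombined
hyperedge exists.  Two necessary conditions prune the search:

* the last part ``S_k`` of any maximal solution is ``B ∩ V_k`` for some
  maximal solution B of the auxiliary instance ``(B_H; theta_k, 1)``;
* the remainder ``S \\ S_k`` must be a maximal solution of the reduced
  (k-1)-partite instance whose hyperedges are the common remainders
  ``Ê(S_k)``.

Candidates are therefore generated recursively part by part, pooled in a hash
set, and filtered to the inclusion-wise maximal ones.  The base case k = 1
has a unique maximal solution: all vertices covered by hyperedges.  The
decision problem is NP-complete already for k = 2 with equal thresholds, so
worst-case O*(2^n) time/space is accepted; a configurable candidate-count
guard aborts cleanly instead of exhausting memory.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .biclique import BipartiteGraph, enum_maximal_bicliques
from .hypergraph import (
    DiscreteTable,
    Instance,
    KPartiteHypergraph,
    Solution,
    Vertex,
    sort_solutions,
    table_to_hypergraph,
)


class GuardLimitError(RuntimeError):
    """Raised when the candidate store exceeds its configured size guard."""


class NeighborhoodIndex:
    """Per-vertex hyperedge incidence and remainder families.

    ``edges_of(v)`` is E(v), the hyperedges containing v; ``remainders(v)`` is
    Ê(v), each hyperedge with v deleted; ``common_remainders(U)`` intersects
    Ê(v) over v in U.  For any F in Ê(U) and v in U, F ∪ {v} is a hyperedge.
    """

    def __init__(self, hg: KPartiteHypergraph):
        self._incident: dict[Vertex, set] = defaultdict(set)
        for edge in hg.edges:
            for v in edge:
                self._incident[v].add(edge)

    def edges_of(self, v: Vertex) -> frozenset:
        return frozenset(self._incident.get(v, ()))

    def remainders(self, v: Vertex) -> frozenset:
        return frozenset(e - {v} for e in self._incident.get(v, ()))

    def common_remainders(self, vertices: Iterable[Vertex]) -> frozenset:
        vertices = list(vertices)
        if not vertices:
            raise ValueError("common_remainders needs a non-empty vertex set")
        out = set(self.remainders(vertices[0]))
        for v in vertices[1:]:
            out &= self.remainders(v)
        return frozenset(out)


@dataclass(frozen=True)
class AuxiliaryBipartite:
    """The reduction graph: left side V_k, right side remainder sets Ê(v)."""

    graph: BipartiteGraph


def build_auxiliary_bipartite(inst: Instance) -> AuxiliaryBipartite:
    """Build ``B_H`` for the last part of a k >= 2 instance.

    Right nodes are deduplicated by set identity; every right node has at
    least one incident edge by construction.
    """
    hg = inst.hypergraph
    if hg.k < 2:
        raise ValueError("the auxiliary graph is defined for k >= 2")
    index = NeighborhoodIndex(hg)
    last = hg.parts[-1]
    right: set = set()
    edges: set = set()
    for v in last:
        for rem in index.remainders(v):
            right.add(rem)
            edges.add((v, rem))
    return AuxiliaryBipartite(
        graph=BipartiteGraph(
            left=frozenset(last), right=frozenset(right), edges=frozenset(edges)
        )
    )


def reduce_instance(inst: Instance, s_k: Iterable[Vertex]) -> Instance:
    """Restrict to the first k-1 parts given a choice of last-part vertices.

    The reduced hypergraph keeps parts ``V_1..V_{k-1}`` and has hyperedges
    ``Ê(S_k)`` (common remainders), which is (k-1)-partite.
    """
    hg = inst.hypergraph
    s_k = frozenset(s_k)
    if not s_k:
        raise ValueError("S_k must be non-empty")
    if not s_k <= hg.parts[-1]:
        raise ValueError("S_k must be a subset of the last part V_k")
    index = NeighborhoodIndex(hg)
    reduced_edges = index.common_remainders(s_k)
    reduced = KPartiteHypergraph(
        columns=hg.columns[:-1],
        parts=hg.parts[:-1],
        edges=frozenset(reduced_edges),
    )
    return Instance(hypergraph=reduced, thetas=inst.thetas[:-1])


def filter_inclusion_maximal(family: Iterable[frozenset]) -> set[frozenset]:
    """Keep exactly the sets with no proper superset in the family.

    Idempotent; agrees with the all-pairs subset check (kept as an oracle in
    the test suite).
    """
    unique = sorted(set(family), key=len, reverse=True)
    kept: list[frozenset] = []
    for s in unique:
        if not any(s < t for t in kept):
            kept.append(s)
    return set(kept)


def _enum(
    hg: KPartiteHypergraph,
    thetas: tuple[int, ...],
    exhaustive: bool,
    guard: int,
) -> set[frozenset]:
    k = hg.k
    if k == 1:
        covered = frozenset(v for e in hg.edges for v in e)
        if covered and len(covered) >= thetas[0]:
            return {covered}
        return set()
    inst = Instance(hg, thetas)
    aux = build_auxiliary_bipartite(inst)
    theta_k = thetas[-1]
    candidates: set[frozenset] = set()
    for bc in enum_maximal_bicliques(aux.graph, theta_k, 1):
        base = bc.left  # = B ∩ V_k, sufficient by the first necessary condition
        if exhaustive:
            picks = [
                frozenset(c)
                for size in range(theta_k, len(base) + 1)
                for c in itertools.combinations(sorted(base), size)
            ]
        else:
            picks = [frozenset(base)]
        for pick in picks:
            reduced = reduce_instance(inst, pick)
            for sub in _enum(reduced.hypergraph, reduced.thetas, exhaustive, guard):
                candidates.add(pick | sub)
                if len(candidates) > guard:
                    raise GuardLimitError(
                        f"candidate store exceeded the guard limit of {guard}; "
                        "raise the guard or tighten the thresholds"
                    )
    return filter_inclusion_maximal(candidates)


def enum_max_sol(
    inst: Instance, *, exhaustive: bool = False, guard: int = 10**6
) -> tuple[Solution, ...]:
    """Enumerate all inclusion-wise maximal solutions of an instance.

    ``exhaustive=True`` additionally iterates every admissible subset of each
    auxiliary maximal solution's last-part piece; the default mode iterates
    only the piece itself, which already guarantees completeness.  Output is
    deterministically ordered (descending size, then canonical form).
    """
    return sort_solutions(
        Solution(s)
        for s in _enum(inst.hypergraph, inst.thetas, exhaustive, guard)
    )


def enumerate_table(
    table: DiscreteTable,
    thetas: Iterable[int] | int | None = None,
    **kwargs,
) -> tuple[Solution, ...]:
    """Convenience wrapper: table -> hypergraph -> maximal solutions.

    The default thresholds are theta_i = 2 for every part, i.e. each solution
    must include at least two distinct values of every attribute.
    """
    hg = table_to_hypergraph(table)
    if thetas is None:
        thetas = tuple(2 for _ in range(hg.k))
    elif isinstance(thetas, int):
        thetas = tuple(thetas for _ in range(hg.k))
    else:
        thetas = tuple(thetas)
    return enum_max_sol(Instance(hg, thetas), **kwargs)


def solutions_to_records(
    solutions: Iterable[Solution], columns: Iterable[str]
) -> list[dict]:
    """JSON-friendly rendering: attribute -> sorted labels plus |Pi_k(S)|."""
    columns = list(columns)
    recs = []
    for sol in solutions:
        rec: dict = {col: list(labels) for col, labels in sol.labels(columns).items()}
        rec["n_combinations"] = sol.n_combinations
        recs.append(rec)
    return recs
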