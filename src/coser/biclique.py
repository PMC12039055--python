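"""Maximal biclique enumeration with side-size thresholds.

Enumerating maximal bicliques of a bipartite graph is the base case (and, via
the auxiliary-graph reduction, the inner subroutine) of the k-partite
complete-combination enumeration.  The enumerator is a depth-first
branch-and-bound over the right vertex set in the style of the MBEA family of
algorithms: each recursion extends the current right set by a candidate
vertex, shrinks the left set to the common neighbourhood, absorbs right
vertices adjacent to all of it, and uses the processed-vertex list to reject
non-maximal branches.  Every reported pair (A, B) satisfies
A = common-neighbours(B) and B = common-neighbours(A), with both sides
non-empty.

Side-size thresholds shrink the solution space monotonically (a superset of a
qualifying biclique always qualifies), so thresholded maximality coincides
with plain maximality and thresholds are applied as a post-filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

from .hypergraph import DiscreteTable, canonical_key


@dataclass(frozen=True)
class BipartiteGraph:
    """A bipartite graph with arbitrary hashable vertices on each side."""

    left: frozenset
    right: frozenset
    edges: frozenset  # of (left vertex, right vertex) pairs

    def __post_init__(self):
        if self.left & self.right:
            raise ValueError("left and right vertex sets must be disjoint")
        for l, r in self.edges:
            if l not in self.left or r not in self.right:
                raise ValueError(f"edge ({l!r}, {r!r}) has an endpoint outside its side")

    @classmethod
    def from_table(cls, table: DiscreteTable) -> "BipartiteGraph":
        """Interpret a 2-column combination table as a bipartite graph."""
        if table.k != 2:
            raise ValueError("a bipartite graph needs a 2-column table")
        edges = frozenset(((0, a), (1, b)) for a, b in table.rows)
        return cls(
            left=frozenset((0, a) for a, _ in table.rows),
            right=frozenset((1, b) for _, b in table.rows),
            edges=edges,
        )

    def right_adjacency(self) -> dict:
        adj: dict[Hashable, set] = {r: set() for r in self.right}
        for l, r in self.edges:
            adj[r].add(l)
        return adj


@dataclass(frozen=True)
class Biclique:
    """A pair (left subset, right subset) with every cross pair an edge."""

    left: frozenset
    right: frozenset


def _all_maximal_bicliques(g: BipartiteGraph) -> set[tuple[frozenset, frozenset]]:
    """All maximal bicliques with both sides non-empty (MBEA-style search)."""
    adj = g.right_adjacency()
    results: set[tuple[frozenset, frozenset]] = set()

    def expand(L: set, R: set, P: list, Q: list) -> None:
        while P:
            x = P.pop(0)
            Lp = L & adj[x]
            if not Lp:
                Q.append(x)
                continue
            Rp = set(R)
            Rp.add(x)
            Pp: list = []
            Qp: list = []
            maximal = True
            for v in Q:
                common = Lp & adj[v]
                if len(common) == len(Lp):
                    maximal = False
                    break
                if common:
                    Qp.append(v)
            if maximal:
                for v in P:
                    common = Lp & adj[v]
                    if len(common) == len(Lp):
                        Rp.add(v)
                    elif common:
                        Pp.append(v)
                results.add((frozenset(Lp), frozenset(Rp)))
                if Pp:
                    expand(set(Lp), Rp, Pp, Qp)
            Q.append(x)

    candidates = sorted((r for r in g.right if adj[r]), key=canonical_key)
    expand(set(g.left), set(), candidates, [])
    return results


def enum_maximal_bicliques(
    g: BipartiteGraph, theta_left: int = 1, theta_right: int = 1
) -> tuple[Biclique, ...]:
    """Enumerate the maximal bicliques (A, B) with |A| >= theta_left and
    |B| >= theta_right, in a deterministic canonical order.

    Because thresholds are inherited by biclique supersets, the thresholded
    result is exactly the unthresholded enumeration filtered by size
    (the "filter law"); an empty graph yields an empty result.
    """
    if theta_left < 1 or theta_right < 1:
        raise ValueError("side-size thresholds must be >= 1")
    out = [
        Biclique(left=a, right=b)
        for a, b in _all_maximal_bicliques(g)
        if len(a) >= theta_left and len(b) >= theta_right
    ]
    return tuple(sorted(out, key=lambda bc: canonical_key((bc.left, bc.right))))


def bicliques_to_records(bicliques: Iterable[Biclique]) -> list[dict]:
    """JSON-friendly rendering with sorted vertex lists."""
    recs = []
    for bc in bicliques:
        recs.append(
            {
                "left": sorted(bc.left, key=canonical_key),
                "right": sorted(bc.right, key=canonical_key),
            }
        )
    return recs
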