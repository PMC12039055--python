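"""Partial-order aggregation of isolated tissue effects into DAGs.

For a gene, every sub-dataset containing at least two of its tissues
contributes pairwise orderings of the fitted tissue coefficients (the
reference tissue sits at zero): an edge u -> v records that the isolated
tissue effect of u is smaller than that of v.  The union of these edges
across sub-datasets is a directed graph over tissues; if it is acyclic the
tissue effects admit a consistent partial order, and when the topological
order is additionally unique the gene has a total-order chain, printed
largest-effect first ("SCAT > BAT > GAT > MAT" style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx


def pairwise_orders(tissue_effects: Mapping[str, float]) -> frozenset[tuple[str, str]]:
    """All ordered pairs (u, v) with effect(u) < effect(v).

    Exact ties emit no edge; a single-tissue mapping yields an empty set.
    """
    items = sorted(tissue_effects.items())
    out = set()
    for i, (u, eu) in enumerate(items):
        for v, ev in items:
            if eu < ev:
                out.add((u, v))
    return frozenset(out)


@dataclass
class EffectDAG:
    """Union of per-sub-dataset coefficient orderings over tissue nodes."""

    graph: nx.DiGraph
    acyclic: bool

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def to_json(self) -> dict:
        return {"nodes": self.nodes, "edges": [list(e) for e in self.edges],
                "acyclic": self.acyclic}

    def to_dot(self, name: str = "effects") -> str:
        lines = [f'digraph "{name}" {{']
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in self.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


def build_effect_dag(
    pair_sets: Iterable[Iterable[tuple[str, str]]],
    nodes: Sequence[str] | None = None,
) -> EffectDAG:
    """Union the pairwise edges of contributing sub-datasets and decide
    acyclicity; a cyclic result is returned (acyclic=False), not an error,
    so such genes can simply be excluded from chain reporting."""
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for pairs in pair_sets:
        for u, v in pairs:
            if u == v:
                raise ValueError(f"self-ordering {u!r} -> {v!r} is not allowed")
            g.add_edge(u, v)
    return EffectDAG(graph=g, acyclic=nx.is_directed_acyclic_graph(g))


@dataclass
class OrderChain:
    """A total-order chain (largest effect first) or a partial-order report."""

    chain: tuple[str, ...] | None
    text: str
    edges: list[tuple[str, str]]

    @property
    def is_total_order(self) -> bool:
        return self.chain is not None


def extract_order_chain(dag: EffectDAG) -> OrderChain:
    """Extract the inequality chain of an acyclic effect graph.

    The topological order is unique iff every peeling step of Kahn's
    algorithm has exactly one source; then the chain is emitted as
    "T1 > T2 > ... > Tn" with the largest effect first.  Otherwise the
    partial order is reported as its edge list.  Cyclic input is an error.
    """
    if not dag.acyclic:
        raise ValueError("cannot extract an order chain from a cyclic graph")
    g = dag.graph.copy()
    order: list[str] = []
    unique = True
    while g:
        sources = sorted(n for n, d in g.in_degree() if d == 0)
        if len(sources) > 1:
            unique = False
        order.append(sources[0])
        g.remove_node(sources[0])
    if unique:
        chain = tuple(reversed(order))  # edges point small -> large
        return OrderChain(chain=chain, text=" > ".join(chain), edges=dag.edges)
    text = "; ".join(f"{v} > {u}" for u, v in dag.edges)
    return OrderChain(chain=None, text=text, edges=dag.edges)


def gene_effect_dag(
    per_subdataset_effects: Mapping[str, Mapping[str, float]],
    nodes: Sequence[str] | None = None,
) -> EffectDAG:
    """Convenience wrapper: sub-dataset name -> tissue-effect mapping."""
    return build_effect_dag(
        (pairwise_orders(effects) for effects in per_subdataset_effects.values()),
        nodes=nodes,
    )
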