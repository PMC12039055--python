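"""Shared fixtures and independent oracles for the test suite."""

from itertools import chain, combinations, product

import numpy as np
import pytest

from coser.hypergraph import DiscreteTable, Instance, table_to_hypergraph


@pytest.fixture
def eight_combo_table() -> DiscreteTable:
    """The eight-combination sex x tissue x cell-type table whose vertices
    form a single extended biclique."""
    rows = list(product(["male", "female"], ["liver", "spleen"], ["T cell", "B cell"]))
    return DiscreteTable.from_records(["sex", "tissue", "cell_type"], rows)


@pytest.fixture
def eight_combo_instance(eight_combo_table) -> Instance:
    return Instance(table_to_hypergraph(eight_combo_table), (2, 2, 2))


def powerset(iterable):
    s = list(iterable)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))


def brute_force_bicliques(left, right, edges):
    """All maximal bicliques (both sides non-empty) by exhaustive subset-pair
    search — the independent oracle for the branch-and-bound enumerator."""
    edge_set = set(edges)
    found = []
    for a in powerset(sorted(left)):
        if not a:
            continue
        for b in powerset(sorted(right)):
            if not b:
                continue
            if all((u, v) in edge_set for u in a for v in b):
                found.append((frozenset(a), frozenset(b)))
    maximal = [
        (a, b)
        for a, b in found
        if not any((a <= a2 and b <= b2 and (a, b) != (a2, b2)) for a2, b2 in found)
    ]
    return set(maximal)


def random_instances(n_instances: int, seed: int = 0, max_vertices: int = 12):
    """Random small instances (k in 2..4, n <= 12, thetas in {1, 2}) paired
    with their tables, for oracle-equivalence harnesses."""
    from coser.synthetic import random_kpartite_table

    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        k = int(rng.integers(2, 5))
        sizes = []
        budget = max_vertices
        for i in range(k):
            hi = min(4, budget - 2 * (k - i - 1))
            sizes.append(int(rng.integers(2, max(hi, 2) + 1)))
            budget -= sizes[-1]
        table = random_kpartite_table(
            sizes, float(rng.uniform(0.3, 0.9)), int(rng.integers(0, 2**31))
        )
        if not table.rows:
            continue
        hg = table_to_hypergraph(table)
        thetas = tuple(int(rng.integers(1, 3)) for _ in range(hg.k))
        out.append((table, Instance(hg, thetas)))
    return out
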