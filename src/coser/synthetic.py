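"""Synthetic study-design generators with known ground truth.

Two families of generators back the test surface:

* combinatorial — crown graphs (the worst-case biclique family: complete
  bipartite minus a perfect matching) and random k-partite combination
  tables, for exercising the enumeration against exhaustive oracles;
* statistical — cell tables with *planted* complete-combination solutions
  and a Gaussian linear expression model with planted additive categorical
  effects (and optional tissue-specific aging shifts), emulating the study
  design of a multi-tissue, multi-age mouse atlas: sexes male/female, ages
  {1, 3, 18, 21, 24, 30} months, adipose-style tissue labels.

Every generator is a pure function of its configuration and seed.  Planted
effects are attached to non-reference levels only (the lexicographically
smallest label of each attribute stays at zero), so a noise-free fit recovers
the planted values exactly as dummy-coded coefficients.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import ExpressionMatrix
from .hypergraph import DiscreteTable

DEFAULT_OLD_AGES = (18, 21, 24, 30)
DEFAULT_YOUNG_AGE = 3

#: Default planted solution, mirroring the aging-analysis study design
#: (two sexes, two adipose sub-tissues, three shared cell types, two age
#: groups) — an 24-combination complete block.
DEFAULT_SOLUTION: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "tissue": ("BAT", "SCAT"),
    "cell_type": ("BC", "EC", "MC"),
    "age_group": ("Old", "Young"),
}


def crown_graph_table(n: int, columns: tuple[str, str] = ("left", "right")) -> DiscreteTable:
    """2-column table of the crown graph: rows (a_i, b_j) for all i != j.

    Crown graphs have exponentially many maximal bicliques (2^n - 2 with
    both sides non-empty), making them the canonical stress family.
    """
    if n < 2:
        raise ValueError("a crown graph needs n >= 2")
    rows = [
        (f"a{i}", f"b{j}") for i in range(n) for j in range(n) if i != j
    ]
    return DiscreteTable.from_records(columns, rows)


def random_kpartite_table(
    sizes: Sequence[int], density: float, seed: int
) -> DiscreteTable:
    """Random k-partite combination table: each of the prod(sizes) possible
    rows is kept independently with probability ``density``."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    letters = string.ascii_uppercase
    columns = [f"attr{i + 1}" for i in range(len(sizes))]
    all_rows = list(
        product(*[[f"{letters[i % 26]}{j}" for j in range(s)] for i, s in enumerate(sizes)])
    )
    keep = rng.random(len(all_rows)) < density
    rows = [r for r, k in zip(all_rows, keep) if k]
    return DiscreteTable.from_records(columns, rows)


def bipartite_table_with_counts(
    n_left: int,
    n_right: int,
    n_edges: int,
    seed: int = 0,
    columns: tuple[str, str] = ("tissue", "cell_type"),
) -> DiscreteTable:
    """A random bipartite combination table with exact part sizes and edge
    count (every vertex covered), for reproducing atlas-level degree and
    coverage statistics from printed counts alone."""
    if n_right < n_left:
        raise ValueError("expects n_right >= n_left (more cell types than tissues)")
    if not max(n_left, n_right) <= n_edges <= n_left * n_right:
        raise ValueError("edge count incompatible with part sizes")
    rng = np.random.default_rng(seed)
    edges = {(j % n_left, j) for j in range(n_right)}  # covers both sides
    pool = [
        (i, j) for i in range(n_left) for j in range(n_right) if (i, j) not in edges
    ]
    order = rng.permutation(len(pool))
    for idx in order:
        if len(edges) == n_edges:
            break
        edges.add(pool[idx])
    rows = [(f"T{i:02d}", f"C{j:03d}") for i, j in sorted(edges)]
    return DiscreteTable.from_records(columns, rows)


@dataclass(frozen=True)
class PlantedEffect:
    """An additive shift of one gene for one attribute level."""

    gene: int
    attribute: str
    level: str
    size: float


@dataclass(frozen=True)
class PlantedAgeEffect:
    """A tissue-specific shift applied to Young cells of one tissue
    (a tissue x age interaction, the divergent-aging signal)."""

    gene: int
    tissue: str
    size: float


@dataclass
class SimulationConfig:
    """Conditions of a planted-atlas simulation.

    ``solutions`` are attribute -> label mappings; cells are generated for
    every cross-combination of every planted solution, ``cells_per_combination``
    each.  Expression is intercept + planted additive effects (+ optional
    Young-by-tissue shifts) + Gaussian noise with ``noise_sd``.
    """

    seed: int = 0
    solutions: tuple[Mapping[str, tuple[str, ...]], ...] = (DEFAULT_SOLUTION,)
    cells_per_combination: int = 200
    n_genes: int = 300
    noise_sd: float = 1.0
    intercept: float = 2.0
    effects: tuple[PlantedEffect, ...] = ()
    young_effects: tuple[PlantedAgeEffect, ...] = ()
    old_ages: tuple[int, ...] = DEFAULT_OLD_AGES
    young_age: int = DEFAULT_YOUNG_AGE
    n_individuals: int = 4
    excluded_age_cells: int = 0  # one-month distractor cells


def planted_cells_and_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ExpressionMatrix, dict]:
    """Generate (cell table, expression matrix, ground-truth registry).

    Every combination of every planted solution receives exactly
    ``cells_per_combination`` cells, so the planted solutions are guaranteed
    to survive any strict cell-count filter below that value and to appear
    among (or within) the enumerated maximal solutions of the resulting
    combination table.
    """
    if config.cells_per_combination < 1:
        raise ValueError("cells_per_combination must be >= 1")
    if not config.solutions:
        raise ValueError("at least one planted solution is required")
    rng = np.random.default_rng(config.seed)

    records: list[dict] = []
    for sol in config.solutions:
        attrs = list(sol)
        for combo in product(*(sol[a] for a in attrs)):
            for _ in range(config.cells_per_combination):
                rec = dict(zip(attrs, combo))
                records.append(rec)
    for _ in range(config.excluded_age_cells):
        sol = config.solutions[0]
        rec = {a: labs[0] for a, labs in sol.items()}
        rec["age_months"] = 1
        rec.pop("age_group", None)
        records.append(rec)

    cells = pd.DataFrame(records)
    n_cells = len(cells)
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(n_cells)])
    if "sex" not in cells.columns:
        cells["sex"] = np.where(np.arange(n_cells) % 2 == 0, "female", "male")
    if "individual" not in cells.columns:
        cells["individual"] = [f"m{i % config.n_individuals + 1}" for i in range(n_cells)]
    if "age_months" not in cells.columns:
        cells["age_months"] = config.young_age
    if "age_group" in cells.columns:
        # age_group drives the concrete month: Young -> 3, Old -> one of the
        # old study ages; one-month distractor cells keep age_months = 1
        old_pick = rng.integers(0, len(config.old_ages), size=n_cells)
        months = np.where(
            cells["age_group"].fillna("Young") == "Young",
            config.young_age,
            np.asarray(config.old_ages)[old_pick],
        )
        cells["age_months"] = months
        if config.excluded_age_cells:
            one_month = cells.index[-config.excluded_age_cells:]
            cells.loc[one_month, "age_months"] = 1
            cells.loc[one_month, "age_group"] = np.nan
    cells["age_months"] = cells["age_months"].fillna(config.young_age).astype(int)

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    values = np.full((config.n_genes, n_cells), float(config.intercept))
    for eff in config.effects:
        if eff.attribute not in cells.columns:
            raise ValueError(f"planted effect on unknown attribute {eff.attribute!r}")
        mask = (cells[eff.attribute] == eff.level).to_numpy()
        values[eff.gene, mask] += eff.size
    for eff in config.young_effects:
        mask = (
            (cells["tissue"] == eff.tissue)
            & (cells.get("age_group", pd.Series("Young", index=cells.index)) == "Young")
        ).to_numpy()
        values[eff.gene, mask] += eff.size
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    expr = ExpressionMatrix(genes=genes, cells=cells["cell_id"].tolist(), values=values)
    registry = {
        "seed": config.seed,
        "solutions": [dict((k, list(v)) for k, v in s.items()) for s in config.solutions],
        "cells_per_combination": config.cells_per_combination,
        "noise_sd": config.noise_sd,
        "intercept": config.intercept,
        "effects": [
            {"gene": genes[e.gene], "attribute": e.attribute, "level": e.level, "size": e.size}
            for e in config.effects
        ],
        "young_effects": [
            {"gene": genes[e.gene], "tissue": e.tissue, "size": e.size}
            for e in config.young_effects
        ],
        "divergent_genes": sorted(
            {
                genes[g]
                for g in {e.gene for e in config.young_effects}
                if len({np.sign(e.size) for e in config.young_effects if e.gene == g}) == 2
            }
        ),
    }
    return cells, expr, registry


def susceptible_scenario(
    n_subdatasets: int = 24,
    n_genes: int = 500,
    planted_counts: Mapping[int, int] | None = None,
    effect_size: float = 2.0,
    cells_per_combination: int = 30,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, tuple[pd.DataFrame, ExpressionMatrix]], dict]:
    """Independent sub-datasets with per-gene planted tissue effects.

    ``planted_counts`` maps gene index -> number of sub-datasets (taken in
    order) in which that gene carries a tissue effect; all other genes are
    null everywhere.  The default plants 50 genes, each affected in 13 to 24
    of 24 sub-datasets — at or above the susceptible-gene count threshold.
    """
    if planted_counts is None:
        planted_counts = {
            g: 13 + (g % (n_subdatasets - 12)) for g in range(50)
        }
    subdatasets: dict[str, tuple[pd.DataFrame, ExpressionMatrix]] = {}
    solution = {
        "individual": ("i1", "i2"),
        "tissue": ("T1", "T2"),
        "cell_type": ("C1", "C2"),
    }
    for d in range(n_subdatasets):
        effects = tuple(
            PlantedEffect(gene=g, attribute="tissue", level="T2", size=effect_size)
            for g, count in planted_counts.items()
            if d < count
        )
        cfg = SimulationConfig(
            seed=seed * 100003 + d,
            solutions=(solution,),
            cells_per_combination=cells_per_combination,
            n_genes=n_genes,
            noise_sd=noise_sd,
            effects=effects,
        )
        cells, expr, _ = planted_cells_and_expression(cfg)
        subdatasets[f"sub{d:02d}"] = (cells, expr)
    truth = {
        "planted_counts": {f"g{g:04d}": c for g, c in planted_counts.items()},
        "susceptible": sorted(f"g{g:04d}" for g, c in planted_counts.items() if c >= 13),
    }
    return subdatasets, truth


def planted_order_coefficients(
    tissues: Sequence[str],
    n_subdatasets: int = 10,
    seed: int = 0,
    min_tissues: int = 2,
    conflict: bool = False,
) -> tuple[dict[str, dict[str, float]], dict]:
    """Per-sub-dataset tissue coefficients consistent with one global order.

    Tissue i (in the given sequence) has true effect i; each sub-dataset
    observes a random subset of at least ``min_tissues`` tissues.  With
    ``conflict=True`` an extra sub-dataset is appended in which two tissues
    of the first sub-dataset have their effects swapped, injecting a direct
    order reversal that must surface as a cycle.
    """
    rng = np.random.default_rng(seed)
    true_effect = {t: float(i) for i, t in enumerate(tissues)}
    out: dict[str, dict[str, float]] = {}
    for d in range(n_subdatasets):
        size = int(rng.integers(min_tissues, len(tissues) + 1))
        picked = sorted(rng.choice(len(tissues), size=size, replace=False).tolist())
        coefs = {tissues[i]: true_effect[tissues[i]] for i in picked}
        out[f"sub{d:02d}"] = coefs
    if conflict:
        first = out[sorted(out)[0]]
        lo, hi = sorted(first, key=first.get)[:2]
        out["conflict"] = {lo: true_effect[hi], hi: true_effect[lo]}
    truth = {"order_smallest_first": list(tissues), "conflict": conflict}
    return out, truth
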