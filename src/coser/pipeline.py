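"""End-to-end pipelines: enumerate -> extract -> per-sub-dataset GLM ->
FDR -> susceptible genes -> effect DAGs, plus the aging variant.

Defaults mirror the study settings: thresholds theta_i = 2, strictly more
than 10 cells per combination for the 3-month tissue-effect analysis
(attributes individual x tissue x cell type), strictly more than 25 cells
for the aging analysis (sex x tissue x cell type x age group), FDR < 0.05,
and the susceptible-gene rule "significant in more than 12 of 24
sub-datasets" (count threshold 13).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .dag import extract_order_chain, gene_effect_dag
from .effects import (
    ExpressionMatrix,
    add_fdr,
    call_susceptible_genes,
    detect_divergent_aging,
    fit_genes,
    gene_effect_table,
)
from .enumeration import enumerate_table, solutions_to_records
from .hypergraph import Solution
from .subdataset import (
    AGING_PIPELINE_ATTRIBUTES,
    TISSUE_PIPELINE_ATTRIBUTES,
    assign_age_groups,
    build_combination_table,
    extract_subdataset,
)

log = logging.getLogger("coser")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Serializable settings of a pipeline run (defaults = study settings)."""

    attributes: tuple[str, ...] = TISSUE_PIPELINE_ATTRIBUTES
    thetas: tuple[int, ...] | None = None  # None -> 2 per attribute
    min_cells: int = 10
    fdr: float = 0.05
    min_subdatasets: int = 13
    variable: str = "tissue"
    covariates: tuple[str, ...] | None = None  # None -> attributes
    seed: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_json(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    cells: pd.DataFrame,
    expr: ExpressionMatrix | None,
    outdir: str | Path,
) -> dict:
    """The 3-month tissue-effect pipeline over one cell table.

    With ``expr=None`` only the combinatorial half (combination table and
    solution enumeration) runs.  All outputs land in ``outdir`` together
    with a machine-readable run log carrying the config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrs = tuple(config.attributes)
    covariates = tuple(config.covariates or attrs)

    table = _stage("combination_table")(build_combination_table)(
        cells, attrs, config.min_cells
    )
    log.info("combination table: %d combinations kept", table.n_rows)
    table.to_dataframe().to_csv(outdir / "combinations.csv", index=False)

    solutions = _stage("enumerate")(enumerate_table)(table, config.thetas)
    log.info("enumeration: %d maximal solutions", len(solutions))
    (outdir / "solutions.json").write_text(
        json.dumps(solutions_to_records(solutions, attrs), indent=2) + "\n"
    )

    results: dict = {
        "config_hash": config.hash(),
        "n_combinations": table.n_rows,
        "n_solutions": len(solutions),
        "solutions": solutions_to_records(solutions, attrs),
    }
    if expr is None:
        _write_run_log(config, results, outdir)
        return results

    per_sub: dict[str, pd.DataFrame] = {}
    effect_maps: dict[str, dict] = {}
    n_skipped = 0
    for i, sol in enumerate(solutions, start=1):
        name = f"solution{i}"
        sub = _stage("extract")(extract_subdataset)(cells, sol, attrs)
        sub_expr = expr.subset_cells(sub.cell_ids)
        usable = [c for c in covariates if sub.cells[c].nunique() > 1]
        tab = _stage("glm")(fit_genes)(sub_expr, sub.cells, usable)
        tab = add_fdr(tab, [c for c in usable])
        n_skipped += int(tab["zero_variance"].sum())
        header = f"# config_hash={config.hash()}\n"
        out_path = outdir / f"effects_{name}.tsv"
        with open(out_path, "w") as fh:
            fh.write(header)
            tab.to_csv(fh, sep="\t")
        per_sub[name] = tab
        if config.variable in usable:
            ref = tab.attrs["references"][config.variable]
            effect_maps[name] = {
                "reference": ref,
                "table": tab,
            }
    log.info("glm: %d sub-datasets fitted, %d zero-variance gene fits skipped",
             len(per_sub), n_skipped)

    effects = gene_effect_table(per_sub, variable=config.variable)
    susceptible = call_susceptible_genes(
        effects, min_subdatasets=config.min_subdatasets, fdr=config.fdr
    )
    log.info("susceptible genes: %d", len(susceptible))
    with open(outdir / "effects_long.tsv", "w") as fh:
        fh.write(f"# config_hash={config.hash()}\n")
        effects.to_csv(fh, sep="\t", index=False)
    pd.DataFrame({"gene": susceptible}).to_csv(
        outdir / "susceptible_genes.tsv", sep="\t", index=False
    )

    dags = {}
    for gene in susceptible:
        per_sd_effects = {}
        for name, info in effect_maps.items():
            tab = info["table"]
            prefix = f"{config.variable}["
            coefs = {info["reference"]: 0.0}
            for col in tab.columns:
                if col.startswith(prefix) and col.endswith("]"):
                    coefs[col[len(prefix):-1]] = float(tab.loc[gene, col])
            if len(coefs) >= 2:
                per_sd_effects[name] = coefs
        dag = gene_effect_dag(per_sd_effects)
        entry = {"acyclic": dag.acyclic, "edges": [list(e) for e in dag.edges]}
        if dag.acyclic:
            chain = extract_order_chain(dag)
            entry["chain"] = chain.text if chain.is_total_order else None
            entry["partial_order"] = chain.text if not chain.is_total_order else None
        dags[gene] = entry
    (outdir / "dags.json").write_text(json.dumps(dags, indent=2) + "\n")

    results.update(
        {
            "n_susceptible": len(susceptible),
            "susceptible_genes": susceptible,
            "n_dag_acyclic": sum(1 for d in dags.values() if d["acyclic"]),
            "n_dag_total_order": sum(1 for d in dags.values() if d.get("chain")),
        }
    )
    _write_run_log(config, results, outdir)
    return results


def run_aging_pipeline(
    config: PipelineConfig,
    cells: pd.DataFrame,
    expr: ExpressionMatrix,
    outdir: str | Path,
) -> dict:
    """The aging variant: age grouping, >min_cells filter over
    sex x tissue x cell type x age group, enumeration, and per-solution
    divergent-aging detection for solutions spanning exactly two tissues."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrs = tuple(config.attributes) if config.attributes != TISSUE_PIPELINE_ATTRIBUTES \
        else AGING_PIPELINE_ATTRIBUTES
    grouped = _stage("age_groups")(assign_age_groups)(cells)
    table = _stage("combination_table")(build_combination_table)(
        grouped, attrs, config.min_cells
    )
    solutions = _stage("enumerate")(enumerate_table)(table, config.thetas)
    (outdir / "solutions.json").write_text(
        json.dumps(solutions_to_records(solutions, attrs), indent=2) + "\n"
    )
    results: dict = {
        "config_hash": config.hash(),
        "n_combinations": table.n_rows,
        "n_solutions": len(solutions),
        "solutions": solutions_to_records(solutions, attrs),
        "divergent": {},
    }
    for i, sol in enumerate(solutions, start=1):
        labels = sol.labels(attrs)
        if len(labels.get("tissue", ())) != 2:
            continue
        name = f"solution{i}"
        sub = _stage("extract")(extract_subdataset)(grouped, sol, attrs)
        sub_expr = expr.subset_cells(sub.cell_ids)
        div = _stage("aging_glm")(detect_divergent_aging)(
            sub.cells, sub_expr, tissues=list(labels["tissue"]), fdr=config.fdr
        )
        with open(outdir / f"divergent_{name}.tsv", "w") as fh:
            fh.write(f"# config_hash={config.hash()}\n")
            div.to_csv(fh, sep="\t", index=False)
        results["divergent"][name] = {
            "tissues": list(labels["tissue"]),
            "n_divergent": int(div["divergent"].sum()),
            "genes": div.loc[div["divergent"], "gene"].tolist(),
        }
    _write_run_log(config, results, outdir, name="aging_run_log.json")
    return results


def _write_run_log(
    config: PipelineConfig, results: Mapping, outdir: Path, name: str = "run_log.json"
) -> None:
    import numpy
    import pandas
    import scipy

    log_payload = {
        "coser_version": __version__,
        "config": config.to_json(),
        "config_hash": config.hash(),
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
        },
        "summary": {
            k: v for k, v in results.items() if isinstance(v, (int, float, str))
        },
    }
    (outdir / name).write_text(json.dumps(log_payload, indent=2) + "\n")
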