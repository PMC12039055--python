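"""Minimal diagnostic plots: p-value QQ curves and Young-coefficient
scatter plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


def substitute_zero_pvalues(p: Sequence[float]) -> np.ndarray:
    """Replace exact zeros with the minimum non-zero p-value of the set.

    Only the log-scale QQ display uses this substitution; result tables keep
    zeros as reported.
    """
    arr = np.asarray(p, dtype=float)
    arr = arr[~np.isnan(arr)]
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        return arr
    return np.where(arr == 0, nonzero.min(), arr)


def qq_plot(pvalue_sets: Mapping[str, Sequence[float]], path: str | Path | None = None):
    """QQ plot of observed vs uniform -log10 p-values, one curve per set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    top = 1.0
    for name, p in pvalue_sets.items():
        obs = np.sort(substitute_zero_pvalues(p))
        if obs.size == 0:
            continue
        exp = (np.arange(1, obs.size + 1) - 0.5) / obs.size
        x, y = -np.log10(exp), -np.log10(obs)
        ax.plot(x, y, lw=1, label=name)
        top = max(top, x.max(), y.max())
    ax.plot([0, top], [0, top], color="grey", ls="--", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} P$")
    ax.set_ylabel(r"observed $-\log_{10} P$")
    if len(pvalue_sets) <= 10:
        ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def young_coefficient_scatter(
    divergent_table, tissues: Sequence[str], path: str | Path | None = None
):
    """Scatter of per-tissue Young coefficients; divergent genes coloured by
    which axis carries the positive coefficient."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t1, t2 = tissues
    x = divergent_table[f"coef_{t1}"]
    y = divergent_table[f"coef_{t2}"]
    flag = divergent_table["divergent"]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x[~flag], y[~flag], s=6, color="grey", alpha=0.5)
    ax.scatter(x[flag & (x > 0)], y[flag & (x > 0)], s=10, color="red")
    ax.scatter(x[flag & (y > 0)], y[flag & (y > 0)], s=10, color="blue")
    ax.axhline(0, color="black", lw=0.5)
    ax.axvline(0, color="black", lw=0.5)
    ax.set_xlabel(f"Young coefficient ({t1})")
    ax.set_ylabel(f"Young coefficient ({t2})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
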