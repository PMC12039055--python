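"""Per-gene Gaussian linear models with Type II ANOVA over sub-datasets.

Within each sub-dataset the model for a gene is

    y_i = intercept + b_sex * sex_i + b_tissue * tissue_i
          + b_celltype * celltype_i (+ further categorical terms) + error,

with Gaussian error and dummy-coded categorical covariates (reference level =
lexicographically smallest label, so each coefficient is the isolated effect
of its level relative to the reference).  Because the design matrix is shared
by every gene of a sub-dataset, fitting is vectorized: one least-squares
solve per model, all genes at once.  Per-variable significance uses Type II
ANOVA, which with main effects only is the drop-one-term F test — the full
model against the model with that variable's columns removed, all other
terms retained.

The module also houses the Benjamini-Hochberg FDR adjustment (applied per
sub-dataset, per variable, across genes), the tissue-environment-susceptible
gene rule (significant tissue effect in strictly more than half of the
analysed sub-datasets), and the divergent-aging detector (opposite-sign
"Young" coefficients, both significant, in two tissues of one solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Relative tolerance deciding when a residual sum of squares is "zero"
#: (noise-free or constant data); scaled by the response magnitude.
_RSS_TOL = 1e-10


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of log-transformed expression values."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise KeyError(f"cell id(s) not in expression matrix: {missing[:5]}")
        cols = [index[c] for c in cell_ids]
        return ExpressionMatrix(
            genes=list(self.genes), cells=list(cell_ids), values=self.values[:, cols]
        )

    def gene_vector(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None


@dataclass(frozen=True)
class DesignInfo:
    """Dummy-coded design matrix plus bookkeeping for term tests."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    terms: dict[str, tuple[int, ...]]  # covariate -> column indices
    references: dict[str, str]  # covariate -> dropped (reference) level
    intercept: bool


def build_design(
    meta: pd.DataFrame, covariates: Sequence[str], intercept: bool = True
) -> DesignInfo:
    """Dummy-code categorical covariates, dropping the lexicographically
    smallest level of each as the reference."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    terms: dict[str, tuple[int, ...]] = {}
    refs: dict[str, str] = {}
    if intercept:
        cols.append(np.ones(len(meta)))
        names.append("Intercept")
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        levels = sorted(meta[cov].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has fewer than two levels")
        refs[cov] = levels[0]
        idx = []
        values = meta[cov].astype(str).to_numpy()
        for level in levels[1:]:
            idx.append(len(names))
            cols.append((values == level).astype(float))
            names.append(f"{cov}[{level}]")
        terms[cov] = tuple(idx)
    X = np.column_stack(cols)
    return DesignInfo(
        matrix=X,
        columns=tuple(names),
        terms=terms,
        references=refs,
        intercept=intercept,
    )


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of every row of Y (genes x cells) on X; returns
    (coefficients p x G, residual sum of squares per gene)."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return beta, np.einsum("ij,ij->j", resid, resid)


@dataclass
class TermTest:
    """One Type II (drop-one-term) F test."""

    F: float
    df_num: int
    df_den: int
    pvalue: float
    flagged: bool = False
    note: str = ""


@dataclass
class GLMFit:
    """A single-gene Gaussian GLM fit."""

    design: DesignInfo
    y: np.ndarray
    coefficients: dict[str, float]
    rss: float
    df_resid: int
    residual_var: float
    ok: bool
    zero_variance: bool

    def tissue_effects(self, covariate: str = "tissue") -> dict[str, float]:
        """Per-level effects with the reference level pinned at zero."""
        ref = self.design.references[covariate]
        out = {ref: 0.0}
        prefix = f"{covariate}["
        for name, value in self.coefficients.items():
            if name.startswith(prefix):
                out[name[len(prefix):-1]] = value
        return out


def fit_gaussian_glm(
    y: np.ndarray,
    meta: pd.DataFrame,
    covariates: Sequence[str],
    intercept: bool = True,
) -> GLMFit:
    """Ordinary-least-squares fit of one gene's expression on dummy-coded
    categorical covariates.

    A rank-deficient design marks the fit as not OK (coefficients NaN) rather
    than silently returning one of many solutions; a constant response yields
    zero non-intercept coefficients and zero residual variance, with the
    zero-variance flag set so downstream p-values can be reported as
    undefined.
    """
    y = np.asarray(y, dtype=float)
    design = build_design(meta, covariates, intercept=intercept)
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more cells ({n}) than fitted parameters ({p})")
    ok = np.linalg.matrix_rank(X) == p
    if not ok:
        coefs = {name: float("nan") for name in design.columns}
        return GLMFit(design, y, coefs, float("nan"), n - p, float("nan"), False, False)
    beta, rss = _ols(X, y[None, :])
    coefs = {name: float(b) for name, b in zip(design.columns, beta[:, 0])}
    df_resid = n - p
    return GLMFit(
        design=design,
        y=y,
        coefficients=coefs,
        rss=float(rss[0]),
        df_resid=df_resid,
        residual_var=float(rss[0] / df_resid),
        ok=True,
        zero_variance=bool(np.ptp(y) == 0),
    )


def type2_anova(fit: GLMFit) -> dict[str, TermTest]:
    """Type II ANOVA: per covariate, F test of the full model against the
    model with that covariate's columns dropped (other main effects kept).

    In the noise-free limit (zero full-model residual but a real RSS change)
    the F statistic diverges and the p-value is reported as exactly 0; a
    constant response makes the test undefined and the term is flagged.
    """
    if not fit.ok:
        raise ValueError("cannot run ANOVA on a rank-deficient fit")
    X = fit.design.matrix
    n, p = X.shape
    scale = 1.0 + float(np.mean(fit.y**2))
    out: dict[str, TermTest] = {}
    for cov, idx in fit.design.terms.items():
        keep = [j for j in range(p) if j not in idx]
        X_red = X[:, keep]
        if X_red.size and np.linalg.matrix_rank(X_red) < len(keep):
            out[cov] = TermTest(
                float("nan"), len(idx), fit.df_resid, float("nan"),
                flagged=True, note="reduced model rank-deficient",
            )
            continue
        _, rss_red = _ols(X_red, fit.y[None, :]) if keep else (None, np.array([float(fit.y @ fit.y)]))
        num = max(float(rss_red[0]) - fit.rss, 0.0) / len(idx)
        den = fit.rss / fit.df_resid
        tol = _RSS_TOL * scale
        if den <= tol:
            if num > tol:
                out[cov] = TermTest(float("inf"), len(idx), fit.df_resid, 0.0)
            else:
                out[cov] = TermTest(
                    float("nan"), len(idx), fit.df_resid, float("nan"),
                    flagged=True, note="zero residual and zero effect (constant response)",
                )
            continue
        F = num / den
        out[cov] = TermTest(
            F, len(idx), fit.df_resid, float(stats.f.sf(F, len(idx), fit.df_resid))
        )
    return out


def fit_genes(
    Y: np.ndarray | ExpressionMatrix,
    meta: pd.DataFrame,
    covariates: Sequence[str],
    intercept: bool = True,
) -> pd.DataFrame:
    """Fit every gene of a sub-dataset at once and run Type II ANOVA.

    Returns a DataFrame indexed by gene with one column per design
    coefficient plus, per covariate, ``F_<cov>`` and ``pvalue_<cov>``, and
    the flags ``ok`` and ``zero_variance``.  Genes with zero variance within
    the sub-dataset get undefined p-values (NaN) and are flagged, not
    failed.  Reference levels are recorded in ``DataFrame.attrs``.
    """
    if isinstance(Y, ExpressionMatrix):
        genes = Y.genes
        values = Y.values
    else:
        values = np.asarray(Y, dtype=float)
        genes = [f"g{i}" for i in range(values.shape[0])]
    design = build_design(meta, covariates, intercept=intercept)
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more cells ({n}) than fitted parameters ({p})")
    if values.shape[1] != n:
        raise ValueError(
            f"expression has {values.shape[1]} cells but metadata has {n} rows"
        )
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    full_rank = np.linalg.matrix_rank(X) == p
    zero_var = np.ptp(values, axis=1) == 0
    table["ok"] = full_rank
    table["zero_variance"] = zero_var
    if not full_rank:
        for name in design.columns:
            table[name] = np.nan
        for cov in covariates:
            table[f"F_{cov}"] = np.nan
            table[f"pvalue_{cov}"] = np.nan
        table.attrs["references"] = design.references
        table.attrs["rank_deficient"] = True
        return table

    beta, rss_full = _ols(X, values)
    for j, name in enumerate(design.columns):
        table[name] = beta[j]
    df_resid = n - p
    scale = 1.0 + np.mean(values**2, axis=1)
    den = rss_full / df_resid
    tiny_den = den <= _RSS_TOL * scale
    for cov in covariates:
        idx = design.terms[cov]
        keep = [j for j in range(p) if j not in idx]
        _, rss_red = _ols(X[:, keep], values)
        num = np.maximum(rss_red - rss_full, 0.0) / len(idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = num / den
        pvals = stats.f.sf(F, len(idx), df_resid)
        # noise-free with a real effect -> p = 0; constant response -> NaN
        pvals = np.where(tiny_den & (num > _RSS_TOL * scale), 0.0, pvals)
        pvals = np.where(tiny_den & (num <= _RSS_TOL * scale), np.nan, pvals)
        pvals = np.where(zero_var, np.nan, pvals)
        table[f"F_{cov}"] = F
        table[f"pvalue_{cov}"] = pvals
    table.attrs["references"] = design.references
    table.attrs["rank_deficient"] = False
    return table


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Values must lie in [0, 1]; NaNs (undefined tests) are passed through and
    excluded from the adjustment, matching R's ``p.adjust`` behaviour.
    """
    arr = np.asarray(p, dtype=float)
    finite = ~np.isnan(arr)
    if ((arr[finite] < 0) | (arr[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(arr[finite], method="fdr_bh")[1]
    return out


def add_fdr(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Add per-covariate BH-adjusted columns (``fdr_<cov>``) across genes."""
    out = table.copy()
    for cov in covariates:
        out[f"fdr_{cov}"] = bh_fdr(out[f"pvalue_{cov}"].to_numpy())
    out.attrs.update(table.attrs)
    return out


def gene_effect_table(
    per_subdataset: Mapping[str, pd.DataFrame], variable: str = "tissue"
) -> pd.DataFrame:
    """Tidy one-row-per-(gene, sub-dataset) table of a variable's p/FDR."""
    frames = []
    for name, tab in per_subdataset.items():
        f = pd.DataFrame(
            {
                "gene": tab.index,
                "subdataset": name,
                "pvalue": tab[f"pvalue_{variable}"].to_numpy(),
                "fdr": tab[f"fdr_{variable}"].to_numpy(),
            }
        )
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def call_susceptible_genes(
    effects: pd.DataFrame, min_subdatasets: int = 13, fdr: float = 0.05
) -> list[str]:
    """Genes significant (FDR < threshold) in at least ``min_subdatasets``
    sub-datasets — the default 13 encodes "more than 12 of the 24"."""
    if effects.empty:
        return []
    sig = effects[effects["fdr"] < fdr]
    counts = sig.groupby("gene").size()
    return sorted(counts[counts >= min_subdatasets].index.tolist())


def detect_divergent_aging(
    cells: pd.DataFrame,
    expr: ExpressionMatrix,
    tissues: Sequence[str] | None = None,
    fdr: float = 0.05,
    extra_covariates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Find genes whose "Young" age coefficient is significant with opposite
    signs in the two tissues of a sub-dataset.

    Per tissue, each gene's expression is regressed on the age group (plus
    sex and cell type when they vary within that tissue's cells, unless an
    explicit covariate list is given); "Old" is the reference level so the
    Young coefficient is the young-vs-old shift.  FDR is computed per tissue
    across genes.  A tissue whose cells carry a single age group is an error.
    """
    if "age_group" not in cells.columns:
        raise ValueError("cells need an age_group column (run assign_age_groups)")
    if tissues is None:
        tissues = sorted(cells["tissue"].unique())
    if len(tissues) != 2:
        raise ValueError(
            f"divergent-aging comparison needs exactly two tissues, got {list(tissues)}"
        )
    per_tissue: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        sub = cells[cells["tissue"] == tissue]
        if sub.empty:
            raise ValueError(f"no cells for tissue {tissue!r}")
        if sub["age_group"].nunique() < 2:
            raise ValueError(f"tissue {tissue!r} has a single age group")
        if extra_covariates is None:
            covs = ["age_group"] + [
                c for c in ("sex", "cell_type") if sub[c].nunique() > 1
            ]
        else:
            covs = ["age_group"] + [c for c in extra_covariates if sub[c].nunique() > 1]
        sub_expr = expr.subset_cells(sub["cell_id"].tolist())
        tab = fit_genes(sub_expr, sub, covs)
        tab = add_fdr(tab, ["age_group"])
        per_tissue[tissue] = tab
    t1, t2 = tissues
    young = "age_group[Young]"
    out = pd.DataFrame(
        {
            "gene": per_tissue[t1].index,
            f"coef_{t1}": per_tissue[t1][young].to_numpy(),
            f"pvalue_{t1}": per_tissue[t1]["pvalue_age_group"].to_numpy(),
            f"fdr_{t1}": per_tissue[t1]["fdr_age_group"].to_numpy(),
            f"coef_{t2}": per_tissue[t2][young].to_numpy(),
            f"pvalue_{t2}": per_tissue[t2]["pvalue_age_group"].to_numpy(),
            f"fdr_{t2}": per_tissue[t2]["fdr_age_group"].to_numpy(),
        }
    )
    opposite = out[f"coef_{t1}"] * out[f"coef_{t2}"] < 0
    significant = (out[f"fdr_{t1}"] < fdr) & (out[f"fdr_{t2}"] < fdr)
    out["divergent"] = (opposite & significant).fillna(False)
    return out
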