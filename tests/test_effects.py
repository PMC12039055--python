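"""GLM fitting, Type II ANOVA, FDR, susceptible-gene and divergent-aging
rules — checked against hand computation, statsmodels, and planted truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coser.effects import (
    add_fdr,
    bh_fdr,
    call_susceptible_genes,
    detect_divergent_aging,
    fit_gaussian_glm,
    fit_genes,
    gene_effect_table,
    type2_anova,
)
from coser.subdataset import assign_age_groups
from coser.synthetic import (
    PlantedAgeEffect,
    PlantedEffect,
    SimulationConfig,
    planted_cells_and_expression,
    susceptible_scenario,
)


def toy_meta(n_per=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for tissue in ("liver", "spleen"):
        for ct in ("B", "T"):
            for sex in ("female", "male"):
                for _ in range(n_per):
                    rows.append({"tissue": tissue, "cell_type": ct, "sex": sex})
    df = pd.DataFrame(rows)
    df["cell_id"] = [f"c{i}" for i in range(len(df))]
    return df, rng


class TestFitGaussianGLM:
    def test_constant_response_degenerate_fit(self):
        meta, _ = toy_meta()
        fit = fit_gaussian_glm(np.full(len(meta), 3.0), meta, ["tissue", "cell_type"])
        assert fit.zero_variance
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        for name, value in fit.coefficients.items():
            if name != "Intercept":
                assert value == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_recovery_is_exact(self):
        meta, _ = toy_meta()
        y = (
            1.0
            + 0.7 * (meta["tissue"] == "spleen")
            - 0.3 * (meta["cell_type"] == "T")
            + 0.2 * (meta["sex"] == "male")
        ).to_numpy()
        fit = fit_gaussian_glm(y, meta, ["sex", "tissue", "cell_type"])
        assert fit.coefficients["tissue[spleen]"] == pytest.approx(0.7, abs=1e-10)
        assert fit.coefficients["cell_type[T]"] == pytest.approx(-0.3, abs=1e-10)
        assert fit.coefficients["sex[male]"] == pytest.approx(0.2, abs=1e-10)
        assert fit.coefficients["Intercept"] == pytest.approx(1.0, abs=1e-10)

    def test_reference_level_is_lexicographically_smallest(self):
        meta, _ = toy_meta()
        fit = fit_gaussian_glm(np.zeros(len(meta)), meta, ["tissue", "sex"])
        assert fit.design.references == {"tissue": "liver", "sex": "female"}

    def test_noisy_estimates_near_truth(self):
        # planted coefficient within 3 SE in the vast majority of replicates
        meta, _ = toy_meta(n_per=25)
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            y = (0.5 * (meta["tissue"] == "spleen")).to_numpy() + rng.normal(
                0, 1, len(meta)
            )
            fit = fit_gaussian_glm(y, meta, ["tissue", "cell_type"])
            # standard error of a balanced two-group contrast
            se = np.sqrt(fit.residual_var * 4 / len(meta))
            if abs(fit.coefficients["tissue[spleen]"] - 0.5) < 3 * se:
                hits += 1
        assert hits >= 96

    def test_rank_deficient_design_is_flagged(self):
        # tissue and cell type perfectly aliased -> no isolated effects
        meta = pd.DataFrame(
            {
                "tissue": ["a", "a", "b", "b"] * 3,
                "cell_type": ["x", "x", "y", "y"] * 3,
            }
        )
        fit = fit_gaussian_glm(np.arange(12.0), meta, ["tissue", "cell_type"])
        assert not fit.ok
        with pytest.raises(ValueError):
            type2_anova(fit)


class TestTypeIIAnova:
    def test_matches_statsmodels_type2(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        meta, rng = toy_meta(n_per=6, seed=7)
        y = (
            0.9 * (meta["tissue"] == "spleen")
            - 0.4 * (meta["cell_type"] == "T")
            + rng.normal(0, 1, len(meta))
        ).to_numpy()
        fit = fit_gaussian_glm(y, meta, ["sex", "tissue", "cell_type"])
        mine = type2_anova(fit)

        df = meta.assign(y=y)
        model = ols("y ~ C(sex) + C(tissue) + C(cell_type)", data=df).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        for cov, term in [("sex", "C(sex)"), ("tissue", "C(tissue)"),
                          ("cell_type", "C(cell_type)")]:
            assert mine[cov].F == pytest.approx(ref.loc[term, "F"], rel=1e-8)
            assert mine[cov].pvalue == pytest.approx(ref.loc[term, "PR(>F)"], rel=1e-8)
        # coefficients agree too (same dummy coding, first level dropped)
        assert fit.coefficients["tissue[spleen]"] == pytest.approx(
            model.params["C(tissue)[T.spleen]"], rel=1e-10
        )

    def test_f_statistic_equals_explicit_two_model_ratio(self):
        # balanced 2x2 toy with integer response, computed by two explicit fits
        meta = pd.DataFrame(
            {
                "tissue": ["a", "a", "b", "b"] * 3,
                "cell_type": ["x", "y", "x", "y"] * 3,
            }
        )
        y = np.array([1, 2, 4, 5, 2, 1, 5, 4, 1, 3, 4, 6], dtype=float)
        fit = fit_gaussian_glm(y, meta, ["tissue", "cell_type"])
        mine = type2_anova(fit)["tissue"]

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        ones = np.ones(len(y))
        t = (meta["tissue"] == "b").to_numpy(float)
        c = (meta["cell_type"] == "y").to_numpy(float)
        rss_full = rss(np.column_stack([ones, t, c]))
        rss_red = rss(np.column_stack([ones, c]))
        expected_f = ((rss_red - rss_full) / 1) / (rss_full / (len(y) - 3))
        assert mine.F == pytest.approx(expected_f, rel=1e-10)
        assert mine.pvalue == pytest.approx(
            stats.f.sf(expected_f, 1, len(y) - 3), rel=1e-10
        )

    def test_noise_free_effect_gives_zero_pvalue(self):
        meta, _ = toy_meta()
        y = (2.0 * (meta["tissue"] == "spleen")).to_numpy()
        fit = fit_gaussian_glm(y, meta, ["tissue", "cell_type"])
        res = type2_anova(fit)
        assert res["tissue"].pvalue == 0.0
        assert res["cell_type"].flagged or np.isnan(res["cell_type"].pvalue)

    def test_null_pvalues_uniform(self):
        # global null across many genes: KS does not reject uniformity
        cfg = SimulationConfig(
            seed=8,
            solutions=(
                {"individual": ("i1", "i2"), "tissue": ("T1", "T2"),
                 "cell_type": ("C1", "C2")},
            ),
            cells_per_combination=20,
            n_genes=2000,
            noise_sd=1.0,
        )
        cells, expr, _ = planted_cells_and_expression(cfg)
        tab = fit_genes(expr, cells, ["individual", "tissue", "cell_type"])
        for cov in ("tissue", "cell_type"):
            ks = stats.kstest(tab[f"pvalue_{cov}"], "uniform")
            assert ks.pvalue > 0.01

    def test_power_increases_with_effect_size(self):
        powers = []
        for size_idx, size in enumerate((0.2, 0.5, 1.0)):
            cfg = SimulationConfig(
                seed=9,  # same draw per effect size; only the signal moves
                solutions=(
                    {"tissue": ("T1", "T2"), "cell_type": ("C1", "C2")},
                ),
                cells_per_combination=13,
                n_genes=300,
                noise_sd=1.0,
                effects=tuple(
                    PlantedEffect(g, "tissue", "T2", size) for g in range(300)
                ),
            )
            cells, expr, _ = planted_cells_and_expression(cfg)
            tab = fit_genes(expr, cells, ["tissue", "cell_type"])
            powers.append(float((tab["pvalue_tissue"] < 0.05).mean()))
        assert powers[0] < powers[1] < powers[2]

    def test_vectorized_fit_matches_single_gene_path(self):
        meta, rng = toy_meta(n_per=4, seed=13)
        Y = rng.normal(0, 1, (5, len(meta)))
        tab = fit_genes(Y, meta, ["tissue", "cell_type"])
        for i in range(5):
            fit = fit_gaussian_glm(Y[i], meta, ["tissue", "cell_type"])
            res = type2_anova(fit)
            assert tab.iloc[i]["tissue[spleen]"] == pytest.approx(
                fit.coefficients["tissue[spleen]"], rel=1e-10
            )
            assert tab.iloc[i]["pvalue_tissue"] == pytest.approx(
                res["tissue"].pvalue, rel=1e-8
            )


class TestBHFDR:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_ties_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_nan_passthrough(self):
        out = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=40)
    )
    @settings(deadline=None, max_examples=100)
    def test_agrees_with_explicit_step_up_oracle(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(bh_fdr(p), adj)
        # adjusted values never fall below raw p-values
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestSusceptibleGenes:
    def test_thirteen_of_24_called_twelve_not(self):
        records = []
        for d in range(24):
            records.append({"gene": "g13", "subdataset": f"s{d}",
                            "pvalue": 0.001, "fdr": 0.01 if d < 13 else 0.9})
            records.append({"gene": "g12", "subdataset": f"s{d}",
                            "pvalue": 0.001, "fdr": 0.01 if d < 12 else 0.9})
        effects = pd.DataFrame(records)
        assert call_susceptible_genes(effects) == ["g13"]

    def test_no_significant_genes(self):
        effects = pd.DataFrame(
            [{"gene": "g", "subdataset": "s", "pvalue": 0.5, "fdr": 0.9}]
        )
        assert call_susceptible_genes(effects) == []

    def test_noise_free_boundary_is_deterministic(self):
        subs, truth = susceptible_scenario(
            n_subdatasets=24, n_genes=6,
            planted_counts={0: 13, 1: 12, 2: 24},
            noise_sd=0.0, cells_per_combination=4, seed=17,
        )
        per = {}
        for name, (cells, expr) in subs.items():
            tab = fit_genes(expr, cells, ["individual", "tissue", "cell_type"])
            per[name] = add_fdr(tab, ["tissue"])
        called = call_susceptible_genes(gene_effect_table(per))
        assert called == ["g0000", "g0002"]  # 13 and 24 in; exactly 12 out

    def test_planted_atlas_recovered_exactly(self):
        subs, truth = susceptible_scenario(n_genes=200, seed=19)
        per = {}
        for name, (cells, expr) in subs.items():
            tab = fit_genes(expr, cells, ["individual", "tissue", "cell_type"])
            per[name] = add_fdr(tab, ["tissue"])
        called = call_susceptible_genes(gene_effect_table(per))
        assert called == truth["susceptible"]


class TestDivergentAging:
    def make_divergent(self, seed=23, n_genes=300, n_div=20, cells_per=200):
        young = tuple(
            [PlantedAgeEffect(g, "BAT", +0.8) for g in range(n_div)]
            + [PlantedAgeEffect(g, "SCAT", -0.5) for g in range(n_div)]
        )
        cfg = SimulationConfig(
            seed=seed, cells_per_combination=cells_per, n_genes=n_genes,
            noise_sd=1.0, young_effects=young,
        )
        cells, expr, truth = planted_cells_and_expression(cfg)
        grouped = assign_age_groups(cells)
        return grouped, expr.subset_cells(grouped["cell_id"].tolist()), truth

    def test_planted_opposite_sign_genes_recovered_exactly(self):
        cells, expr, truth = self.make_divergent()
        div = detect_divergent_aging(cells, expr, tissues=["BAT", "SCAT"])
        got = sorted(div.loc[div["divergent"], "gene"])
        assert got == truth["divergent_genes"]

    def test_same_sign_not_flagged(self):
        young = tuple(
            [PlantedAgeEffect(0, "BAT", +0.8), PlantedAgeEffect(0, "SCAT", +0.5)]
        )
        cfg = SimulationConfig(seed=29, cells_per_combination=100, n_genes=5,
                               noise_sd=0.5, young_effects=young)
        cells, expr, _ = planted_cells_and_expression(cfg)
        grouped = assign_age_groups(cells)
        div = detect_divergent_aging(
            grouped, expr.subset_cells(grouped["cell_id"].tolist()),
            tissues=["BAT", "SCAT"],
        )
        assert not div["divergent"].any()

    def test_single_age_group_tissue_is_an_error(self):
        cells, expr, _ = self.make_divergent(cells_per=5, n_genes=2, n_div=0)
        young_only = cells[cells["age_group"] == "Young"]
        with pytest.raises(ValueError, match="single age group"):
            detect_divergent_aging(
                young_only, expr.subset_cells(young_only["cell_id"].tolist()),
                tissues=["BAT", "SCAT"],
            )
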