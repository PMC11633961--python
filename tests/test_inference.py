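"""Mixed-model engine: REML fits, Satterthwaite tests, Tukey, phylogenetic
species model, and the nutrient x climate interaction model."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gscover.climate import zscore_columns
from gscover.inference import (
    ModelSpec,
    CLIMATE_ANOVA_LABELS,
    build_design,
    fit_lmm,
    fit_phylo_mixed,
    run_climate_interaction_model,
    treatment_cell,
    tukey_hsd,
)
from gscover.synthetic import SyntheticConfig, simulate_dataset


def _factorial_data(seed, n_effect=0.0, site_sd=0.1, block_sd=0.05,
                    noise=0.2, n_sites=12, blocks=3):
    rng = np.random.default_rng(seed)
    rows = []
    for site in range(n_sites):
        se = rng.normal(0, site_sd)
        for blk in range(blocks):
            be = rng.normal(0, block_sd)
            for trt in range(4):
                n = int(trt in (1, 3))
                p = int(trt in (2, 3))
                rows.append(
                    {"site": f"s{site:02d}", "block": f"b{blk}",
                     "n_added": n, "p_added": p,
                     "lrr": n_effect * n + se + be + rng.normal(0, noise)}
                )
    return pd.DataFrame(rows)


SPEC_NP = ModelSpec(
    "lrr", ["n_added", "p_added", "n_added:p_added"], ["site", "site:block"]
)


class TestDesign:
    def test_interaction_and_categorical_expansion(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "g": ["a", "b", "a", "b"]}
        )
        X, names, term_map, cat_levels = build_design(df, ["x", "g", "x:g"])
        assert names == ["(intercept)", "x", "g[b]", "x:g[b]"]
        np.testing.assert_allclose(X[:, 3], [0.0, 2.0, 0.0, 4.0])
        assert cat_levels["g"] == ["a", "b"]

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="aliased"):
            build_design(df, ["x", "y"])

    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing column"):
            build_design(pd.DataFrame({"x": [1.0]}), ["z"])

    def test_treatment_cell(self):
        df = pd.DataFrame({"n_added": [0, 1, 0, 1], "p_added": [0, 0, 1, 1]})
        assert list(treatment_cell(df)) == ["control", "N", "P", "NP"]


class TestFitLMM:
    def test_zero_variance_limit_equals_ols(self):
        df = _factorial_data(1, n_effect=0.4, site_sd=0.0, block_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(SPEC_NP, df)
        X = np.column_stack(
            [np.ones(len(df)), df.n_added, df.p_added, df.n_added * df.p_added]
        )
        beta, *_ = np.linalg.lstsq(X, df["lrr"].to_numpy(), rcond=None)
        np.testing.assert_allclose(
            fit.params["estimate"].to_numpy(), beta, atol=1e-6
        )

    def test_effect_recovery(self):
        ests = []
        for s in range(100):
            fit = fit_lmm(SPEC_NP, _factorial_data(100 + s, n_effect=0.3))
            ests.append(fit.params.loc["n_added", "estimate"])
        assert np.mean(ests) == pytest.approx(0.3, abs=0.05)

    def test_null_type_one_error(self):
        rej = 0
        N = 400
        for s in range(N):
            fit = fit_lmm(SPEC_NP, _factorial_data(10_000 + s))
            rej += fit.anova.loc["n_added", "p"] < 0.05
        assert 0.025 <= rej / N <= 0.075

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _factorial_data(7, n_effect=0.5, site_sd=0.3, block_sd=0.2,
                             noise=0.4, n_sites=10)
        fit = fit_lmm(ModelSpec("lrr", ["n_added"], ["site", "site:block"]), df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(
                "lrr ~ n_added", df, groups=df["site"],
                re_formula="1", vc_formula={"blk": "0 + C(block)"},
            ).fit(reml=True)
        assert fit.params.loc["n_added", "estimate"] == pytest.approx(
            m.params["n_added"], abs=1e-5
        )
        assert fit.params.loc["n_added", "se"] == pytest.approx(
            m.bse["n_added"], rel=0.1
        )

    def test_reml_optimum_beats_grid(self):
        df = _factorial_data(3, n_effect=0.2, site_sd=0.3)
        fit = fit_lmm(ModelSpec("lrr", ["n_added"], ["site"]), df)
        eng = fit._engine
        best = eng._neg2_profile(eng.log_gammas)
        for ratio in (0.01, 0.1, 1.0, 10.0):
            assert best <= eng._neg2_profile(np.log([ratio])) + 1e-6

    def test_deterministic_refit(self):
        df = _factorial_data(5, n_effect=0.2)
        f1 = fit_lmm(SPEC_NP, df)
        f2 = fit_lmm(SPEC_NP, df)
        pd.testing.assert_frame_equal(f1.params, f2.params)
        pd.testing.assert_frame_equal(f1.anova, f2.anova)

    def test_marginal_r2_bounds_and_varcomps(self):
        df = _factorial_data(9, n_effect=0.5)
        fit = fit_lmm(SPEC_NP, df)
        assert 0.0 <= fit.marginal_r2 <= 1.0
        assert (fit.varcomps >= 0).all()
        assert set(fit.varcomps.index) == {"site", "site:block", "residual"}


class TestTukey:
    def test_identical_means_share_a_letter(self):
        df = _factorial_data(21, n_effect=0.0, noise=0.05)
        df["treatment"] = treatment_cell(df)
        fit = fit_lmm(
            ModelSpec("lrr", ["treatment"], ["site", "site:block"]), df
        )
        tk = tukey_hsd(fit, "treatment")
        assert len(set(tk.letters.values())) == 1

    def test_shifted_group_gets_unique_letter(self):
        df = _factorial_data(22, n_effect=0.0, noise=0.05, site_sd=0.0,
                             block_sd=0.0)
        df.loc[(df.n_added == 1) & (df.p_added == 1), "lrr"] += 10 * 0.05
        df["treatment"] = treatment_cell(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(
                ModelSpec("lrr", ["treatment"], ["site", "site:block"]), df
            )
        tk = tukey_hsd(fit, "treatment")
        np_letters = tk.letters["NP"]
        others = {lev: s for lev, s in tk.letters.items() if lev != "NP"}
        assert all(set(np_letters).isdisjoint(set(s)) for s in others.values())

    def test_adjusted_p_not_smaller_than_unadjusted(self):
        df = _factorial_data(23, n_effect=0.1)
        df["treatment"] = treatment_cell(df)
        fit = fit_lmm(
            ModelSpec("lrr", ["treatment"], ["site", "site:block"]), df
        )
        tk = tukey_hsd(fit, "treatment")
        for r in tk.contrasts.itertuples():
            unadj = 2 * stats.t.sf(abs(r.diff) / r.se, r.df)
            assert r.p_adj >= unadj - 1e-12

    def test_letters_consistent_with_significance(self):
        df = _factorial_data(24, n_effect=0.6, noise=0.15)
        df["treatment"] = treatment_cell(df)
        fit = fit_lmm(
            ModelSpec("lrr", ["treatment"], ["site", "site:block"]), df
        )
        tk = tukey_hsd(fit, "treatment")
        for r in tk.contrasts.itertuples():
            shared = set(tk.letters[r.level_a]) & set(tk.letters[r.level_b])
            if r.p_adj < tk.alpha:
                assert not shared
            else:
                assert shared


class TestPhyloMixed:
    def test_star_tree_equals_iid_species_model(self, small_species_delta,
                                                small_dataset):
        # a star tree makes the phylogenetic correlation an identity, so
        # the fit must match a model with an ordinary species intercept
        from gscover.phylo import read_newick

        sd = small_species_delta
        species = sorted(sd["species"].unique())
        star = read_newick(
            "(" + ",".join(f"{s}:1" for s in species) + ");"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_star = fit_phylo_mixed(
                sd, star, include_iid_species=False,
                include_design_random=False,
            )
            spec = ModelSpec(
                "delta_cover",
                ["n_added", "p_added", "n_added:p_added", "log_gs",
                 "log_gs:n_added", "log_gs:p_added", "log_gs:n_added:p_added"],
                ["species"],
            )
            f_iid = fit_lmm(spec, sd)
        np.testing.assert_allclose(
            f_star.params["estimate"], f_iid.params["estimate"], atol=1e-6
        )

    def test_relabeling_invariance(self, small_species_delta, small_dataset):
        sd = small_species_delta.copy()
        mapping = {s: f"zz{s}" for s in sd["species"].unique()}
        sd2 = sd.assign(species=sd["species"].map(mapping))
        nwk = small_dataset.tree.to_newick()
        for old, new in mapping.items():
            nwk = nwk.replace(old + ":", new + ":")
        from gscover.phylo import read_newick

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_phylo_mixed(sd, small_dataset.tree)
            f2 = fit_phylo_mixed(sd2, read_newick(nwk))
        np.testing.assert_allclose(
            f1.params["estimate"], f2.params["estimate"], atol=1e-8
        )

    def test_species_missing_from_tree_listed(self, small_species_delta,
                                              small_dataset):
        sd = small_species_delta.copy()
        sd.loc[sd.index[:5], "species"] = "unknown_taxon"
        with pytest.raises(ValueError, match="unknown_taxon"):
            fit_phylo_mixed(sd, small_dataset.tree)

    def test_too_few_species(self, small_dataset):
        sd = pd.DataFrame(
            {"species": ["a", "b"], "delta_cover": [0.0, 1.0],
             "log_gs": [0.1, 0.2], "n_added": [0, 1], "p_added": [0, 0]}
        )
        with pytest.raises(ValueError, match=">= 20"):
            fit_phylo_mixed(sd, small_dataset.tree)

    def test_table2_coefficient_rows(self, small_species_delta, small_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_phylo_mixed(small_species_delta, small_dataset.tree)
        expected = {
            "(intercept)", "n_added", "p_added", "n_added:p_added",
            "log_gs", "log_gs:n_added", "log_gs:p_added",
            "log_gs:n_added:p_added",
        }
        assert set(fit.params.index) == expected
        assert (fit.params["ci_low"] <= fit.params["estimate"]).all()
        assert (fit.params["estimate"] <= fit.params["ci_high"]).all()


class TestClimateInteractionModel:
    @staticmethod
    def _data(seed=3):
        cfg = SyntheticConfig(
            n_sites=8, blocks_per_site=2, n_species_pool=50,
            species_per_site=10, seed=seed,
        )
        ds = simulate_dataset(cfg)
        from gscover.community import (
            delta_cwgs, mean_cover_recent, plot_cwgs, pretreatment_cover,
        )

        pre = pretreatment_cover(ds.cover)
        rec = mean_cover_recent(ds.cover)
        resolved = (
            ds.gs_true.rename("c_value_1C").reset_index()
            .rename(columns={"index": "species"})
        )
        needed = ds.cover[["species", "site"]].drop_duplicates()
        res = needed.merge(resolved, on="species")
        cw = plot_cwgs(pre, rec, res)
        lrr = delta_cwgs(cw)
        dat = lrr[lrr["contrast"] == "control_vs_treatment"].copy()
        z = zscore_columns(ds.climate[["bio1", "bio12", "bio4", "bio15"]])
        z.columns = ["z_mat", "z_map", "z_tseas", "z_pseas"]
        return dat.merge(
            pd.concat([ds.climate[["site"]], z], axis=1), on="site"
        )

    def test_anova_rows_match_conventional_layout(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_climate_interaction_model(self._data())
        assert list(fit.anova.index) == list(CLIMATE_ANOVA_LABELS.values())
        assert len(fit.anova) == 19
        assert (fit.anova["df_num"] == 1).all()

    def test_requires_zscored_climate(self):
        dat = self._data()
        dat["z_map"] = dat["z_map"] * 3.0 + 1.0
        with pytest.raises(ValueError, match="z_map"):
            run_climate_interaction_model(dat)

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="missing columns"):
            run_climate_interaction_model(pd.DataFrame({"lrr": [1.0]}))
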