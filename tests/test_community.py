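"""Cover means, Δcover, cover-weighted genome size, and response ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gscover.community import (
    UndefinedStatisticError,
    cover_weighted_gs,
    delta_cover,
    delta_cwgs,
    lrr_control_vs_treatment,
    lrr_pre_vs_treatment,
    mean_cover_recent,
    plot_cwgs,
    pretreatment_cover,
)


def _obs(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "site", "block", "plot", "year", "year_type", "n_added",
            "p_added", "species", "functional_group", "pathway",
            "percent_cover",
        ],
    )


def _row(site="s1", block="b1", plot="p1", year=1, yt="treatment", n=1, p=0,
         sp="a", cover=10.0):
    return (site, block, plot, year, yt, n, p, sp, "grass", "C3", cover)


class TestMeanCoverRecent:
    def test_three_year_mean(self):
        obs = _obs([_row(year=y, cover=c) for y, c in [(1, 10), (2, 14), (3, 18)]])
        out = mean_cover_recent(obs)
        assert out["mean_cover"].iloc[0] == pytest.approx(14.0)

    def test_absence_counts_as_zero(self):
        obs = _obs(
            [_row(year=1, sp="b", cover=5.0), _row(year=2, sp="b", cover=5.0),
             _row(year=3, sp="b", cover=5.0), _row(year=3, sp="a", cover=9.0)]
        )
        out = mean_cover_recent(obs).set_index("species")
        assert out.loc["a", "mean_cover"] == pytest.approx(3.0)

    def test_single_year_window(self):
        obs = _obs([_row(year=4, cover=7.0)])
        assert mean_cover_recent(obs)["mean_cover"].iloc[0] == pytest.approx(7.0)

    def test_uses_most_recent_years_only(self):
        obs = _obs([_row(year=y, cover=c) for y, c in
                    [(1, 100), (2, 10), (3, 14), (4, 18)]])
        assert mean_cover_recent(obs)["mean_cover"].iloc[0] == pytest.approx(14.0)

    def test_plot_without_treatment_years_excluded(self, caplog):
        obs = _obs(
            [_row(year=0, yt="pretreatment", cover=3.0),
             _row(plot="p2", year=1, cover=5.0)]
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="gscover.community"):
            out = mean_cover_recent(obs)
        assert set(out["plot"]) == {"p2"}
        assert "excluding" in caplog.text


class TestDeltaCover:
    @staticmethod
    def _tables():
        obs = _obs(
            [
                _row(year=0, yt="pretreatment", sp="kept", cover=10.0),
                _row(year=0, yt="pretreatment", sp="lost", cover=8.0),
                _row(year=1, sp="kept", cover=14.0),
                _row(year=1, sp="recruit", cover=6.0),
            ]
        )
        return pretreatment_cover(obs), mean_cover_recent(obs)

    def test_change_recruit_and_loss_conventions(self):
        pre, rec = self._tables()
        out = delta_cover(rec, pre).set_index("species")["delta_cover"]
        assert out["kept"] == pytest.approx(4.0)
        assert out["recruit"] == pytest.approx(6.0)
        assert out["lost"] == pytest.approx(-8.0)

    def test_delta_sums_to_total_change(self):
        pre, rec = self._tables()
        out = delta_cover(rec, pre)
        total = rec["mean_cover"].sum() - pre["pre_cover"].sum()
        assert out["delta_cover"].sum() == pytest.approx(total)

    def test_log_gs_attachment(self):
        pre, rec = self._tables()
        gs = pd.DataFrame(
            {"species": ["kept"], "site": ["s1"], "c_value_1C": [2.0]}
        )
        out = delta_cover(rec, pre, resolved_gs=gs).set_index("species")
        assert out.loc["kept", "log_gs"] == pytest.approx(math.log(2.0))
        assert np.isnan(out.loc["recruit", "log_gs"])


class TestCoverWeightedGS:
    def test_single_species_identity(self):
        assert cover_weighted_gs([("a", 30.0)], {"a": 2.0}) == pytest.approx(2.0)

    def test_equal_cover_geometric_mean(self):
        cw = cover_weighted_gs([("a", 10.0), ("b", 10.0)], {"a": 1.0, "b": 4.0})
        assert cw == pytest.approx(2.0)

    def test_weighted_closed_form(self):
        cw = cover_weighted_gs([("a", 75.0), ("b", 25.0)], {"a": 1.0, "b": 16.0})
        assert cw == pytest.approx(math.exp(0.25 * math.log(16.0)))

    def test_missing_gs_species_renormalized(self):
        cw = cover_weighted_gs(
            [("a", 10.0), ("b", 10.0), ("nogs", 80.0)], {"a": 1.0, "b": 4.0}
        )
        assert cw == pytest.approx(2.0)

    def test_no_usable_species_raises(self):
        with pytest.raises(UndefinedStatisticError):
            cover_weighted_gs([("x", 10.0)], {"a": 1.0})

    def test_wls_equivalence(self):
        # intercept-only weighted least squares on ln GS equals the
        # weighted mean, hence exp of it equals cwGS
        rng = np.random.default_rng(3)
        gs = {f"s{i}": v for i, v in enumerate(rng.lognormal(0.5, 1, 8))}
        covers = [(f"s{i}", c) for i, c in enumerate(rng.uniform(1, 30, 8))]
        w = np.array([c for _, c in covers])
        lg = np.log([gs[s] for s, _ in covers])
        X = np.ones((8, 1))
        beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ lg)
        assert cover_weighted_gs(covers, gs) == pytest.approx(
            math.exp(beta[0]), rel=1e-12
        )

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(1, 13)
            gs = {f"s{i}": v for i, v in enumerate(rng.lognormal(0.4, 1, n))}
            covers = [(f"s{i}", c) for i, c in enumerate(rng.uniform(0.1, 60, n))]
            total = sum(c for _, c in covers)
            oracle = math.exp(
                sum((c / total) * math.log(gs[s]) for s, c in covers)
            )
            assert cover_weighted_gs(covers, gs) == pytest.approx(
                oracle, abs=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        covers=st.lists(st.floats(0.1, 100), min_size=2, max_size=8),
        scale=st.floats(0.01, 50),
        gs_vals=st.lists(st.floats(0.2, 50), min_size=8, max_size=8),
    )
    def test_scale_invariance(self, covers, scale, gs_vals):
        gs = {f"s{i}": v for i, v in enumerate(gs_vals)}
        pairs = [(f"s{i}", c) for i, c in enumerate(covers)]
        scaled = [(s, c * scale) for s, c in pairs]
        assert cover_weighted_gs(pairs, gs) == pytest.approx(
            cover_weighted_gs(scaled, gs), rel=1e-9
        )

    def test_monotone_in_largest_gs_cover(self):
        gs = {"small": 0.5, "mid": 2.0, "big": 20.0}
        base = [("small", 30.0), ("mid", 20.0), ("big", 10.0)]
        prev = cover_weighted_gs(base, gs)
        for extra in [5.0, 15.0, 40.0]:
            cur = cover_weighted_gs(
                [("small", 30.0), ("mid", 20.0), ("big", 10.0 + extra)], gs
            )
            assert cur >= prev
            prev = cur

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(12)
        gs = {f"s{i}": v for i, v in enumerate(rng.lognormal(0, 1, 6))}
        covers = [(f"s{i}", c) for i, c in enumerate(rng.uniform(1, 20, 6))]
        cw = cover_weighted_gs(covers, gs)
        assert min(gs.values()) <= cw <= max(gs.values())


class TestLogResponseRatios:
    def test_identity_zero(self):
        assert lrr_control_vs_treatment(2.0, [1.0, 3.0]) == pytest.approx(0.0)
        assert lrr_pre_vs_treatment(5.0, 5.0) == 0.0

    def test_closed_forms(self):
        assert lrr_control_vs_treatment(math.e * 2.0, [2.0]) == pytest.approx(1.0)
        assert lrr_pre_vs_treatment(2.0, 1.0) == pytest.approx(math.log(2.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100), c=st.floats(0.01, 100))
    def test_antisymmetry_and_additivity(self, a, b, c):
        assert lrr_control_vs_treatment(a, [b]) == pytest.approx(
            -lrr_control_vs_treatment(b, [a]), abs=1e-9
        )
        assert lrr_pre_vs_treatment(c, a) == pytest.approx(
            lrr_pre_vs_treatment(c, b) + lrr_pre_vs_treatment(b, a), abs=1e-9
        )

    def test_errors(self):
        with pytest.raises(UndefinedStatisticError):
            lrr_control_vs_treatment(1.0, [])
        with pytest.raises(ValueError):
            lrr_pre_vs_treatment(-1.0, 2.0)


class TestDeltaCwGSTable:
    @staticmethod
    def _cwgs_table():
        rows = []
        for plot, (n, p, cw_t, cw_pre) in {
            "p1": (0, 0, 2.0, 2.0),
            "p2": (1, 0, 4.0, 2.0),
            "p3": (0, 1, 2.0, 1.0),
            "p4": (1, 1, 6.0, 3.0),
        }.items():
            rows.append(dict(site="s1", block="b1", plot=plot, n_added=n,
                             p_added=p, epoch="treatment_mean", cwgs=cw_t,
                             gs_cover_fraction=1.0))
            rows.append(dict(site="s1", block="b1", plot=plot, n_added=n,
                             p_added=p, epoch="pretreatment", cwgs=cw_pre,
                             gs_cover_fraction=1.0))
        return pd.DataFrame(rows)

    def test_control_contrast_values(self):
        out = delta_cwgs(self._cwgs_table())
        ctrl = out[out["contrast"] == "control_vs_treatment"].set_index("plot")
        # single control plot with cwgs 2.0 is the reference
        assert ctrl.loc["p2", "lrr"] == pytest.approx(math.log(2.0))
        assert ctrl.loc["p1", "lrr"] == pytest.approx(0.0)

    def test_pretreatment_contrast_values(self):
        out = delta_cwgs(self._cwgs_table())
        pre = out[out["contrast"] == "pretreatment_vs_treatment"].set_index("plot")
        assert pre.loc["p2", "lrr"] == pytest.approx(math.log(2.0))
        assert pre.loc["p4", "lrr"] == pytest.approx(math.log(2.0))

    def test_block_scope(self):
        out = delta_cwgs(self._cwgs_table(), scope="block")
        assert len(out[out["contrast"] == "control_vs_treatment"]) == 4

    def test_plot_cwgs_epochs_and_diagnostic(self, small_dataset):
        pre = pretreatment_cover(small_dataset.cover)
        rec = mean_cover_recent(small_dataset.cover)
        resolved = (
            small_dataset.gs_true.rename("c_value_1C").reset_index()
            .rename(columns={"index": "species"})
        )
        needed = small_dataset.cover[["species", "site"]].drop_duplicates()
        res = needed.merge(resolved, on="species")
        cw = plot_cwgs(pre, rec, res)
        assert set(cw["epoch"]) == {"pretreatment", "treatment_mean"}
        assert (cw["cwgs"] > 0).all()
        np.testing.assert_allclose(cw["gs_cover_fraction"], 1.0)
        n_plots = small_dataset.cover.groupby(["site", "block", "plot"]).ngroups
        assert len(cw) == 2 * n_plots
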