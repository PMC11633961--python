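"""Plot- and species-level community statistics.

Core quantities:

* **mean recent cover** — per plot and species, the arithmetic mean percent
  cover over the most recent (up to) three treatment years, with absence
  counted as zero cover;
* **Δcover** — mean recent cover minus the pretreatment-year cover, in
  percentage points; new recruits enter with pretreatment 0, lost species
  with recent mean 0;
* **cwGS** — cover-weighted genome size of a plot: the cover-weighted
  geometric mean of the species 1C-values, ``exp(sum_i w_i ln GS_i)`` with
  weights ``w_i`` the species' share of the summed cover of GS-bearing
  species.  Weighting the *log* genome size and back-transforming keeps
  cwGS strictly positive (1C-values below 1 pg make ln GS negative), so the
  log response ratios built on it are always defined;
* **ΔcwGS** — natural-log response ratios of cwGS, either against the
  average cwGS of the control plots (treatment contrast) or against the
  same plot's pretreatment value (temporal contrast).

Note the weighted-least-squares connection: an intercept-only WLS fit of
ln GS with cover weights has the weighted mean as its estimate, so the
direct weighted mean used here is the same statistic.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mean_cover_recent",
    "pretreatment_cover",
    "delta_cover",
    "cover_weighted_gs",
    "plot_cwgs",
    "lrr_control_vs_treatment",
    "lrr_pre_vs_treatment",
    "delta_cwgs",
    "UndefinedStatisticError",
]

logger = logging.getLogger(__name__)

PLOT_KEY = ["site", "block", "plot"]
_META = ["n_added", "p_added"]


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for the given plot (e.g., no GS-bearing
    species with positive cover)."""


def _plot_meta(obs: pd.DataFrame) -> pd.DataFrame:
    return obs[PLOT_KEY + _META].drop_duplicates(PLOT_KEY)


def mean_cover_recent(obs: pd.DataFrame, n_years: int = 3) -> pd.DataFrame:
    """Mean percent cover per plot x species over the most recent
    treatment years.

    Uses the most recent ``min(n_years, available)`` treatment-epoch years
    of each plot.  A species recorded in some but not all of those years
    contributes zero for the missing years.  Plots without any
    treatment-epoch data are excluded with a logged warning.

    Returns columns ``site, block, plot, n_added, p_added, species,
    functional_group, pathway, mean_cover``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    treat = obs[obs["year_type"] == "treatment"]
    skipped = (
        set(map(tuple, obs[PLOT_KEY].drop_duplicates().to_numpy()))
        - set(map(tuple, treat[PLOT_KEY].drop_duplicates().to_numpy()))
    )
    if skipped:
        logger.warning(
            "excluding %d plot(s) without treatment-epoch data: %s",
            len(skipped), sorted(skipped),
        )
    parts = []
    for key, grp in treat.groupby(PLOT_KEY, sort=True):
        years = sorted(grp["year"].unique())[-n_years:]
        window = grp[grp["year"].isin(years)]
        per_species = (
            window.groupby("species")["percent_cover"].sum() / len(years)
        )
        sub = window.drop_duplicates("species")[
            ["species", "functional_group", "pathway"]
        ].set_index("species")
        part = sub.assign(mean_cover=per_species).reset_index()
        for col, val in zip(PLOT_KEY, key):
            part[col] = val
        part["n_added"] = int(grp["n_added"].iloc[0])
        part["p_added"] = int(grp["p_added"].iloc[0])
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=PLOT_KEY + _META
            + ["species", "functional_group", "pathway", "mean_cover"]
        )
    out = pd.concat(parts, ignore_index=True)
    return out[
        PLOT_KEY + _META + ["species", "functional_group", "pathway", "mean_cover"]
    ]


def pretreatment_cover(obs: pd.DataFrame) -> pd.DataFrame:
    """Per plot x species percent cover in the (latest) pretreatment year."""
    pre = obs[obs["year_type"] == "pretreatment"]
    if len(pre) == 0:
        raise ValueError("no pretreatment-epoch rows in the cover table")
    last = pre.groupby(PLOT_KEY)["year"].transform("max")
    pre = pre[pre["year"] == last]
    out = pre[
        PLOT_KEY + _META + ["species", "functional_group", "pathway", "percent_cover"]
    ].rename(columns={"percent_cover": "pre_cover"})
    return out.reset_index(drop=True)


def delta_cover(
    mean_recent: pd.DataFrame,
    pretreatment: pd.DataFrame,
    resolved_gs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Species-level change in percent cover: recent mean minus pretreatment.

    Species absent at pretreatment (new recruits) enter with pretreatment
    cover zero; species absent from all recent years enter with recent
    mean zero.  If ``resolved_gs`` is given (columns ``species, site,
    c_value_1C``), a ``log_gs`` column (natural log of the site-resolved
    1C-value) is attached; species without a resolved value get NaN there
    and should be filtered by the caller.
    """
    key = PLOT_KEY + ["species"]
    left = mean_recent.set_index(key)
    right = pretreatment.set_index(key)
    merged = left[["mean_cover"]].join(right[["pre_cover"]], how="outer")
    merged["mean_cover"] = merged["mean_cover"].fillna(0.0)
    merged["pre_cover"] = merged["pre_cover"].fillna(0.0)
    merged["delta_cover"] = merged["mean_cover"] - merged["pre_cover"]

    attrs = pd.concat(
        [
            mean_recent[key + _META + ["functional_group", "pathway"]],
            pretreatment[key + _META + ["functional_group", "pathway"]],
        ]
    ).drop_duplicates(key).set_index(key)
    out = merged.join(attrs).reset_index()

    if resolved_gs is not None:
        gs_map = resolved_gs.set_index(["species", "site"])["c_value_1C"]
        out["log_gs"] = [
            math.log(gs_map[(sp, st)]) if (sp, st) in gs_map.index else np.nan
            for sp, st in zip(out["species"], out["site"])
        ]
    return out[
        PLOT_KEY
        + ["species", "delta_cover", "mean_cover", "pre_cover"]
        + (["log_gs"] if resolved_gs is not None else [])
        + ["functional_group", "pathway"] + _META
    ]


# ---------------------------------------------------------------------------
# Cover-weighted genome size
# ---------------------------------------------------------------------------

def cover_weighted_gs(
    plot_covers: Sequence[tuple[str, float]] | Mapping[str, float],
    gs: Mapping[str, float] | pd.DataFrame,
    site: str | None = None,
) -> float:
    """Cover-weighted geometric-mean genome size of one plot.

    ``plot_covers`` maps species to percent cover; ``gs`` maps species to
    the resolved 1C-value (or is a resolved table, in which case ``site``
    selects the site-specific rows).  Weights are the cover shares among
    species *with* a genome size; species lacking one are excluded and the
    remaining weights renormalized.
    """
    if isinstance(gs, pd.DataFrame):
        sub = gs if site is None else gs[gs["site"] == site]
        gs_map = dict(zip(sub["species"], sub["c_value_1C"]))
    else:
        gs_map = dict(gs)
    items = (
        plot_covers.items()
        if isinstance(plot_covers, Mapping)
        else list(plot_covers)
    )
    pairs = [
        (gs_map[sp], cv) for sp, cv in items if sp in gs_map and cv > 0
    ]
    if not pairs:
        raise UndefinedStatisticError(
            "no species with both positive cover and a resolved genome size"
        )
    values = np.array([v for v, _ in pairs])
    weights = np.array([w for _, w in pairs], dtype=float)
    weights = weights / weights.sum()
    return float(np.exp(weights @ np.log(values)))


def plot_cwgs(
    pretreatment: pd.DataFrame,
    mean_recent: pd.DataFrame,
    resolved_gs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-plot cwGS for the pretreatment and treatment-mean epochs.

    Returns one row per plot x epoch with columns ``site, block, plot,
    n_added, p_added, epoch, cwgs, gs_cover_fraction``, the last being the
    share of the plot's total cover carried by GS-bearing species (a
    coverage diagnostic).  Plots where no species has a resolved GS are
    dropped with a logged warning.
    """
    rows = []
    for epoch, table, col in (
        ("pretreatment", pretreatment, "pre_cover"),
        ("treatment_mean", mean_recent, "mean_cover"),
    ):
        for key, grp in table.groupby(PLOT_KEY, sort=True):
            site = key[0]
            covers = dict(zip(grp["species"], grp[col]))
            total = sum(v for v in covers.values() if v > 0)
            sub = resolved_gs[resolved_gs["site"] == site]
            gs_map = dict(zip(sub["species"], sub["c_value_1C"]))
            covered = sum(
                v for sp, v in covers.items() if v > 0 and sp in gs_map
            )
            try:
                cw = cover_weighted_gs(covers, gs_map)
            except UndefinedStatisticError:
                logger.warning("no GS-bearing cover on plot %s (%s)", key, epoch)
                continue
            rows.append(
                {
                    "site": site,
                    "block": key[1],
                    "plot": key[2],
                    "n_added": int(grp["n_added"].iloc[0]),
                    "p_added": int(grp["p_added"].iloc[0]),
                    "epoch": epoch,
                    "cwgs": cw,
                    "gs_cover_fraction": covered / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Log response ratios
# ---------------------------------------------------------------------------

def lrr_control_vs_treatment(
    cwgs_treated: float, cwgs_controls: Iterable[float]
) -> float:
    """ln(cwGS of a plot / arithmetic mean cwGS of the control plots)."""
    controls = [float(c) for c in cwgs_controls]
    if not controls:
        raise UndefinedStatisticError("empty control set")
    if cwgs_treated <= 0 or any(c <= 0 for c in controls):
        raise ValueError("cwGS values must be positive")
    return math.log(cwgs_treated / (sum(controls) / len(controls)))


def lrr_pre_vs_treatment(cwgs_now: float, cwgs_pre: float) -> float:
    """ln(current cwGS / pretreatment cwGS of the same plot)."""
    if cwgs_now <= 0 or cwgs_pre <= 0:
        raise ValueError("cwGS values must be positive")
    return math.log(cwgs_now / cwgs_pre)


def delta_cwgs(cwgs_table: pd.DataFrame, scope: str = "site") -> pd.DataFrame:
    """Both ΔcwGS log response ratios for every plot.

    ``scope`` sets the averaging pool for the control contrast: ``"site"``
    (default) averages the treatment-epoch cwGS of all control plots of the
    site, ``"block"`` restricts to the plot's own block.  Control plots get
    a control-contrast value too (their deviation from the control mean).

    Returns columns ``site, block, plot, n_added, p_added, contrast, lrr``.
    """
    if scope not in ("site", "block"):
        raise ValueError("scope must be 'site' or 'block'")
    treat_epoch = cwgs_table[cwgs_table["epoch"] == "treatment_mean"]
    pre_epoch = cwgs_table[cwgs_table["epoch"] == "pretreatment"]
    controls = treat_epoch[
        (treat_epoch["n_added"] == 0) & (treat_epoch["p_added"] == 0)
    ]
    pool_key = ["site"] if scope == "site" else ["site", "block"]
    control_mean = controls.groupby(pool_key)["cwgs"].mean()

    rows = []
    for r in treat_epoch.itertuples():
        key = (r.site,) if scope == "site" else (r.site, r.block)
        key = key[0] if len(key) == 1 else key
        if key in control_mean.index:
            rows.append(
                {
                    "site": r.site, "block": r.block, "plot": r.plot,
                    "n_added": r.n_added, "p_added": r.p_added,
                    "contrast": "control_vs_treatment",
                    "lrr": lrr_control_vs_treatment(r.cwgs, [control_mean[key]]),
                }
            )
    pre_map = pre_epoch.set_index(PLOT_KEY)["cwgs"]
    for r in treat_epoch.itertuples():
        key = (r.site, r.block, r.plot)
        if key in pre_map.index:
            rows.append(
                {
                    "site": r.site, "block": r.block, "plot": r.plot,
                    "n_added": r.n_added, "p_added": r.p_added,
                    "contrast": "pretreatment_vs_treatment",
                    "lrr": lrr_pre_vs_treatment(r.cwgs, float(pre_map[key])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=PLOT_KEY + _META + ["contrast", "lrr"],
    )
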