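"""End-to-end orchestration: simulate → resolve → metrics → models.

A run lives in one directory.  Each stage reads only persisted inputs from
that directory (or, for the first stage, the configured external files) and
writes its outputs back as tab-delimited text, so any stage can be re-run
in isolation and reproduces its artifacts exactly.  A plain-text log
records stage timings and row counts; the configuration is echoed as YAML.

Stage order and artifacts:

1. ``simulate``  — data/ (cover, genome sizes, climate, plots, tree, config)
2. ``resolve-gs``— resolved_gs.tsv, unresolved_species.tsv, gs_coverage.tsv,
                   gs_summary.tsv
3. ``metrics``   — cwgs.tsv, delta_cwgs_control.tsv,
                   delta_cwgs_pretreatment.tsv, species_delta.tsv
4. ``climate``   — climate_loadings_*.tsv, climate_selected.tsv, climate_z.tsv
5. ``signal``    — signal.tsv (Pagel's lambda, Blomberg's K)
6. ``fit``       — treatment, climate-interaction, and phylogenetic
                   mixed-model tables plus Tukey contrasts
7. ``report``    — summary.txt with treatment means ± 95% CI and letters
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import community, genome_size, inference, phylo, synthetic

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and keys."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    # external inputs (used when synthetic is None)
    cover_path: str | None = None
    gs_path: str | None = None
    climate_path: str | None = None
    tree_path: str | None = None
    # analysis switches
    n_recent_years: int = 3
    control_scope: str = "site"           # averaging pool for the LRR
    lambda_mode: str = "fixed_1"          # PGLS lambda handling
    n_perm: int = 1000                    # Blomberg K permutations
    include_iid_species: bool = True
    climate_override: list[str] = field(
        default_factory=lambda: list(climate_mod.CANONICAL_VARS.values())
    )

    def __post_init__(self) -> None:
        if self.synthetic is None and self.cover_path is None:
            self.synthetic = synthetic.SyntheticConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _stage_logger(rundir: Path) -> logging.Logger:
    lg = logging.getLogger(f"gscover.run.{rundir.name}")
    lg.setLevel(logging.INFO)
    logfile = rundir / "run.log"
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == logfile.resolve()
        for h in lg.handlers
    ):
        handler = logging.FileHandler(logfile)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        lg.addHandler(handler)
    return lg


def _read(path: Path, **kw) -> pd.DataFrame:
    if not path.exists():
        raise StageError(f"required input missing: {path.name}")
    return pd.read_csv(path, sep="\t", **kw)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    data = rundir / "data"
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        ds = synthetic.simulate_dataset(syn)
        synthetic.write_dataset(ds, data)
    else:
        data.mkdir(parents=True, exist_ok=True)
        for src, name in (
            (cfg.cover_path, "cover.tsv"),
            (cfg.gs_path, "genome_sizes.tsv"),
            (cfg.climate_path, "climate.tsv"),
            (cfg.tree_path, "tree.nwk"),
        ):
            if src is None:
                raise StageError(f"simulate: missing input path for {name}")
            (data / name).write_text(Path(src).read_text())
    cfg.to_yaml(rundir / "run_config.yaml")


def stage_resolve(cfg: RunConfig, rundir: Path) -> None:
    cover = _read(rundir / "data" / "cover.tsv")
    records = genome_size.read_gs_table(rundir / "data" / "genome_sizes.tsv")
    needed = set(zip(cover["species"], cover["site"]))
    resolved, unresolved = genome_size.resolve_genome_size(records, needed)
    genome_size.write_resolved(resolved, unresolved, rundir)
    coverage = genome_size.site_coverage(resolved, unresolved)
    coverage.to_csv(rundir / "gs_coverage.tsv", sep="\t", index=False)
    per_species = resolved.groupby("species")["c_value_1C"].min()
    summ = genome_size.summarize_gs(per_species)
    pd.DataFrame([dataclasses.asdict(summ)]).to_csv(
        rundir / "gs_summary.tsv", sep="\t", index=False
    )


def stage_metrics(cfg: RunConfig, rundir: Path) -> None:
    cover = _read(rundir / "data" / "cover.tsv")
    resolved = _read(rundir / "resolved_gs.tsv")
    pre = community.pretreatment_cover(cover)
    recent = community.mean_cover_recent(cover, cfg.n_recent_years)
    cwgs = community.plot_cwgs(pre, recent, resolved)
    cwgs.to_csv(rundir / "cwgs.tsv", sep="\t", index=False)
    lrrs = community.delta_cwgs(cwgs, scope=cfg.control_scope)
    for contrast, name in (
        ("control_vs_treatment", "delta_cwgs_control.tsv"),
        ("pretreatment_vs_treatment", "delta_cwgs_pretreatment.tsv"),
    ):
        lrrs[lrrs["contrast"] == contrast].to_csv(
            rundir / name, sep="\t", index=False
        )
    sd = community.delta_cover(recent, pre, resolved_gs=resolved)
    sd.to_csv(rundir / "species_delta.tsv", sep="\t", index=False)


def stage_climate(cfg: RunConfig, rundir: Path) -> None:
    clim = _read(rundir / "data" / "climate.tsv")
    sel = climate_mod.pca_select(
        clim.drop(columns=["site"]), override=cfg.climate_override or None
    )
    for group, load in sel.loadings.items():
        load.to_csv(rundir / f"climate_loadings_{group}.tsv", sep="\t")
    pd.DataFrame({"selected": sel.selected}).to_csv(
        rundir / "climate_selected.tsv", sep="\t", index=False
    )
    zcols = ["z_mat", "z_map", "z_tseas", "z_pseas"]
    z = climate_mod.zscore_columns(clim[sel.selected])
    z.columns = zcols
    out = pd.concat([clim[["site"]], z], axis=1)
    out.to_csv(rundir / "climate_z.tsv", sep="\t", index=False)


def stage_signal(cfg: RunConfig, rundir: Path) -> None:
    resolved = _read(rundir / "resolved_gs.tsv")
    tree = phylo.read_newick((rundir / "data" / "tree.nwk").read_text())
    trait = resolved.groupby("species")["c_value_1C"].min()
    tips = [t for t in tree.tip_labels if t in trait.index]
    if len(tips) < 4:
        raise StageError("signal: fewer than 4 tree tips carry a genome size")
    sub = tree.prune(tips) if len(tips) < tree.n_tips else tree
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    lam = phylo.pagels_lambda(sub, trait[tips])
    kst = phylo.blombergs_K(sub, trait[tips], n_perm=cfg.n_perm, seed=seed)
    pd.DataFrame(
        [dataclasses.asdict(lam), dataclasses.asdict(kst)]
    ).to_csv(rundir / "signal.tsv", sep="\t", index=False)


def stage_fit(cfg: RunConfig, rundir: Path) -> None:
    lrr_ctrl = _read(rundir / "delta_cwgs_control.tsv")
    climate_z = _read(rundir / "climate_z.tsv")
    species_delta = _read(rundir / "species_delta.tsv")
    tree = phylo.read_newick((rundir / "data" / "tree.nwk").read_text())

    # (a) treatment-only model of the control-contrast LRR + Tukey letters
    dat = lrr_ctrl.copy()
    dat["treatment"] = inference.treatment_cell(dat)
    fit_t = inference.fit_lmm(
        inference.ModelSpec(
            response="lrr", fixed=["treatment"], random=["site", "site:block"]
        ),
        dat,
    )
    tk = inference.tukey_hsd(fit_t, "treatment")
    fit_t.params.to_csv(rundir / "fit_treatment_coefs.tsv", sep="\t")
    fit_t.anova.to_csv(rundir / "fit_treatment_anova.tsv", sep="\t")
    tk.contrasts.to_csv(rundir / "tukey_contrasts.tsv", sep="\t", index=False)
    letters = pd.DataFrame(
        {"treatment": list(tk.letters), "letters": list(tk.letters.values())}
    )
    tk.means_ci.join(letters.set_index("treatment")).to_csv(
        rundir / "treatment_means.tsv", sep="\t"
    )

    # (b) nutrient x climate interaction model
    merged = dat.merge(climate_z, on="site", how="left")
    if merged[["z_mat", "z_map", "z_tseas", "z_pseas"]].isna().any().any():
        bad = sorted(
            merged.loc[merged["z_mat"].isna(), "site"].unique()
        )
        raise StageError(f"fit: sites without climate data: {bad}")
    fit_c = inference.run_climate_interaction_model(merged)
    fit_c.anova.to_csv(rundir / "fit_climate_anova.tsv", sep="\t")
    fit_c.params.to_csv(rundir / "fit_climate_coefs.tsv", sep="\t")
    pd.DataFrame(
        {"component": fit_c.varcomps.index, "variance": fit_c.varcomps.values}
    ).to_csv(rundir / "fit_climate_varcomps.tsv", sep="\t", index=False)

    # (c) species-level phylogenetic mixed model
    sd = species_delta.dropna(subset=["log_gs"]).copy()
    fit_p = inference.fit_phylo_mixed(
        sd, tree, include_iid_species=cfg.include_iid_species
    )
    fit_p.params.to_csv(rundir / "fit_phylo_coefs.tsv", sep="\t")
    pd.DataFrame(
        {"component": fit_p.varcomps.index, "variance": fit_p.varcomps.values}
    ).to_csv(rundir / "fit_phylo_varcomps.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        [
            {"model": "treatment", "marginal_r2": fit_t.marginal_r2,
             "n": fit_t.n_obs, "singular": fit_t.singular},
            {"model": "climate_interaction", "marginal_r2": fit_c.marginal_r2,
             "n": fit_c.n_obs, "singular": fit_c.singular},
            {"model": "phylo_mixed", "marginal_r2": fit_p.marginal_r2,
             "n": fit_p.n_obs, "singular": fit_p.singular},
        ]
    )
    meta.to_csv(rundir / "fit_meta.tsv", sep="\t", index=False)


def stage_report(cfg: RunConfig, rundir: Path) -> None:
    means = _read(rundir / "treatment_means.tsv", index_col=0)
    signal = _read(rundir / "signal.tsv")
    gs_summary = _read(rundir / "gs_summary.tsv")
    phylo_coefs = _read(rundir / "fit_phylo_coefs.tsv", index_col=0)
    meta = _read(rundir / "fit_meta.tsv")

    lines = ["gscover run summary", "===================", ""]
    lines.append("Genome-size distribution (resolved, per species):")
    s = gs_summary.iloc[0]
    lines.append(
        f"  mean {s['mean']:.2f} pg, median {s['median']:.2f} pg, "
        f"mode {s['mode']:.2f} pg, range {s['min']:.2f}-{s['max']:.2f} pg "
        f"({s['fold_range']:.0f}-fold)"
    )
    lines.append("")
    lines.append("Phylogenetic signal in genome size:")
    for _, row in signal.iterrows():
        lines.append(
            f"  {row['statistic']}: {row['value']:.4g} (p = {row['p_value']:.4g})"
        )
    lines.append("")
    lines.append(
        "Treatment means of the cwGS log response ratio "
        "(control contrast), 95% CI and Tukey letters:"
    )
    for lev in ("control", "N", "P", "NP"):
        if lev in means.index:
            r = means.loc[lev]
            lines.append(
                f"  {lev:>7}: {r['mean']:+.4f} "
                f"[{r['ci_low']:+.4f}, {r['ci_high']:+.4f}]  {r['letters']}"
            )
    lines.append("")
    if "log_gs:n_added" in phylo_coefs.index:
        r = phylo_coefs.loc["log_gs:n_added"]
        lines.append(
            "Species-level phylogenetic mixed model, log(GS) x N slope: "
            f"{r['estimate']:.3f} %-points per ln pg "
            f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}]"
        )
    lines.append("")
    for _, row in meta.iterrows():
        lines.append(
            f"model {row['model']}: n = {row['n']}, "
            f"marginal R2 = {row['marginal_r2']:.3f}"
        )
    lines.append("")
    lines.append(inference.METHOD_NOTE)
    (rundir / "summary.txt").write_text("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "resolve-gs": stage_resolve,
    "metrics": stage_metrics,
    "climate": stage_climate,
    "signal": stage_signal,
    "fit": stage_fit,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages in order; returns the run directory."""
    rundir = Path(cfg.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    lg = _stage_logger(rundir)
    for name, fn in STAGES.items():
        t0 = time.perf_counter()
        try:
            fn(cfg, rundir)
        except Exception as exc:
            lg.error("stage %s failed: %s", name, exc)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        lg.info("stage %s completed in %.2fs", name, time.perf_counter() - t0)
    return rundir
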