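"""Synthetic NutNet-style nutrient-addition experiments with known truth.

The generator emulates the structure of a coordinated grassland
fertilization network: ~27 sites, each with 2–6 blocks, each block holding
the four factorial nutrient cells (control, N, P, N+P) on separate plots;
species percent cover recorded in one pretreatment year and the following
treatment years; a species pool related by a Yule phylogeny carrying a
log-Brownian genome-size (GS) trait with tunable phylogenetic signal; and
site climates with correlated temperature and precipitation variable blocks.

Cover change is generated on the percentage-point scale.  The expected
change for species *i* on plot *p* is::

    [beta_gs_n + beta_gs_n_map * z(MAP) + beta_gs_n_tseas * z(TSeas)]
        * ln(GS_i) * N_p   (+ analogous optional P and N:P terms)

plus site, block, and species random intercepts and observation noise, with
covers truncated at zero.  Every effect size is a configuration field, so
downstream estimators can be tested by parameter recovery.

Reproducibility: one RNG stream per generator, with the four stream seeds
derived deterministically from the master seed, so the same master seed
yields bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .phylo import Phylogeny, bm_covariance, lambda_transform

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_phylogeny",
    "simulate_genome_sizes",
    "simulate_climate",
    "simulate_cover",
    "simulate_dataset",
    "write_dataset",
]

TREATMENTS = ("control", "N", "P", "NP")

FUNCTIONAL_GROUPS = (
    "geophyte", "grass", "legume", "woody", "annual_forb", "perennial_forb"
)

#: Default share of the species pool per functional group.  Groups are laid
#: out contiguously in tree-traversal order, so with phylogenetic signal in
#: GS the groups differ in mean GS without breaking the Brownian model.
DEFAULT_GROUP_PROPORTIONS = {
    "grass": 0.35,
    "perennial_forb": 0.30,
    "annual_forb": 0.15,
    "legume": 0.08,
    "geophyte": 0.07,
    "woody": 0.05,
}


class ConfigurationError(ValueError):
    """A generator input is inconsistent (missing GS or climate, bad sizes)."""


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of one synthetic experiment.

    Cover-change effect sizes are in percentage points per unit ln(GS in
    pg); climate modifiers are per standard deviation of the site climate
    variable.
    """

    n_sites: int = 27
    blocks_per_site: int = 3
    n_species_pool: int = 200
    species_per_site: int = 25
    n_treatment_years: int = 3
    birth_rate: float = 1.0
    gs_root_log: float = math.log(1.5)   # ln pg; median-sized genome
    gs_bm_sigma2: float = 0.2            # Brownian rate on ln GS
    gs_lambda_true: float = 0.9
    beta_gs_n: float = 1.0               # ln(GS) x N slope, %-points
    beta_gs_n_map: float = -0.5          # modifier per SD of MAP
    beta_gs_n_tseas: float = -0.3        # modifier per SD of temp seasonality
    beta_gs_p: float = 0.0               # ln(GS) x P slope
    beta_gs_np: float = 0.0              # ln(GS) x N x P three-way slope
    cover_noise_sd: float = 1.5          # %-points, per plot x species x year
    site_sd: float = 0.5
    block_sd: float = 0.3
    species_sd: float = 0.5
    mean_species_cover: float = 8.0      # baseline mean percent cover
    total_cover_scale: float = 1.0       # multiplies all baseline covers
    gs_coverage_fraction: float = 1.0    # share of pool with a GS record
    measured_fraction: float = 0.2       # share of covered species with a
                                         # site-specific measured record
    group_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    c4_fraction_of_grasses: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        if not (2 <= self.blocks_per_site <= 6):
            raise ConfigurationError("blocks_per_site must lie in [2, 6]")
        if self.n_species_pool < 2:
            raise ConfigurationError("n_species_pool must be >= 2")
        if self.species_per_site < 1:
            raise ConfigurationError("species_per_site must be >= 1")
        if self.species_per_site > self.n_species_pool:
            raise ConfigurationError("species_per_site exceeds the pool")
        if self.n_treatment_years < 1:
            raise ConfigurationError("n_treatment_years must be >= 1")
        if self.birth_rate <= 0:
            raise ConfigurationError("birth_rate must be positive")
        if self.gs_bm_sigma2 < 0:
            raise ConfigurationError("gs_bm_sigma2 must be >= 0")
        if not (0.0 <= self.gs_lambda_true <= 1.0):
            raise ConfigurationError("gs_lambda_true must lie in [0, 1]")
        for name in ("cover_noise_sd", "site_sd", "block_sd", "species_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mean_species_cover <= 0 or self.total_cover_scale <= 0:
            raise ConfigurationError("cover scales must be positive")
        if not (0.0 < self.gs_coverage_fraction <= 1.0):
            raise ConfigurationError("gs_coverage_fraction must be in (0, 1]")

    def stream_seeds(self) -> dict[str, int]:
        """Per-generator seeds, derived deterministically from the master."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("phylogeny", "genome_sizes", "climate", "cover")
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


# ---------------------------------------------------------------------------
# Phylogeny: Yule (pure-birth) simulation
# ---------------------------------------------------------------------------

def simulate_phylogeny(
    n_species: int, birth_rate: float, seed: int
) -> Phylogeny:
    """Simulate a rooted ultrametric Yule tree with ``n_species`` tips.

    The process starts with the two daughters of the root; with *k* extant
    lineages the next split arrives after an Exponential(k * birth_rate)
    wait on a uniformly chosen lineage.  After the n-th lineage appears the
    process runs one further Exponential(n * birth_rate) interval so every
    terminal branch has strictly positive length.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    # active lineage = (birth_time, parent_node)
    active: list[tuple[float, dendropy.Node]] = [(0.0, root), (0.0, root)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        birth, parent = active.pop(idx)
        node = dendropy.Node()
        parent.add_child(node)
        node.edge.length = t - birth
        active.append((t, node))
        active.append((t, node))
    t += rng.exponential(1.0 / (n_species * birth_rate))
    width = len(str(n_species))
    for i, (birth, parent) in enumerate(active, start=1):
        leaf = dendropy.Node()
        parent.add_child(leaf)
        leaf.edge.length = t - birth
        leaf.taxon = ns.new_taxon(f"sp{i:0{width}d}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Genome sizes: Brownian motion on the ln scale
# ---------------------------------------------------------------------------

def _true_log_gs(tree: Phylogeny, cfg: SyntheticConfig, seed: int) -> pd.Series:
    """Draw ln(1C) per tip: multivariate normal with covariance
    gs_bm_sigma2 * C_lambda around the root value."""
    n = tree.n_tips
    if cfg.gs_bm_sigma2 == 0.0:
        return pd.Series(np.full(n, cfg.gs_root_log), index=tree.tip_labels)
    C = bm_covariance(tree).to_numpy()
    Clam = lambda_transform(C, cfg.gs_lambda_true)
    L = np.linalg.cholesky(cfg.gs_bm_sigma2 * Clam)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    return pd.Series(cfg.gs_root_log + L @ z, index=tree.tip_labels)


def simulate_genome_sizes(
    tree: Phylogeny, cfg: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Genome-size records for the species pool.

    Returns one database row per covered species plus, for a configurable
    fraction, a site-specific measured record (both carrying the species'
    true value, so provenance resolution can be exercised without
    distorting the ground truth).  Columns: ``species, site, c_value_1C,
    source, note``; ``site`` is empty for database records.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.stream_seeds()["genome_sizes"]
    log_gs = _true_log_gs(tree, cfg, seed)
    rng = np.random.default_rng(seed + 1)

    species = list(log_gs.index)
    n_cov = max(1, int(round(cfg.gs_coverage_fraction * len(species))))
    covered = sorted(rng.choice(species, size=n_cov, replace=False))

    rows = [
        {
            "species": sp,
            "site": "",
            "c_value_1C": float(np.exp(log_gs[sp])),
            "source": "database",
            "note": "",
        }
        for sp in covered
    ]
    n_meas = int(round(cfg.measured_fraction * len(covered)))
    if n_meas > 0:
        width = len(str(cfg.n_sites))
        measured = rng.choice(covered, size=n_meas, replace=False)
        for sp in sorted(measured):
            site = f"site{int(rng.integers(cfg.n_sites)) + 1:0{width}d}"
            rows.append(
                {
                    "species": sp,
                    "site": site,
                    "c_value_1C": float(np.exp(log_gs[sp])),
                    "source": "measured",
                    "note": "flow cytometry (synthetic)",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Climate: two correlated variable blocks
# ---------------------------------------------------------------------------

#: (mean, SD) on natural scales for the 19 BioClim-style variables.
#: bio1..bio11 form the temperature group, bio12..bio19 the precipitation
#: group.  bio1 = mean annual temperature (degC), bio4 = temperature
#: seasonality (SD * 100), bio12 = annual precipitation (mm), bio15 =
#: precipitation seasonality (CV).
CLIMATE_SCALES = {
    "bio1": (12.0, 3.5), "bio2": (11.0, 2.0), "bio3": (35.0, 6.0),
    "bio4": (7000.0, 2000.0), "bio5": (26.0, 4.0), "bio6": (-2.0, 5.0),
    "bio7": (28.0, 6.0), "bio8": (14.0, 5.0), "bio9": (8.0, 6.0),
    "bio10": (20.0, 3.5), "bio11": (2.0, 5.0),
    "bio12": (1000.0, 270.0), "bio13": (120.0, 40.0), "bio14": (30.0, 18.0),
    "bio15": (40.0, 15.0), "bio16": (330.0, 100.0), "bio17": (110.0, 60.0),
    "bio18": (220.0, 80.0), "bio19": (200.0, 90.0),
}

TEMPERATURE_VARS = [f"bio{i}" for i in range(1, 12)]
PRECIPITATION_VARS = [f"bio{i}" for i in range(12, 20)]

_WITHIN_GROUP_CORR = 0.7
_FACTOR_CORR = 0.3


def simulate_climate(n_sites: int, seed: int) -> pd.DataFrame:
    """Per-site climate table with grouped correlation structure.

    Each site draws a temperature factor and a precipitation factor
    (correlated at 0.3); each of the 19 variables loads on its group's
    factor so that within-group correlations (~0.7) exceed between-group
    correlations (~0.2), then is shifted/scaled to a plausible natural
    scale.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2 (z-scoring undefined)")
    rng = np.random.default_rng(seed)
    f_temp = rng.standard_normal(n_sites)
    f_prec = _FACTOR_CORR * f_temp + math.sqrt(
        1.0 - _FACTOR_CORR**2
    ) * rng.standard_normal(n_sites)

    width = len(str(n_sites))
    out = {"site": [f"site{i + 1:0{width}d}" for i in range(n_sites)]}
    a = math.sqrt(_WITHIN_GROUP_CORR)
    b = math.sqrt(1.0 - _WITHIN_GROUP_CORR)
    for var in TEMPERATURE_VARS + PRECIPITATION_VARS:
        factor = f_temp if var in TEMPERATURE_VARS else f_prec
        latent = a * factor + b * rng.standard_normal(n_sites)
        mean, sd = CLIMATE_SCALES[var]
        out[var] = mean + sd * latent
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Percent cover
# ---------------------------------------------------------------------------

def _assign_groups(
    tree: Phylogeny, cfg: SyntheticConfig
) -> tuple[pd.Series, pd.Series]:
    """Functional group and photosynthetic pathway per pool species.

    Groups occupy contiguous stretches of the tip traversal order, i.e.
    clades, so group GS differences emerge from the phylogenetic signal of
    the trait rather than from an added offset.
    """
    labels = tree.tip_labels
    n = len(labels)
    props = cfg.group_proportions
    counts = {g: int(round(p * n)) for g, p in props.items()}
    drift = n - sum(counts.values())
    first = next(iter(counts))
    counts[first] += drift
    groups: list[str] = []
    for g in props:
        groups.extend([g] * counts[g])
    groups = groups[:n]
    while len(groups) < n:
        groups.append(first)
    fg = pd.Series(groups, index=labels, name="functional_group")

    pathway = pd.Series("not_applicable", index=labels, name="pathway")
    grass_idx = [lab for lab in labels if fg[lab] == "grass"]
    n_c4 = int(round(cfg.c4_fraction_of_grasses * len(grass_idx)))
    for lab in grass_idx[: len(grass_idx) - n_c4]:
        pathway[lab] = "C3"
    for lab in grass_idx[len(grass_idx) - n_c4:]:
        pathway[lab] = "C4"
    return fg, pathway


def simulate_cover(
    cfg: SyntheticConfig,
    gs: pd.DataFrame,
    climate: pd.DataFrame,
    tree: Phylogeny,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long plot x year x species percent-cover table.

    Every species drawn for a site must have a genome-size value in ``gs``
    and every site a row in ``climate``; violations raise
    :class:`ConfigurationError` naming the offender.  Rows are emitted only
    for species with positive cover in that year (absence = zero cover by
    convention downstream).
    """
    cfg.validate()
    if seed is None:
        seed = cfg.stream_seeds()["cover"]
    rng = np.random.default_rng(seed)

    sites = list(climate["site"])
    if len(sites) < cfg.n_sites:
        raise ConfigurationError(
            f"climate table has {len(sites)} sites; config needs {cfg.n_sites}"
        )
    sites = sites[: cfg.n_sites]

    gs_by_species = (
        gs.groupby("species")["c_value_1C"].min()
        if len(gs) else pd.Series(dtype=float)
    )
    pool = tree.tip_labels
    missing_gs = [sp for sp in pool if sp not in gs_by_species.index]

    z_map = _zscore(climate.set_index("site").loc[sites, "bio12"])
    z_tseas = _zscore(climate.set_index("site").loc[sites, "bio4"])

    fg, pathway = _assign_groups(tree, cfg)
    species_eff = pd.Series(
        rng.normal(0.0, cfg.species_sd, len(pool)), index=pool
    )

    rows: list[dict] = []
    years = list(range(cfg.n_treatment_years + 1))  # year 0 = pretreatment
    for site in sites:
        chosen = sorted(rng.choice(pool, cfg.species_per_site, replace=False))
        bad = [sp for sp in chosen if sp in missing_gs]
        if bad:
            raise ConfigurationError(
                f"species without genome-size value at {site}: {bad}"
            )
        site_eff = rng.normal(0.0, cfg.site_sd)
        slope = (
            cfg.beta_gs_n
            + cfg.beta_gs_n_map * z_map[site]
            + cfg.beta_gs_n_tseas * z_tseas[site]
        )
        for b in range(1, cfg.blocks_per_site + 1):
            block = f"b{b}"
            block_eff = rng.normal(0.0, cfg.block_sd)
            assignment = rng.permutation(TREATMENTS)
            for p_idx, treat in enumerate(assignment, start=1):
                plot = f"p{p_idx}"
                n_add = int(treat in ("N", "NP"))
                p_add = int(treat in ("P", "NP"))
                base = cfg.total_cover_scale * rng.gamma(
                    2.0, cfg.mean_species_cover / 2.0, len(chosen)
                )
                log_gs = np.log(gs_by_species[chosen].to_numpy())
                delta_expect = (
                    slope * log_gs * n_add
                    + cfg.beta_gs_p * log_gs * p_add
                    + cfg.beta_gs_np * log_gs * n_add * p_add
                    + site_eff
                    + block_eff
                    + species_eff[chosen].to_numpy()
                )
                for year in years:
                    if year == 0:
                        level = base
                        year_type = "pretreatment"
                    else:
                        level = base + delta_expect
                        year_type = "treatment"
                    noise = (
                        rng.normal(0.0, cfg.cover_noise_sd, len(chosen))
                        if cfg.cover_noise_sd > 0
                        else 0.0
                    )
                    cover = np.maximum(level + noise, 0.0)
                    for sp, cv in zip(chosen, cover):
                        if cv > 0:
                            rows.append(
                                {
                                    "site": site,
                                    "block": block,
                                    "plot": plot,
                                    "year": year,
                                    "year_type": year_type,
                                    "n_added": n_add,
                                    "p_added": p_add,
                                    "species": sp,
                                    "functional_group": fg[sp],
                                    "pathway": pathway[sp],
                                    "percent_cover": float(cv),
                                }
                            )
    return pd.DataFrame(rows)


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigurationError(f"climate variable {x.name} is constant")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Whole-dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """One realized experiment plus its ground truth."""

    config: SyntheticConfig
    tree: Phylogeny
    gs_records: pd.DataFrame      # emitted record table (may be subsampled)
    gs_true: pd.Series            # true 1C per pool species (pg)
    climate: pd.DataFrame
    cover: pd.DataFrame
    plots: pd.DataFrame           # per-plot covariates (age, soils)


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate tree, genome sizes, climate, cover, and plot covariates."""
    cfg.validate()
    seeds = cfg.stream_seeds()
    tree = simulate_phylogeny(
        cfg.n_species_pool, cfg.birth_rate, seeds["phylogeny"]
    )
    log_gs = _true_log_gs(tree, cfg, seeds["genome_sizes"])
    gs_true = np.exp(log_gs).rename("c_value_1C")
    records = simulate_genome_sizes(tree, cfg, seeds["genome_sizes"])
    climate = simulate_climate(cfg.n_sites, seeds["climate"])
    full_gs = pd.DataFrame(
        {
            "species": gs_true.index,
            "site": "",
            "c_value_1C": gs_true.to_numpy(),
            "source": "database",
            "note": "",
        }
    )
    cover = simulate_cover(cfg, full_gs, climate, tree, seeds["cover"])

    rng = np.random.default_rng(seeds["cover"] + 1)
    plot_rows = []
    for (site, block, plot), grp in cover.groupby(
        ["site", "block", "plot"], sort=True
    ):
        plot_rows.append(
            {
                "site": site,
                "block": block,
                "plot": plot,
                "n_added": int(grp["n_added"].iloc[0]),
                "p_added": int(grp["p_added"].iloc[0]),
                "plot_age": int(rng.integers(2, 15)),
                "soil_n_pct": float(np.exp(rng.normal(-1.2, 0.4))),
                "soil_p_ppm": float(np.exp(rng.normal(3.5, 0.6))),
            }
        )
    plots = pd.DataFrame(plot_rows)
    return SyntheticDataset(
        config=cfg, tree=tree, gs_records=records, gs_true=gs_true,
        climate=climate, cover=cover, plots=plots,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all tables as tab-delimited text, the tree as Newick, and the
    configuration echo as YAML.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cover": outdir / "cover.tsv",
        "genome_sizes": outdir / "genome_sizes.tsv",
        "climate": outdir / "climate.tsv",
        "plots": outdir / "plots.tsv",
        "tree": outdir / "tree.nwk",
        "config": outdir / "config.yaml",
    }
    ds.cover.to_csv(paths["cover"], sep="\t", index=False)
    ds.gs_records.to_csv(paths["genome_sizes"], sep="\t", index=False)
    ds.climate.to_csv(paths["climate"], sep="\t", index=False)
    ds.plots.to_csv(paths["plots"], sep="\t", index=False)
    paths["tree"].write_text(ds.tree.to_newick() + "\n")
    paths["config"].write_text(
        yaml.safe_dump(dataclasses.asdict(ds.config), sort_keys=False)
    )
    return paths
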