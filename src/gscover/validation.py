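"""Replicated validation experiments over the synthetic generator.

Each experiment runs the full analysis chain (simulate → resolve genome
sizes → community metrics → model fit) many times under known ground truth
and summarizes how well the estimators recover it:

* ``lambda_recovery_experiment`` — Pagel's lambda on traits simulated with
  no signal and with pure Brownian signal;
* ``k_calibration_experiment``   — Blomberg's K under Brownian evolution
  (expectation 1);
* ``gsxn_recovery_experiment``   — the species-level phylogenetic mixed
  model's log(GS) x N slope against the generator's true value, with Wald
  interval coverage;
* ``type1_error_experiment``     — rejection rate of the log(GS) x N test
  when every genome-size effect is zero;
* ``directional_experiment``     — the qualitative pattern: nitrogen
  raises cover-weighted genome size, and a negative precipitation modifier
  surfaces as a negative N x precipitation interaction;
* ``cwgs_oracle_check`` / ``lrr_identity_check`` — exact numerical
  contracts of the plot statistics.

Replicate problem sizes are chosen per experiment (see each default) so a
full validation sweep stays desk-scale; seeds derive deterministically
from one master seed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .community import (
    cover_weighted_gs,
    delta_cover,
    delta_cwgs,
    lrr_control_vs_treatment,
    lrr_pre_vs_treatment,
    mean_cover_recent,
    plot_cwgs,
    pretreatment_cover,
)
from .climate import zscore_columns
from .genome_size import resolve_genome_size
from .inference import fit_phylo_mixed, run_climate_interaction_model, treatment_cell
from .phylo import blombergs_K, bm_covariance, pagels_lambda
from .synthetic import SyntheticConfig, simulate_dataset, simulate_phylogeny

__all__ = [
    "lambda_recovery_experiment",
    "k_calibration_experiment",
    "gsxn_recovery_experiment",
    "type1_error_experiment",
    "directional_experiment",
    "cwgs_oracle_check",
    "lrr_identity_check",
]


def _rep_seeds(seed: int, n: int, salt: int) -> list[int]:
    state = np.random.SeedSequence([seed, salt]).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _analysis_tables(ds):
    """Resolve genome sizes and build the species-level change table and
    plot-level cwGS response ratios for one simulated dataset."""
    cover = ds.cover
    needed = set(zip(cover["species"], cover["site"]))
    resolved, _ = resolve_genome_size(ds.gs_records, needed)
    pre = pretreatment_cover(cover)
    rec = mean_cover_recent(cover)
    sd = delta_cover(rec, pre, resolved_gs=resolved).dropna(subset=["log_gs"])
    cw = plot_cwgs(pre, rec, resolved)
    lrr = delta_cwgs(cw)
    return resolved, sd, lrr


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def lambda_recovery_experiment(
    seed: int, n_reps: int = 100, n_tips: int = 200
) -> dict[str, float]:
    """Mean lambda estimate under true lambda = 0 (iid trait) and
    lambda = 1 (Brownian trait)."""
    out = {}
    for true_lam, salt in ((0.0, 1), (1.0, 2)):
        seeds = _rep_seeds(seed, n_reps, salt)
        vals = []
        for s in seeds:
            tree = simulate_phylogeny(n_tips, 1.0, s)
            rng = np.random.default_rng(s + 1)
            if true_lam == 1.0:
                C = bm_covariance(tree).to_numpy()
                y = np.linalg.cholesky(C) @ rng.standard_normal(n_tips)
            else:
                y = rng.standard_normal(n_tips)
            trait = pd.Series(y, index=tree.tip_labels)
            vals.append(pagels_lambda(tree, trait).value)
        out[f"mean_lambda_hat_true{int(true_lam)}"] = float(np.mean(vals))
    return out


def k_calibration_experiment(
    seed: int, n_reps: int = 200, n_tips: int = 200
) -> dict[str, float]:
    """Mean Blomberg's K over Brownian simulations (expectation 1)."""
    vals = []
    for s in _rep_seeds(seed, n_reps, 3):
        tree = simulate_phylogeny(n_tips, 1.0, s)
        rng = np.random.default_rng(s + 1)
        C = bm_covariance(tree).to_numpy()
        y = np.linalg.cholesky(C) @ rng.standard_normal(n_tips)
        trait = pd.Series(y, index=tree.tip_labels)
        vals.append(blombergs_K(tree, trait, n_perm=99, seed=s).value)
    return {"mean_K_bm": float(np.mean(vals))}


# ---------------------------------------------------------------------------
# Species-level mixed model
# ---------------------------------------------------------------------------

#: Replicate experiment sizes: deliberately smaller than the default
#: (27-site) generator so hundreds of replicates stay desk-scale, while
#: keeping the factorial block design and a phylogeny of realistic depth.
RECOVERY_CONFIG = dict(
    n_sites=10, blocks_per_site=2, n_species_pool=80, species_per_site=15,
)
TYPE1_CONFIG = dict(
    n_sites=8, blocks_per_site=2, n_species_pool=60, species_per_site=12,
)


def gsxn_recovery_experiment(
    seed: int, n_reps: int = 200, true_slope: float = 1.0
) -> dict[str, float]:
    """Recovery of the log(GS) x N slope and 95%-interval coverage."""
    ests, covered = [], 0
    for s in _rep_seeds(seed, n_reps, 4):
        cfg = SyntheticConfig(
            beta_gs_n=true_slope, beta_gs_n_map=0.0, beta_gs_n_tseas=0.0,
            seed=s, **RECOVERY_CONFIG,
        )
        ds = simulate_dataset(cfg)
        _, sd, _ = _analysis_tables(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_phylo_mixed(sd, ds.tree)
        row = fit.params.loc["log_gs:n_added"]
        ests.append(float(row["estimate"]))
        covered += int(row["ci_low"] <= true_slope <= row["ci_high"])
    return {
        "mean_gsxn_slope": float(np.mean(ests)),
        "gsxn_ci_coverage": covered / n_reps,
    }


def type1_error_experiment(seed: int, n_reps: int = 500) -> dict[str, float]:
    """Rejection rate of the log(GS) x N Wald test at alpha = 0.05 when all
    genome-size effects are zero."""
    rej = 0
    for s in _rep_seeds(seed, n_reps, 5):
        cfg = SyntheticConfig(
            beta_gs_n=0.0, beta_gs_n_map=0.0, beta_gs_n_tseas=0.0,
            seed=s, **TYPE1_CONFIG,
        )
        ds = simulate_dataset(cfg)
        _, sd, _ = _analysis_tables(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_phylo_mixed(sd, ds.tree)
        rej += int(fit.params.loc["log_gs:n_added", "p"] < 0.05)
    return {"type1_error_rate": rej / n_reps}


# ---------------------------------------------------------------------------
# Plot-level directional pattern
# ---------------------------------------------------------------------------

def directional_experiment(seed: int, n_reps: int = 100) -> dict[str, float]:
    """Qualitative end-to-end pattern under the default effect sizes
    (positive GS x N slope, negative precipitation modifier).

    Uses the default 27-site generator with the replication level at the
    top of the 2-6 block design range, so each replicate carries the full
    between-site climate gradient.
    """
    n_neg, n_dir = 0, 0
    diffs_n, diffs_np = [], []
    for s in _rep_seeds(seed, n_reps, 6):
        cfg = SyntheticConfig(blocks_per_site=6, seed=s)
        ds = simulate_dataset(cfg)
        _, _, lrr = _analysis_tables(ds)
        dat = lrr[lrr["contrast"] == "control_vs_treatment"].copy()
        z = zscore_columns(ds.climate[["bio1", "bio12", "bio4", "bio15"]])
        z.columns = ["z_mat", "z_map", "z_tseas", "z_pseas"]
        dat = dat.merge(
            pd.concat([ds.climate[["site"]], z], axis=1), on="site"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_climate_interaction_model(dat)
        n_neg += int(fit.params.loc["n_added:z_map", "estimate"] < 0)
        cm = dat.groupby(treatment_cell(dat))["lrr"].mean()
        diffs_n.append(cm["N"] - cm["control"])
        diffs_np.append(cm["NP"] - cm["control"])
        n_dir += int(cm["N"] > cm["control"] and cm["NP"] > cm["control"])
    return {
        "frac_negative_n_precip": n_neg / n_reps,
        "frac_n_and_np_above_control": n_dir / n_reps,
        "mean_delta_cwgs_n_minus_control": float(np.mean(diffs_n)),
        "mean_delta_cwgs_np_minus_control": float(np.mean(diffs_np)),
    }


# ---------------------------------------------------------------------------
# Exact numerical contracts
# ---------------------------------------------------------------------------

def cwgs_oracle_check(
    seed: int, n_plots: int = 1000, max_species: int = 12
) -> dict[str, float]:
    """Maximum absolute deviation of cwGS from the brute-force weighted
    geometric mean over random plots."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_plots):
        n = int(rng.integers(1, max_species + 1))
        gs = {f"s{i}": float(v) for i, v in enumerate(rng.lognormal(0.4, 1.0, n))}
        covers = [(f"s{i}", float(c)) for i, c in enumerate(rng.uniform(0.1, 60, n))]
        total = sum(c for _, c in covers)
        oracle = math.exp(sum((c / total) * math.log(gs[s]) for s, c in covers))
        worst = max(worst, abs(cover_weighted_gs(covers, gs) - oracle))
    return {"cwgs_oracle_max_abs_err": worst}


def lrr_identity_check(seed: int, n_triples: int = 200) -> dict[str, float]:
    """Largest deviation from the exact response-ratio identities:
    zero at equality, antisymmetry, and log-additivity."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_triples):
        a, b, c = rng.lognormal(0.0, 1.0, 3)
        worst = max(
            worst,
            abs(lrr_control_vs_treatment(a, [a])),
            abs(
                lrr_control_vs_treatment(a, [b])
                + lrr_control_vs_treatment(b, [a])
            ),
            abs(
                lrr_pre_vs_treatment(c, a)
                - (lrr_pre_vs_treatment(c, b) + lrr_pre_vs_treatment(b, a))
            ),
        )
    return {"lrr_identity_max_abs_err": worst}
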