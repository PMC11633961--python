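"""Likelihood-based mixed-model inference.

All models are Gaussian linear mixed models

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma_k^2 G_k),
    eps ~ N(0, sigma_e^2 I),

fitted by REML (ML optional).  Three model families are built on one
engine:

* plot-level models of the cwGS log response ratio with random intercepts
  for site and block-within-site, including the nutrient x climate
  interaction model with its conventional 19-row fixed-effect ANOVA
  layout;
* post hoc plot-level models (plot age, pretreatment soils) expressed as
  ordinary term lists over the same engine;
* the species-level phylogenetic mixed model of cover change, where one
  random term is the species effect with covariance proportional to the
  phylogenetic correlation matrix (plus, by default, an independent
  species effect).

The species-level model is a deliberate frequentist re-cast of a Bayesian
phylogenetic regression: REML variance components, GLS fixed effects, and
Wald intervals replace MCMC.  With weak priors the point estimates are
expected to be close, but no equivalence with a posterior is claimed; every
report carries this note.

Inference detail: variance ratios are profiled out of the REML criterion
via the Woodbury identity (the inner solve is per random level, never per
observation), the criterion is minimized deterministically from fixed
starting values, and denominator degrees of freedom use a
Satterthwaite-style approximation with finite-difference derivatives of
the coefficient covariance with respect to the variance parameters.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny, bm_covariance

__all__ = [
    "ModelSpec",
    "ModelFit",
    "TukeyResult",
    "fit_lmm",
    "tukey_hsd",
    "fit_phylo_mixed",
    "run_climate_interaction_model",
    "treatment_cell",
    "CLIMATE_ANOVA_LABELS",
    "ConvergenceError",
]

METHOD_NOTE = (
    "REML/GLS fit with Wald intervals; Satterthwaite-style denominator df. "
    "Species-level phylogenetic models re-cast a Bayesian formulation as "
    "likelihood-based; equivalence with a posterior is not claimed."
)


class ConvergenceError(RuntimeError):
    """The REML optimizer failed to converge."""


# ---------------------------------------------------------------------------
# Design construction from declarative term lists
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists main effects and interactions as colon-joined column
    names (e.g. ``"log_gs:n_added"``); categorical columns are dummy-coded
    against their first (sorted) level.  ``random`` lists grouping columns
    for iid random intercepts; nesting is written with a colon
    (``"site:block"`` groups by the site-block combination).
    """

    response: str
    fixed: list[str]
    random: list[str] = field(default_factory=list)
    estimation: str = "reml"

    def __post_init__(self) -> None:
        if self.estimation not in ("reml", "ml"):
            raise ValueError("estimation must be 'reml' or 'ml'")


def _term_block(data: pd.DataFrame, var: str) -> pd.DataFrame:
    """Columns for one base variable: itself if numeric, else dummies."""
    col = data[var]
    if np.issubdtype(col.dtype, np.number):
        return pd.DataFrame({var: col.to_numpy(dtype=float)})
    levels = sorted(col.astype(str).unique())
    block = {}
    for lev in levels[1:]:
        block[f"{var}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
    return pd.DataFrame(block)


def build_design(
    data: pd.DataFrame, fixed: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]], dict[str, list[str]]]:
    """Build the fixed-effects design matrix with an intercept.

    Returns (X, column names, term -> columns map, categorical variable ->
    sorted levels).  Every interaction must reference columns present in
    ``data``; rank deficiency raises with the aliased columns named.
    """
    cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(data))}
    term_map: dict[str, list[str]] = {}
    cat_levels: dict[str, list[str]] = {}
    for term in fixed:
        parts = term.split(":")
        for v in parts:
            if v not in data.columns:
                raise ValueError(f"term {term!r} references missing column {v!r}")
            if not np.issubdtype(data[v].dtype, np.number):
                cat_levels[v] = sorted(data[v].astype(str).unique())
        blocks = [_term_block(data, v) for v in parts]
        names_here = []
        for combo in itertools.product(*(b.columns for b in blocks)):
            name = ":".join(combo)
            prod = np.ones(len(data))
            for b, c in zip(blocks, combo):
                prod = prod * b[c].to_numpy()
            cols[name] = prod
            names_here.append(name)
        term_map[term] = names_here
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, R, piv = _qr_pivot(X)
        tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        aliased = [names[piv[i]] for i in range(X.shape[1]) if abs(R[i, i]) < tol]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names, term_map, cat_levels


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, mode="economic", pivoting=True)


def treatment_cell(data: pd.DataFrame) -> pd.Series:
    """Derive the 4-level treatment factor from the (n_added, p_added) pair."""
    lut = {(0, 0): "control", (1, 0): "N", (0, 1): "P", (1, 1): "NP"}
    return pd.Series(
        [lut[(int(n), int(p))] for n, p in zip(data["n_added"], data["p_added"])],
        index=data.index,
        name="treatment",
    )


# ---------------------------------------------------------------------------
# Core REML engine
# ---------------------------------------------------------------------------

class _RandomPart:
    """One random term: indicator matrix Z and covariance factor L
    (G = L L'; L is None for an identity covariance)."""

    def __init__(self, name: str, Z: np.ndarray, L: np.ndarray | None):
        self.name = name
        self.Z = Z
        self.L = L
        self.ZL = Z if L is None else Z @ L
        self.m = Z.shape[1]


def _indicator(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(groups.astype(str).unique())
    idx = {g: i for i, g in enumerate(levels)}
    Z = np.zeros((len(groups), len(levels)))
    for row, g in enumerate(groups.astype(str)):
        Z[row, idx[g]] = 1.0
    return Z, levels


class _LMMEngine:
    """Dense-Woodbury REML/ML fitter for a handful of variance components.

    All n-dependent cross-products are formed once at construction; each
    likelihood evaluation then costs O(m^3) in the total number of random
    levels m, independent of the number of observations.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        parts: list[_RandomPart],
        reml: bool = True,
    ):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.parts = parts
        self.reml = reml
        self.n, self.p = self.X.shape
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        # precomputed cross-products (U = concat of Z_k L_k blocks)
        if parts:
            U = np.hstack([p.ZL for p in parts])
            self._UtU = U.T @ U
            self._UtX = U.T @ self.X
            self._Uty = U.T @ self.y
            self._block_slices = []
            start = 0
            for p_ in parts:
                self._block_slices.append(slice(start, start + p_.m))
                start += p_.m
            self._m = start
        else:
            self._m = 0
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    # -- likelihood pieces ---------------------------------------------------
    def _solve_pieces(self, gammas: np.ndarray):
        """GLS pieces at variance ratios gamma_k = sigma_k^2 / sigma_e^2."""
        if self.parts and np.any(gammas > 0):
            s = np.concatenate(
                [
                    np.full(p_.m, math.sqrt(max(g, 0.0)))
                    for g, p_ in zip(gammas, self.parts)
                ]
            )
            M = self._UtU * np.outer(s, s)
            M[np.diag_indices_from(M)] += 1.0
            cho_M = cho_factor(M, lower=True, check_finite=False)
            logdetV0 = 2.0 * np.sum(np.log(np.diag(cho_M[0])))
            WtX = s[:, None] * self._UtX
            Wty = s * self._Uty
            MiWtX = cho_solve(cho_M, WtX, check_finite=False)
            XtVX = self._XtX - WtX.T @ MiWtX
            XtVy = self._Xty - MiWtX.T @ Wty
            yVy = self._yty - float(
                Wty @ cho_solve(cho_M, Wty, check_finite=False)
            )
        else:
            logdetV0 = 0.0
            XtVX = self._XtX
            XtVy = self._Xty
            yVy = self._yty
        cho_B = cho_factor(XtVX, lower=True, check_finite=False)
        beta = cho_solve(cho_B, XtVy, check_finite=False)
        quad = float(yVy - beta @ XtVy)
        logdetB = 2.0 * np.sum(np.log(np.diag(cho_B[0])))
        return beta, XtVX, quad, logdetV0, logdetB

    def _neg2_profile(self, log_gammas: np.ndarray) -> float:
        gammas = np.exp(np.clip(log_gammas, -30.0, 30.0))
        try:
            _, _, quad, logdetV0, logdetB = self._solve_pieces(gammas)
        except np.linalg.LinAlgError:
            return 1e12
        if quad <= 0:
            return 1e12
        if self.reml:
            dof = self.n - self.p
            s2 = quad / dof
            return dof * math.log(s2) + logdetV0 + logdetB + dof
        s2 = quad / self.n
        return self.n * math.log(s2) + logdetV0 + quad / s2

    def neg2_at_variances(self, variances: np.ndarray) -> float:
        """-2 log (restricted) likelihood on the natural variance scale
        (sigma_1^2 ... sigma_K^2, sigma_e^2), beta profiled by GLS."""
        *sig2s, s2e = variances
        if s2e <= 0 or any(s < 0 for s in sig2s):
            return 1e12
        gammas = np.array([s / s2e for s in sig2s])
        _, _, quad, logdetV0, logdetB = self._solve_pieces(gammas)
        val = (
            self.n * math.log(s2e)
            + logdetV0
            + quad / s2e
            + self.n * math.log(2.0 * math.pi)
        )
        if self.reml:
            val += logdetB - self.p * math.log(s2e)
        return val

    # -- fitting --------------------------------------------------------------
    def fit(self) -> None:
        k = len(self.parts)
        if k == 0:
            self.log_gammas = np.array([])
        elif k == 1:
            res = optimize.minimize_scalar(
                lambda t: self._neg2_profile(np.array([t])),
                bounds=(-14.0, 14.0),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if not res.success:  # pragma: no cover - bounded Brent converges
                raise ConvergenceError(res.message)
            self.log_gammas = np.array([float(res.x)])
        else:
            # smooth low-dimensional surface: quasi-Newton with numerical
            # gradients, deterministic from a fixed start; simplex fallback
            res = optimize.minimize(
                self._neg2_profile,
                x0=np.zeros(k),
                method="L-BFGS-B",
                bounds=[(-14.0, 14.0)] * k,
                options={"ftol": 1e-12, "gtol": 1e-7, "eps": 1e-6,
                         "maxiter": 500},
            )
            if not res.success:
                res = optimize.minimize(
                    self._neg2_profile,
                    x0=np.zeros(k),
                    method="Nelder-Mead",
                    options={
                        "xatol": 1e-5, "fatol": 1e-9,
                        "maxiter": 4000, "maxfev": 4000,
                    },
                )
                if not res.success:
                    raise ConvergenceError(str(res.message))
            self.log_gammas = np.asarray(res.x, float)

        gammas = np.exp(self.log_gammas)
        beta, XtVX, quad, logdetV0, logdetB = self._solve_pieces(gammas)
        dof = self.n - self.p if self.reml else self.n
        self.sigma2_e = quad / dof
        self.sigma2_parts = gammas * self.sigma2_e
        self.beta = beta
        self.vcov = self.sigma2_e * np.linalg.inv(XtVX)
        self.neg2ll = self._neg2_profile(self.log_gammas)
        self.singular = bool(np.any(gammas < 1e-6) or np.any(gammas > 1e6))
        self._theta_hat = np.append(self.sigma2_parts, self.sigma2_e)
        self._theta_cov: np.ndarray | None = None
        self._vcov_grads: list[np.ndarray] | None = None

    # -- Satterthwaite machinery ----------------------------------------------
    def _vcov_at(self, variances: np.ndarray) -> np.ndarray:
        *sig2s, s2e = variances
        gammas = np.array([max(s, 0.0) / s2e for s in sig2s])
        _, XtVX, _, _, _ = self._solve_pieces(gammas)
        return s2e * np.linalg.inv(XtVX)

    def _variance_param_cov(self) -> np.ndarray:
        """Asymptotic covariance of the variance parameters: twice the
        inverse Hessian of -2 l_R, by central finite differences."""
        if self._theta_cov is not None:
            return self._theta_cov
        th = self._theta_hat
        q = len(th)
        h = np.maximum(1e-6, 1e-4 * np.abs(th))
        H = np.zeros((q, q))
        f0 = self.neg2_at_variances(th)
        for i in range(q):
            for j in range(i, q):
                ei = np.zeros(q); ei[i] = h[i]
                ej = np.zeros(q); ej[j] = h[j]
                if i == j:
                    fp = self.neg2_at_variances(th + ei)
                    fm = self.neg2_at_variances(th - ei)
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    fpp = self.neg2_at_variances(th + ei + ej)
                    fpm = self.neg2_at_variances(th + ei - ej)
                    fmp = self.neg2_at_variances(th - ei + ej)
                    fmm = self.neg2_at_variances(th - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                        4 * h[i] * h[j]
                    )
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(H)
        self._theta_cov = cov
        return cov

    def _vcov_derivatives(self) -> list[np.ndarray]:
        """d vcov(beta) / d theta_j at the estimate, by central differences;
        computed once and shared by every contrast."""
        if self._vcov_grads is not None:
            return self._vcov_grads
        th = self._theta_hat
        h = np.maximum(1e-6, 1e-4 * np.abs(th))
        grads = []
        for i in range(len(th)):
            e = np.zeros(len(th)); e[i] = h[i]
            vp = self._vcov_at(th + e)
            vm = self._vcov_at(np.maximum(th - e, 1e-12))
            grads.append((vp - vm) / (2 * h[i]))
        self._vcov_grads = grads
        return grads

    def contrast_df(self, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast c'beta."""
        var_c = float(c @ self.vcov @ c)
        if var_c <= 0:
            return float(self.n - self.p)
        grad = np.array([float(c @ D @ c) for D in self._vcov_derivatives()])
        denom = float(grad @ self._variance_param_cov() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)
        df = 2.0 * var_c**2 / denom
        if not np.isfinite(df) or df < 1.0:
            return 1.0
        return min(df, float(self.n - self.p))


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Mixed-model fit: coefficients, ANOVA, variance components."""

    params: pd.DataFrame          # estimate, se, df, t, p, ci_low, ci_high
    anova: pd.DataFrame           # sum_sq, mean_sq, df_num, df_den, F, p
    varcomps: pd.Series           # one entry per random term + residual
    marginal_r2: float
    loglik: float                 # (restricted) log-likelihood
    n_obs: int
    converged: bool
    singular: bool
    method_note: str = METHOD_NOTE
    term_map: dict[str, list[str]] = field(default_factory=dict)
    cat_levels: dict[str, list[str]] = field(default_factory=dict)
    _engine: "_LMMEngine | None" = field(default=None, repr=False)
    _colnames: list[str] = field(default_factory=list, repr=False)

    def coefficient(self, name: str) -> pd.Series:
        return self.params.loc[name]


def _summarize_fit(
    engine: _LMMEngine,
    colnames: list[str],
    term_map: dict[str, list[str]],
    part_names: list[str],
    cat_levels: dict[str, list[str]] | None = None,
    conf_level: float = 0.95,
) -> ModelFit:
    beta, vcov = engine.beta, engine.vcov
    p = len(beta)
    rows = []
    for j, name in enumerate(colnames):
        c = np.zeros(p); c[j] = 1.0
        se = math.sqrt(max(vcov[j, j], 0.0))
        df = engine.contrast_df(c)
        t = beta[j] / se if se > 0 else np.nan
        pval = 2.0 * stats.t.sf(abs(t), df) if se > 0 else np.nan
        tq = stats.t.ppf(0.5 + conf_level / 2.0, df)
        rows.append(
            {
                "estimate": beta[j], "se": se, "df": df, "t": t, "p": pval,
                "ci_low": beta[j] - tq * se, "ci_high": beta[j] + tq * se,
            }
        )
    params = pd.DataFrame(rows, index=colnames)

    # marginal Wald F-tests per term (Type-III style)
    anova_rows = []
    for term, cols in term_map.items():
        idx = [colnames.index(c) for c in cols]
        L = np.zeros((len(idx), p))
        for r_i, j in enumerate(idx):
            L[r_i, j] = 1.0
        Q = L @ vcov @ L.T
        b = L @ beta
        q = len(idx)
        try:
            F = float(b @ np.linalg.solve(Q, b)) / q
        except np.linalg.LinAlgError:
            F = np.nan
        if q == 1:
            df_den = engine.contrast_df(L[0])
        else:
            # eigen-split the multi-df hypothesis into independent
            # 1-df contrasts and pool their Satterthwaite dfs
            eigval, eigvec = np.linalg.eigh(Q)
            dfs = []
            for vi in range(q):
                if eigval[vi] <= 1e-12:
                    continue
                cvec = eigvec[:, vi] @ L
                dfs.append(engine.contrast_df(cvec))
            nu = np.array(dfs)
            E = float(np.sum(nu / (nu - 2.0))) if np.all(nu > 2) else np.nan
            df_den = (
                2.0 * E / (E - q) if np.isfinite(E) and E > q else engine.n - p
            )
        p_f = float(stats.f.sf(F, q, df_den)) if np.isfinite(F) else np.nan
        anova_rows.append(
            {
                "term": term,
                "sum_sq": F * q * engine.sigma2_e if np.isfinite(F) else np.nan,
                "mean_sq": F * engine.sigma2_e if np.isfinite(F) else np.nan,
                "df_num": q,
                "df_den": df_den,
                "F": F,
                "p": p_f,
            }
        )
    anova = pd.DataFrame(anova_rows).set_index("term")

    fixed_pred = engine.X @ beta
    var_f = float(np.var(fixed_pred, ddof=0))
    total = var_f + float(np.sum(engine.sigma2_parts)) + engine.sigma2_e
    varcomps = pd.Series(
        list(engine.sigma2_parts) + [engine.sigma2_e],
        index=part_names + ["residual"],
    )
    if engine.singular:
        warnings.warn(
            "singular fit: a variance component is at the boundary",
            stacklevel=3,
        )
    return ModelFit(
        params=params,
        anova=anova,
        varcomps=varcomps,
        marginal_r2=var_f / total,
        loglik=-0.5 * engine.neg2ll,
        n_obs=engine.n,
        converged=True,
        singular=engine.singular,
        term_map=term_map,
        cat_levels=cat_levels or {},
        _engine=engine,
        _colnames=colnames,
    )


# ---------------------------------------------------------------------------
# Public model fits
# ---------------------------------------------------------------------------

def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a linear mixed model from a declarative spec.

    Random terms are iid random intercepts over the named grouping columns
    (``"site:block"`` nests block within site by grouping on the pair).
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    y = data[spec.response].to_numpy(dtype=float)
    X, colnames, term_map, cat_levels = build_design(data, spec.fixed)
    parts = []
    for rterm in spec.random:
        cols = rterm.split(":")
        for c in cols:
            if c not in data.columns:
                raise ValueError(f"random term {rterm!r} missing column {c!r}")
        key = data[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + "/" + data[c].astype(str)
        Z, _ = _indicator(key)
        parts.append(_RandomPart(rterm, Z, None))
    engine = _LMMEngine(y, X, parts, reml=spec.estimation == "reml")
    engine.fit()
    return _summarize_fit(
        engine, colnames, term_map, [p.name for p in parts], cat_levels
    )


@dataclass
class TukeyResult:
    """All pairwise treatment contrasts with studentized-range adjustment."""

    contrasts: pd.DataFrame   # level_a, level_b, diff, se, q, df, p_adj
    letters: dict[str, str]   # compact letter display per level
    means: pd.Series
    means_ci: pd.DataFrame    # mean, se, ci_low, ci_high per level
    alpha: float = 0.05


def tukey_hsd(
    fit: ModelFit, factor: str, alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD contrasts for a categorical term of a fitted model.

    The factor's cell means are the model-based (LS) means at the
    reference level of every other term; p-values use the studentized
    range distribution with Satterthwaite df per contrast; the compact
    letter display uses the insertion–absorption algorithm.
    """
    if factor not in fit.term_map:
        raise ValueError(
            f"factor {factor!r} not a term of this fit: {list(fit.term_map)}"
        )
    engine = fit._engine
    colnames = fit._colnames
    dummy_cols = fit.term_map[factor]
    levels_from_cols = [c[c.index("[") + 1: c.index("]")] for c in dummy_cols]
    if factor not in fit.cat_levels:
        raise ValueError(f"factor {factor!r} is not categorical in this fit")
    ref = fit.cat_levels[factor][0]  # build_design drops the first level
    p = len(colnames)
    base = np.zeros(p)
    base[colnames.index("(intercept)")] = 1.0
    cvecs = {ref: base}
    for col, lev in zip(dummy_cols, levels_from_cols):
        v = base.copy()
        v[colnames.index(col)] = 1.0
        cvecs[lev] = v

    means = pd.Series({lev: float(v @ engine.beta) for lev, v in cvecs.items()})
    ci_rows = {}
    for lev, v in cvecs.items():
        se_m = math.sqrt(max(float(v @ engine.vcov @ v), 0.0))
        df_m = engine.contrast_df(v)
        tq = stats.t.ppf(0.975, df_m)
        ci_rows[lev] = {
            "mean": means[lev], "se": se_m,
            "ci_low": means[lev] - tq * se_m,
            "ci_high": means[lev] + tq * se_m,
        }
    means_ci = pd.DataFrame(ci_rows).T
    k = len(cvecs)
    rows = []
    sig_pairs = []
    for (la, va), (lb, vb) in itertools.combinations(cvecs.items(), 2):
        d = va - vb
        diff = float(d @ engine.beta)
        se = math.sqrt(max(float(d @ engine.vcov @ d), 0.0))
        df = engine.contrast_df(d)
        qstat = abs(diff) / se * math.sqrt(2.0) if se > 0 else np.nan
        p_adj = float(stats.studentized_range.sf(qstat, k, df))
        p_adj = min(1.0, p_adj)
        rows.append(
            {
                "level_a": la, "level_b": lb, "diff": diff, "se": se,
                "q": qstat, "df": df, "p_adj": p_adj,
            }
        )
        if p_adj < alpha:
            sig_pairs.append((la, lb))
    contrasts = pd.DataFrame(rows)

    letters = _compact_letter_display(list(cvecs.keys()), sig_pairs, means)
    return TukeyResult(
        contrasts=contrasts, letters=letters, means=means,
        means_ci=means_ci, alpha=alpha,
    )


def _compact_letter_display(
    levels: list[str],
    significant_pairs: list[tuple[str, str]],
    means: pd.Series,
) -> dict[str, str]:
    """Insertion–absorption compact letter display."""
    groups: list[set[str]] = [set(levels)]
    for a, b in significant_pairs:
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    # assign letters in order of ascending group mean
    groups.sort(key=lambda g: min(means[lev] for lev in g))
    letters = {lev: "" for lev in levels}
    for letter, g in zip(string.ascii_lowercase, groups):
        for lev in sorted(g):
            letters[lev] += letter
    return letters


# ---------------------------------------------------------------------------
# Species-level phylogenetic mixed model
# ---------------------------------------------------------------------------

SPECIES_MODEL_FIXED = [
    "n_added",
    "p_added",
    "n_added:p_added",
    "log_gs",
    "log_gs:n_added",
    "log_gs:p_added",
    "log_gs:n_added:p_added",
]


def fit_phylo_mixed(
    data: pd.DataFrame,
    tree: Phylogeny,
    fixed: Sequence[str] | None = None,
    response: str = "delta_cover",
    include_iid_species: bool = True,
    include_design_random: bool = True,
    estimation: str = "reml",
) -> ModelFit:
    """Species-level mixed model of cover change with a phylogenetic
    random effect.

    The species random effect has covariance ``sigma_p^2 * A`` where A is
    the phylogenetic correlation matrix (the Brownian covariance of the
    tree pruned to the observed species, scaled to unit diagonal).  By
    default an independent species intercept is included as well
    (``include_iid_species=False`` drops it), and — when the plot key
    columns are present — random intercepts for block within site and for
    plot, mirroring the experimental design.  Omitting the design terms
    treats correlated within-plot and within-block cover shifts as
    independent noise and distorts the precision of the treatment
    contrasts.  Fixed effects default to the three-way nutrient x log(GS)
    structure.
    """
    if estimation not in ("reml", "ml"):
        raise ValueError("estimation must be 'reml' or 'ml'")
    fixed = list(fixed) if fixed is not None else list(SPECIES_MODEL_FIXED)
    species = sorted(data["species"].astype(str).unique())
    if len(species) < 20:
        raise ValueError("phylogenetic mixed model needs >= 20 species")
    missing = [s for s in species if s not in set(tree.tip_labels)]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    if data[response].isna().any():
        raise ValueError("response contains missing values")
    if "log_gs" in "".join(fixed) and data["log_gs"].isna().any():
        bad = sorted(data.loc[data["log_gs"].isna(), "species"].unique())
        raise ValueError(f"log_gs missing for species: {bad}")

    sub = tree.prune(species) if len(species) < tree.n_tips else tree
    C = bm_covariance(sub)
    C = C.loc[species, species].to_numpy()
    d = np.sqrt(np.diag(C))
    A = C / np.outer(d, d)
    try:
        L_A = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance is not positive definite") from exc

    y = data[response].to_numpy(dtype=float)
    X, colnames, term_map, cat_levels = build_design(data, fixed)
    Z, _ = _indicator(data["species"])
    # _indicator sorts levels, matching the sorted `species` list
    parts = [_RandomPart("species_phylo", Z, L_A)]
    if include_iid_species:
        parts.append(_RandomPart("species_iid", Z, None))
    if include_design_random and {"site", "block", "plot"} <= set(data.columns):
        blk = data["site"].astype(str) + "/" + data["block"].astype(str)
        Zb, _ = _indicator(blk)
        parts.append(_RandomPart("site:block", Zb, None))
        Zp, _ = _indicator(blk + "/" + data["plot"].astype(str))
        parts.append(_RandomPart("plot", Zp, None))
    engine = _LMMEngine(y, X, parts, reml=estimation == "reml")
    engine.fit()
    return _summarize_fit(
        engine, colnames, term_map, [p.name for p in parts], cat_levels
    )


# ---------------------------------------------------------------------------
# Climate-interaction model of the cwGS response ratio
# ---------------------------------------------------------------------------

#: Fixed-effect term -> conventional display label, in display order.
CLIMATE_ANOVA_LABELS = {
    "n_added": "N added",
    "p_added": "P added",
    "n_added:p_added": "N added: P added",
    "z_mat": "Mean Temperature",
    "z_map": "Mean Precipitation",
    "z_tseas": "Temperature Seasonality",
    "z_pseas": "Precipitation Seasonality",
    "n_added:z_mat": "N: Temperature",
    "p_added:z_mat": "P: Temperature",
    "n_added:p_added:z_mat": "N and P: Temperature",
    "n_added:z_map": "N: Precipitation",
    "p_added:z_map": "P: Precipitation",
    "n_added:p_added:z_map": "N and P: Precipitation",
    "n_added:z_tseas": "N: Temp. Seasonality",
    "p_added:z_tseas": "P: Temp. Seasonality",
    "n_added:p_added:z_tseas": "N and P: Temp. Seasonality",
    "n_added:z_pseas": "N: Precip. Seasonality",
    "p_added:z_pseas": "P: Precip. Seasonality",
    "n_added:p_added:z_pseas": "N and P: Precip. Seasonality",
}


def run_climate_interaction_model(data: pd.DataFrame) -> ModelFit:
    """Mixed model of the cwGS log response ratio with nutrient x climate
    interactions.

    ``data`` holds one row per plot with columns ``lrr, n_added, p_added``,
    the z-scored climate columns ``z_mat, z_map, z_tseas, z_pseas`` (mean
    0, SD 1 across sites), and the grouping columns ``site, block``.
    Fixed effects are the nutrient main effects and interaction, the four
    climate main effects, and every nutrient x climate two- and three-way
    interaction (19 single-df rows); random intercepts for site and block
    within site.  The ANOVA index uses the conventional printed labels.
    """
    needed = ["lrr", "n_added", "p_added", "site", "block",
              "z_mat", "z_map", "z_tseas", "z_pseas"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"climate-interaction model missing columns: {missing}")
    for zc in ("z_mat", "z_map", "z_tseas", "z_pseas"):
        site_z = data.drop_duplicates("site")[zc]
        if abs(site_z.mean()) > 1e-6 or abs(site_z.std(ddof=1) - 1.0) > 1e-6:
            raise ValueError(f"column {zc} is not z-scored across sites")
    spec = ModelSpec(
        response="lrr",
        fixed=list(CLIMATE_ANOVA_LABELS.keys()),
        random=["site", "site:block"],
    )
    fit = fit_lmm(spec, data)
    fit.anova.index = [CLIMATE_ANOVA_LABELS[t] for t in fit.anova.index]
    return fit
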