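"""Phylogenetic comparative machinery.

Tree handling (Newick input/output, pruning) is delegated to :mod:`dendropy`;
the statistics built on top of the tree — the Brownian-motion covariance
matrix, Pagel's :math:`\\lambda`, Blomberg's *K*, and phylogenetic
generalized least squares (PGLS) — are implemented here with dense matrix
algebra.

The Brownian model treats a continuous trait as the endpoint of a random
walk along the branches: the covariance between two tips equals the depth of
their most recent common ancestor, giving the matrix *C*.  Pagel's
:math:`\\lambda` rescales the off-diagonal of *C* (``C_lam = lam*C +
(1-lam)*diag(C)``); :math:`\\lambda = 0` means tips are independent,
:math:`\\lambda = 1` recovers pure Brownian motion.  Blomberg's *K*
compares observed trait variance partitioning against the Brownian
expectation and has expectation 1 under Brownian evolution.

Dense algebra is deliberate: the trees handled here have at most a few
hundred tips, and explicit matrices keep every estimator testable against a
brute-force likelihood oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Phylogeny",
    "SignalEstimate",
    "PGLSFit",
    "read_newick",
    "bm_covariance",
    "lambda_transform",
    "pagels_lambda",
    "blombergs_K",
    "pgls_fit",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class DegenerateTraitError(ValueError):
    """Trait vector is constant; signal statistics are undefined."""


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------

class Phylogeny:
    """A rooted tree with branch lengths, wrapping a :class:`dendropy.Tree`.

    Tip labels must be unique; branch lengths must be strictly positive.
    The tip order exposed by :attr:`tip_labels` is the tree's leaf-iteration
    order and is the row/column order of every matrix derived from the tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise ValueError(
                    f"non-positive or missing branch length at node "
                    f"{node.taxon.label if node.taxon else '<internal>'!s}"
                )
        self._labels = labels

    # -- basic accessors ----------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_tips

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    # -- operations ----------------------------------------------------------
    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``keep``, preserving patristic distances.

        Degree-2 nodes created by the pruning are collapsed with their
        branch lengths summed.  Taxa in ``keep`` that are not tips of the
        tree are reported in a warning and ignored.
        """
        keep = list(dict.fromkeys(keep))
        present = set(self._labels)
        unknown = [k for k in keep if k not in present]
        if unknown:
            warnings.warn(
                f"taxa not in tree ignored during pruning: {unknown}",
                stacklevel=2,
            )
        kept = [k for k in keep if k in present]
        if len(kept) < 2:
            raise ValueError("pruning requires at least 2 known taxa to keep")
        sub = self._tree.extract_tree_with_taxa_labels(kept)
        return Phylogeny(sub)

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path length for every tip."""
        depths = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return pd.Series(depths).reindex(self._labels)

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self._tree.phylogenetic_distance_matrix()
        ns = self._tree.taxon_namespace
        return float(pdm.patristic_distance(ns.get_taxon(a), ns.get_taxon(b)))


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------

def bm_covariance(tree: Phylogeny) -> pd.DataFrame:
    """Brownian-motion covariance matrix of the tips.

    ``C[i, j]`` is the depth (root-to-node distance) of the most recent
    common ancestor of tips *i* and *j*; the diagonal holds root-to-tip
    distances.  Returned as a labelled DataFrame in tip order.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    dtree = tree.dendropy_tree
    # node depth from root
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # postorder: tips below each node; MRCA depth fills cross-child blocks
    below: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            children = [below.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            merged: list[int] = []
            for ch in children:
                merged.extend(ch)
            below[id(node)] = merged
    return pd.DataFrame(C, index=labels, columns=labels)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: scale off-diagonal covariances by ``lam``."""
    D = np.diag(np.diag(C))
    return lam * C + (1.0 - lam) * D


# ---------------------------------------------------------------------------
# Signal statistics
# ---------------------------------------------------------------------------

@dataclass
class SignalEstimate:
    """Result of a phylogenetic-signal estimator."""

    statistic: str              # "lambda" or "K"
    value: float
    p_value: float
    loglik: float | None = None
    loglik_null: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _align_trait(tree: Phylogeny, trait) -> np.ndarray:
    """Return trait values in tip order; raise on missing or constant input."""
    if isinstance(trait, Mapping):
        trait = pd.Series(trait)
    if isinstance(trait, pd.Series):
        missing = [t for t in tree.tip_labels if t not in trait.index]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        y = trait.reindex(tree.tip_labels).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if y.shape != (tree.n_tips,):
            raise ValueError("trait length does not match number of tips")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait contains non-finite values")
    if np.ptp(y) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    return y


def _mvn_profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Gaussian log-likelihood with mean mu*1 and covariance sigma2*V,
    profiled analytically over mu and sigma2 (ML)."""
    n = y.size
    c, low = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    one = np.ones(n)
    Vi_y = cho_solve((c, low), y)
    Vi_1 = cho_solve((c, low), one)
    mu = (one @ Vi_y) / (one @ Vi_1)
    r = y - mu
    Vi_r = cho_solve((c, low), r)
    sigma2 = (r @ Vi_r) / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def pagels_lambda(tree: Phylogeny, trait, tol: float = 1e-6) -> SignalEstimate:
    """Maximum-likelihood estimate of Pagel's lambda with a LR test vs 0.

    The profile log-likelihood over lambda in [0, 1] is maximized by
    bounded scalar (Brent-style) search; mean and scale are profiled
    analytically.  The p-value is a likelihood-ratio test of the estimate
    against lambda = 0 on a chi-squared distribution with 1 df.
    """
    if tree.n_tips < 4:
        raise ValueError("Pagel's lambda requires at least 4 tips")
    y = _align_trait(tree, trait)
    C = bm_covariance(tree).to_numpy()

    def negll(lam: float) -> float:
        return -_mvn_profile_loglik(y, lambda_transform(C, lam))

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": tol},
    )
    # guard the boundaries: the interior search can miss an endpoint optimum
    candidates = [(0.0, negll(0.0)), (1.0, negll(1.0)), (float(res.x), res.fun)]
    lam_hat, nll_hat = min(candidates, key=lambda t: t[1])
    ll_hat = -nll_hat
    ll0 = -candidates[0][1]
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalEstimate(
        statistic="lambda", value=float(lam_hat), p_value=p,
        loglik=float(ll_hat), loglik_null=float(ll0),
    )


def blombergs_K(
    tree: Phylogeny, trait, n_perm: int = 1000, seed: int | None = None
) -> SignalEstimate:
    """Blomberg's *K* with a one-sided tip-permutation test.

    K is the ratio of the observed MSE0/MSE — variance about the
    phylogenetic mean over the C-whitened residual variance — to its
    expectation under Brownian motion, ``(tr(C) - n/(1'C^-1 1))/(n-1)``.
    The p-value is the fraction of tip-label permutations with an
    MSE0/MSE ratio at least as large as observed (with the +1 correction);
    the permutation stream is controlled entirely by ``seed``.
    """
    if tree.n_tips < 4:
        raise ValueError("Blomberg's K requires at least 4 tips")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    y = _align_trait(tree, trait)
    C = bm_covariance(tree).to_numpy()
    n = y.size
    c, low = cho_factor(C, lower=True)
    one = np.ones(n)
    Vi_1 = cho_solve((c, low), one)
    denom_mean = one @ Vi_1
    expected_ratio = (np.trace(C) - n / denom_mean) / (n - 1)

    def ratio(v: np.ndarray) -> float:
        a_hat = (one @ cho_solve((c, low), v)) / denom_mean
        r = v - a_hat
        mse0 = (r @ r) / (n - 1)
        mse = (r @ cho_solve((c, low), r)) / (n - 1)
        return mse0 / mse

    obs_ratio = ratio(y)
    K = obs_ratio / expected_ratio

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if ratio(rng.permutation(y)) >= obs_ratio:
            hits += 1
    p = (hits + 1.0) / (n_perm + 1.0)
    return SignalEstimate(
        statistic="K", value=float(K), p_value=float(p),
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Phylogenetic GLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """Phylogenetic GLS fit of a trait on a group factor."""

    coefficients: pd.Series
    std_errors: pd.Series
    lambda_: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    sigma2: float
    loglik: float
    groups: list[str] = field(default_factory=list)

    def group_means(self) -> pd.Series:
        """Estimated mean per group (reference level + offsets)."""
        base = self.coefficients.iloc[0]
        means = {self.groups[0]: base}
        for g, coef in zip(self.groups[1:], self.coefficients.iloc[1:]):
            means[g] = base + coef
        return pd.Series(means)


def _gls_whitened(
    y: np.ndarray, X: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """GLS via whitening; returns (beta, cov_unscaled, rss, logdetV)."""
    c, low = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    from scipy.linalg import solve_triangular

    L = np.tril(c) if low else np.triu(c).T
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    return beta, np.linalg.inv(XtX), rss, logdet


def pgls_fit(
    tree: Phylogeny,
    response,
    design: Sequence,
    lambda_mode: str = "fixed_1",
) -> PGLSFit:
    """PGLS regression of a tip trait on a categorical group factor.

    The residual covariance is ``sigma2 * C_lambda`` with lambda either
    fixed at 1 (Brownian residuals, the default) or estimated by maximum
    likelihood.  Reports the F-test of the group factor against the
    intercept-only model.
    """
    if lambda_mode not in ("fixed_1", "ml"):
        raise ValueError("lambda_mode must be 'fixed_1' or 'ml'")
    y = _align_trait(tree, response)
    if isinstance(design, Mapping):
        design = pd.Series(design)
    if isinstance(design, pd.Series):
        g = design.reindex(tree.tip_labels)
        if g.isna().any():
            raise ValueError("design missing for some tips")
        g = g.astype(str).to_numpy()
    else:
        g = np.asarray(design, dtype=object).astype(str)
        if g.shape != (tree.n_tips,):
            raise ValueError("design length does not match number of tips")

    levels = sorted(pd.unique(g))
    n = y.size
    X = np.ones((n, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (g == lev).astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        counts = pd.Series(g).value_counts()
        raise ValueError(f"design rank-deficient; group counts: {dict(counts)}")

    C = bm_covariance(tree).to_numpy()

    def fit_at(lam: float):
        V = lambda_transform(C, lam)
        beta, covu, rss, logdet = _gls_whitened(y, X, V)
        sigma2_ml = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
        return beta, covu, rss, ll

    if lambda_mode == "ml":
        res = optimize.minimize_scalar(
            lambda lam: -fit_at(lam)[3], bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        cands = [0.0, 1.0, float(res.x)]
        lam_hat = min(cands, key=lambda l: -fit_at(l)[3])
    else:
        lam_hat = 1.0

    beta, covu, rss, ll = fit_at(lam_hat)
    p = X.shape[1]
    sigma2 = rss / (n - p)
    se = np.sqrt(sigma2 * np.diag(covu))

    # F-test of the group factor: full vs intercept-only under the same V
    V = lambda_transform(C, lam_hat)
    _, _, rss0, _ = _gls_whitened(y, np.ones((n, 1)), V)
    q = p - 1
    F = ((rss0 - rss) / q) / (rss / (n - p))
    p_val = float(stats.f.sf(F, q, n - p))

    names = ["intercept"] + [f"group[{lev}]" for lev in levels[1:]]
    return PGLSFit(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        lambda_=float(lam_hat),
        f_statistic=float(F),
        df_num=q,
        df_den=n - p,
        p_value=p_val,
        sigma2=float(sigma2),
        loglik=float(ll),
        groups=levels,
    )
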