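"""Site-climate standardization and PCA-based variable selection.

Sites are characterized by 19 BioClim-style variables split into a
temperature group (11 variables) and a precipitation group (8 variables).
Because the variables differ wildly in scale, analyses use z-scores across
sites.  Four working axes — mean annual temperature, mean annual
precipitation, temperature seasonality, precipitation seasonality — are
picked per group from a correlation-matrix PCA: the variable with the
largest |loading| on PC1 and on PC2 within each group, with an optional
a-priori override list taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "zscore_columns",
    "pca_select",
    "PCASelection",
    "DEFAULT_GROUPS",
    "CANONICAL_VARS",
]

#: Default partition of the 19 variables.
DEFAULT_GROUPS = {
    "temperature": [f"bio{i}" for i in range(1, 12)],
    "precipitation": [f"bio{i}" for i in range(12, 20)],
}

#: The canonical a-priori axes: MAT (bio1), MAP (bio12), temperature
#: seasonality (bio4), precipitation seasonality (bio15).
CANONICAL_VARS = {
    "mat": "bio1",
    "map": "bio12",
    "temp_seasonality": "bio4",
    "precip_seasonality": "bio15",
}


class DegenerateColumnError(ValueError):
    """A column has zero standard deviation and cannot be z-scored."""


def zscore_columns(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric column across sites ((x - mean) / sample SD)."""
    if len(values) < 2:
        raise ValueError("z-scoring needs at least 2 sites")
    out = values.copy()
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            continue
        sd = values[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateColumnError(f"column {col!r} has zero variance")
        out[col] = (values[col] - values[col].mean()) / sd
    return out


@dataclass
class PCASelection:
    """PCA per variable group and the resulting variable picks."""

    loadings: dict[str, pd.DataFrame]             # group -> vars x PCs
    variance_explained: dict[str, np.ndarray]     # group -> % per PC
    selected: list[str] = field(default_factory=list)


def _group_pca(z: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigendecomposition of the correlation matrix of z-scored columns.

    Loadings are the unit eigenvectors ordered by decreasing eigenvalue;
    each component's sign is fixed so its largest-|loading| entry is
    positive.  Rank-deficient inputs simply yield trailing zero
    eigenvalues, which are kept (they carry 0% of the variance).
    """
    R = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_pct = 100.0 * eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec,
        index=z.columns,
        columns=[f"PC{j + 1}" for j in range(eigvec.shape[1])],
    )
    return loadings, var_pct


def pca_select(
    raw: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    override: list[str] | None = None,
) -> PCASelection:
    """Select four climate axes by per-group PCA on z-scored variables.

    Within each group the variables with the largest absolute loading on
    PC1 and PC2 are picked (if one variable tops both components, the
    runner-up on PC2 is taken so the picks stay distinct).  ``override``,
    when given, replaces the selection wholesale — the hook for a-priori
    variable choices.
    """
    groups = groups or DEFAULT_GROUPS
    if len(raw) < 3:
        raise ValueError("PCA selection needs at least 3 sites")
    loadings: dict[str, pd.DataFrame] = {}
    variance: dict[str, np.ndarray] = {}
    selected: list[str] = []
    for name, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {name!r} must contain >= 2 variables")
        missing = [c for c in cols if c not in raw.columns]
        if missing:
            raise ValueError(f"group {name!r} references missing columns {missing}")
        z = zscore_columns(raw[cols])
        load, var_pct = _group_pca(z)
        loadings[name] = load
        variance[name] = var_pct
        pick1 = load["PC1"].abs().idxmax()
        pc2_order = load["PC2"].abs().sort_values(ascending=False).index
        pick2 = next(v for v in pc2_order if v != pick1)
        selected.extend([pick1, pick2])
    if override is not None:
        if len(override) != 4:
            raise ValueError("override must list exactly 4 variables")
        missing = [v for v in override if v not in raw.columns]
        if missing:
            raise ValueError(f"override references missing columns {missing}")
        selected = list(override)
    return PCASelection(
        loadings=loadings, variance_explained=variance, selected=selected
    )
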