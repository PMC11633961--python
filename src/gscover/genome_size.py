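"""Genome-size assembly: one 1C-value per species (and site).

Genome size is measured as the 1C-value, the DNA amount (pg) of an
unreplicated gametic nucleus.  Values come from two kinds of sources:
curated database entries (possibly several per species, one per cytotype)
and site-specific flow-cytometry measurements.  The resolution rules are:

1. a measured record matching the exact (species, site) pair wins;
2. measured values are site-specific and are never transferred to other
   sites;
3. otherwise the species' minimum database value is used — the most
   conservative choice when cytotypes of different ploidy are listed, since
   it shrinks any genome-size effect rather than inflating it;
4. species with no record at all are returned in a separate unresolved
   listing, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "resolve_genome_size",
    "summarize_gs",
    "site_coverage",
    "read_gs_table",
    "write_resolved",
    "GSSummary",
    "AmbiguousGSError",
]

RECORD_COLUMNS = ["species", "site", "c_value_1C", "source", "note"]


class AmbiguousGSError(ValueError):
    """Duplicate measured values exist for one (species, site)."""


def read_gs_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited genome-size record table."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "site": str})
    missing = [c for c in ("species", "c_value_1C", "source") if c not in df]
    if missing:
        raise ValueError(f"genome-size table lacks columns: {missing}")
    if "site" not in df:
        df["site"] = ""
    df["site"] = df["site"].fillna("")
    if "note" not in df:
        df["note"] = ""
    return df[["species", "site", "c_value_1C", "source", "note"]]


def resolve_genome_size(
    records: pd.DataFrame,
    needed: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve one 1C-value per needed (species, site) pair.

    Parameters
    ----------
    records
        Table with columns ``species, site, c_value_1C, source`` (and
        optionally ``note``).  ``source`` is ``database`` or ``measured``;
        database records carry an empty site.
    needed
        The (species, site) pairs occurring in the cover data.

    Returns
    -------
    (resolved, unresolved)
        ``resolved`` has columns ``species, site, c_value_1C, provenance``
        with provenance ``measured_site_specific`` or ``database_min``;
        ``unresolved`` lists the (species, site) pairs with no usable
        record.
    """
    if records is None or len(records) == 0:
        raise ValueError("records table is empty")
    bad = records[records["c_value_1C"] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive 1C-values for species: {sorted(bad['species'])}"
        )
    measured = records[records["source"] == "measured"]
    dup = measured.groupby(["species", "site"]).size()
    dup = dup[dup > 1]
    if len(dup):
        raise AmbiguousGSError(
            "duplicate measured values for (species, site): "
            f"{sorted(dup.index.tolist())}"
        )
    measured_map = {
        (r.species, r.site): float(r.c_value_1C)
        for r in measured.itertuples()
    }
    database = records[records["source"] == "database"]
    db_min = database.groupby("species")["c_value_1C"].min()

    resolved_rows, unresolved_rows = [], []
    for species, site in dict.fromkeys(
        (str(sp), str(st)) for sp, st in needed
    ):
        if (species, site) in measured_map:
            resolved_rows.append(
                {
                    "species": species,
                    "site": site,
                    "c_value_1C": measured_map[(species, site)],
                    "provenance": "measured_site_specific",
                }
            )
        elif species in db_min.index:
            resolved_rows.append(
                {
                    "species": species,
                    "site": site,
                    "c_value_1C": float(db_min[species]),
                    "provenance": "database_min",
                }
            )
        else:
            unresolved_rows.append({"species": species, "site": site})
    resolved = pd.DataFrame(
        resolved_rows, columns=["species", "site", "c_value_1C", "provenance"]
    )
    unresolved = pd.DataFrame(unresolved_rows, columns=["species", "site"])
    return resolved, unresolved


def site_coverage(
    resolved: pd.DataFrame, unresolved: pd.DataFrame
) -> pd.DataFrame:
    """Per-site fraction of species with a resolved genome size."""
    n_res = resolved.groupby("site").size() if len(resolved) else pd.Series(dtype=int)
    n_unres = (
        unresolved.groupby("site").size() if len(unresolved) else pd.Series(dtype=int)
    )
    sites = sorted(set(n_res.index) | set(n_unres.index))
    rows = []
    for site in sites:
        r = int(n_res.get(site, 0))
        u = int(n_unres.get(site, 0))
        rows.append(
            {
                "site": site,
                "n_resolved": r,
                "n_species": r + u,
                "coverage": r / (r + u) if (r + u) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GSSummary:
    mean: float
    median: float
    mode: float
    min: float
    max: float
    fold_range: float
    mode_bin_width: float

    def fold_range_2sf(self) -> float:
        """Fold range rounded to two significant figures (the convention
        behind statements like a '230-fold' range)."""
        from math import floor, log10

        fr = self.fold_range
        if fr <= 0:
            return fr
        digits = 1 - int(floor(log10(abs(fr))))
        return round(fr, digits)


def summarize_gs(values, mode_bin_width: float = 0.1) -> GSSummary:
    """Distribution summary of a set of 1C-values.

    The mode is the centre of the fullest histogram bin.  Bins have width
    ``mode_bin_width`` pg and are centred on multiples of that width, so
    candidate modes are round values (0.1, 0.2, ... pg at the default
    width); ties break toward the smallest bin.  ``fold_range`` is
    max/min.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("summarize_gs requires a non-empty input")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("all genome sizes must be positive and finite")
    if mode_bin_width <= 0:
        raise ValueError("mode_bin_width must be positive")
    lo, hi = float(x.min()), float(x.max())
    # bin k covers [(k - 1/2) w, (k + 1/2) w); its centre is k w
    centres = np.round(x / mode_bin_width).astype(int)
    counts = np.bincount(centres)
    mode = int(np.argmax(counts)) * mode_bin_width
    return GSSummary(
        mean=float(x.mean()),
        median=float(np.median(x)),
        mode=float(mode),
        min=lo,
        max=hi,
        fold_range=hi / lo,
        mode_bin_width=mode_bin_width,
    )


def write_resolved(
    resolved: pd.DataFrame, unresolved: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "resolved": outdir / "resolved_gs.tsv",
        "unresolved": outdir / "unresolved_species.tsv",
    }
    resolved.to_csv(paths["resolved"], sep="\t", index=False)
    unresolved.to_csv(paths["unresolved"], sep="\t", index=False)
    return paths
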