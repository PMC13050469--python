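"""Normalization, per-cell-type means, target-signature scores, correlations.

The cell-by-gene container is :class:`anndata.AnnData` with obs columns
``condition`` and ``cell_type`` and a ``uns["normalized"]`` flag.  All mean
expression feeding the ligand-receptor interaction score is computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["normalize", "type_means", "TypeMeanTable", "signature_score", "spearman_correlation"]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=np.float64)


def _check_annotated(adata: ad.AnnData) -> None:
    for col in ("condition", "cell_type"):
        if col not in adata.obs:
            raise ValueError(f"matrix lacks per-cell annotation column {col!r}")
    if adata.obs_names.has_duplicates or adata.var_names.has_duplicates:
        raise ValueError("duplicate cell or gene identifiers")


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    Cells with zero total counts are dropped with a warning.  A matrix that is
    already normalized is rejected rather than silently transformed twice.
    """
    _check_annotated(adata)
    if adata.uns.get("normalized", False):
        raise ValueError("matrix is already normalized; refusing to normalize twice")
    x = _dense(adata.X)
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("expression values must be finite and non-negative")
    totals = x.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cell(s) with zero total counts", int((~keep).sum()))
    x = x[keep]
    totals = totals[keep]
    out = adata[keep].copy()
    out.X = np.log1p(x * (scale / totals[:, None]))
    out.uns["normalized"] = True
    out.uns["normalize_scale"] = float(scale)
    return out


@dataclass
class TypeMeanTable:
    """Mean expression per (gene, cell type, condition) stratum.

    ``means`` is genes x strata with a (cell_type, condition) column
    MultiIndex; ``n_cells`` counts cells per stratum; ``excluded`` lists the
    strata removed by the ``min_cells`` rule.
    """

    means: pd.DataFrame
    n_cells: pd.Series
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def mean(self, gene: str, cell_type: str, condition: str) -> float:
        return float(self.means.at[gene, (cell_type, condition)])

    def has_stratum(self, cell_type: str, condition: str) -> bool:
        return (cell_type, condition) in self.means.columns

    @property
    def strata(self) -> list[tuple[str, str]]:
        return list(self.means.columns)


def type_means(adata: ad.AnnData, min_cells: int = 10) -> TypeMeanTable:
    """Arithmetic mean expression within each (cell type, condition) stratum.

    Strata with fewer than ``min_cells`` cells are excluded and recorded.
    """
    _check_annotated(adata)
    x = _dense(adata.X)
    obs = adata.obs
    key = pd.MultiIndex.from_frame(
        pd.DataFrame({"cell_type": obs["cell_type"].astype(str),
                      "condition": obs["condition"].astype(str)})
    )
    df = pd.DataFrame(x, index=key, columns=adata.var_names)
    counts = df.groupby(level=["cell_type", "condition"], observed=True).size()
    grouped = df.groupby(level=["cell_type", "condition"], observed=True).mean()
    keep = counts[counts >= min_cells].index
    excluded = [tuple(t) for t in counts.index.difference(keep)]
    if excluded:
        logger.warning("excluding %d stratum/strata below min_cells=%d: %s",
                       len(excluded), min_cells, excluded)
    means = grouped.loc[keep].T  # genes x (type, condition)
    means.columns = pd.MultiIndex.from_tuples(list(keep), names=["cell_type", "condition"])
    return TypeMeanTable(means=means, n_cells=counts.loc[keep], excluded=excluded)


def signature_score(adata: ad.AnnData, genes: Iterable[str]) -> pd.Series:
    """Per-cell mean expression over a gene set (a target-signature score).

    Genes absent from the matrix are dropped with a warning; an empty
    effective set is an error.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in adata.var_names]
    missing = len(genes) - len(present)
    if missing:
        logger.warning("signature_score: %d gene(s) absent from matrix dropped", missing)
    if not present:
        raise ValueError("no signature genes present in the matrix")
    x = _dense(adata[:, present].X)
    return pd.Series(x.mean(axis=1), index=adata.obs_names, name="signature_score")


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    Constant input is rejected: rank correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
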