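"""Ligand-receptor communication scoring between cell types, per condition.

The interaction score for a pair (L, R) from a source to a target cell type
in one condition is the product of the ligand's mean expression in the source
type and the receptor's mean expression in the target type — the mean-product
score popularized by cell-cell communication tools.  An optional label-
permutation test attaches an empirical p-value per record.
"""

from __future__ import annotations

import logging
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from .expression import TypeMeanTable, _check_annotated, _dense, type_means

logger = logging.getLogger(__name__)

__all__ = ["interaction_score", "score_all", "permutation_test", "interaction_counts"]

RECORD_COLUMNS = ["pair_id", "ligand", "receptor", "source", "target", "condition", "score"]


def interaction_score(
    means: TypeMeanTable,
    pair: Mapping[str, str] | pd.Series,
    source: str,
    target: str,
    condition: str,
) -> float:
    """mean(ligand | source, condition) x mean(receptor | target, condition)."""
    for ct in (source, target):
        if not means.has_stratum(ct, condition):
            raise KeyError(f"stratum ({ct!r}, {condition!r}) absent from mean table")
    for gene in (pair["ligand"], pair["receptor"]):
        if gene not in means.means.index:
            raise KeyError(f"gene {gene!r} absent from mean table")
    return means.mean(pair["ligand"], source, condition) * means.mean(
        pair["receptor"], target, condition
    )


def score_all(
    adata: ad.AnnData,
    reference: pd.DataFrame,
    min_cells: int = 10,
    means: TypeMeanTable | None = None,
) -> pd.DataFrame:
    """Score every (pair, source type, target type, condition) combination.

    Pairs whose ligand or receptor is missing from the matrix are skipped with
    a warning.  Autocrine (source = target) combinations are included.  Rows
    are ordered by (pair_id, source, target, condition) for stable diffs.
    """
    _check_annotated(adata)
    if not adata.uns.get("normalized", False):
        raise ValueError("score_all expects a normalized matrix")
    if reference.empty:
        raise ValueError("empty LR reference")
    if means is None:
        means = type_means(adata, min_cells=min_cells)
    if means.means.empty or not means.strata:
        logger.warning("no stratum passes min_cells=%d; returning empty record set", min_cells)
        return pd.DataFrame(columns=RECORD_COLUMNS)

    present = reference[
        reference["ligand"].isin(means.means.index)
        & reference["receptor"].isin(means.means.index)
    ]
    n_skipped = len(reference) - len(present)
    if n_skipped:
        logger.warning("skipping %d pair(s) with genes absent from the matrix", n_skipped)
    if present.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    strata = means.strata  # list of (cell_type, condition)
    types = sorted({t for t, _ in strata})
    conditions = sorted({c for _, c in strata})
    # mean arrays: pairs x types x conditions, NaN where the stratum is absent
    lmat = np.full((len(present), len(types), len(conditions)), np.nan)
    rmat = np.full_like(lmat, np.nan)
    t_idx = {t: i for i, t in enumerate(types)}
    c_idx = {c: i for i, c in enumerate(conditions)}
    lig_rows = means.means.loc[present["ligand"]].to_numpy()
    rec_rows = means.means.loc[present["receptor"]].to_numpy()
    for j, (t, c) in enumerate(strata):
        lmat[:, t_idx[t], c_idx[c]] = lig_rows[:, j]
        rmat[:, t_idx[t], c_idx[c]] = rec_rows[:, j]

    score = lmat[:, :, None, :] * rmat[:, None, :, :]  # pair x source x target x cond
    p_i, s_i, t_i, k_i = np.nonzero(np.isfinite(score))
    out = pd.DataFrame(
        {
            "pair_id": present["pair_id"].to_numpy()[p_i],
            "ligand": present["ligand"].to_numpy()[p_i],
            "receptor": present["receptor"].to_numpy()[p_i],
            "source": np.asarray(types, dtype=object)[s_i],
            "target": np.asarray(types, dtype=object)[t_i],
            "condition": np.asarray(conditions, dtype=object)[k_i],
            "score": score[p_i, s_i, t_i, k_i],
        }
    )
    return out.sort_values(["pair_id", "source", "target", "condition"], kind="mergesort").reset_index(drop=True)


def permutation_test(
    adata: ad.AnnData,
    record: Mapping[str, str] | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for one interaction record.

    Cell-type labels are shuffled within the record's condition; the add-one
    estimate p = (1 + #{permuted score >= observed}) / (n_perm + 1) keeps p
    strictly positive.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _check_annotated(adata)
    cond_mask = (adata.obs["condition"].astype(str) == record["condition"]).to_numpy()
    labels = adata.obs["cell_type"].astype(str).to_numpy()[cond_mask]
    if len(set(labels)) < 2:
        raise ValueError("fewer than 2 cell types in condition: permutation meaningless")
    sub = adata[cond_mask]
    vl = _dense(sub[:, [record["ligand"]]].X).ravel()
    vr = _dense(sub[:, [record["receptor"]]].X).ravel()
    src_mask = labels == record["source"]
    tgt_mask = labels == record["target"]
    if not src_mask.any() or not tgt_mask.any():
        raise ValueError("source or target type absent from condition")
    observed = vl[src_mask].mean() * vr[tgt_mask].mean()

    rng = np.random.default_rng(seed)
    # permuting labels == permuting values against fixed label positions
    perm = rng.random((n_perm, len(labels))).argsort(axis=1)
    pl = vl[perm]
    pr = vr[perm]
    perm_scores = pl[:, src_mask].mean(axis=1) * pr[:, tgt_mask].mean(axis=1)
    return float((1 + int((perm_scores >= observed).sum())) / (n_perm + 1))


def interaction_counts(
    records: pd.DataFrame,
    threshold: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count records with score > threshold per (source, target, condition).

    If a ``permutation_p`` column is present, only records with
    permutation_p < alpha are counted.
    """
    if records.empty:
        return pd.DataFrame(columns=["source", "target", "condition", "n_interactions"])
    keep = records["score"] > threshold
    if "permutation_p" in records.columns:
        keep &= records["permutation_p"] < alpha
    kept = records[keep]
    counts = (
        kept.groupby(["source", "target", "condition"], observed=True)
        .size()
        .rename("n_interactions")
        .reset_index()
    )
    full = (
        records[["source", "target", "condition"]]
        .drop_duplicates()
        .merge(counts, how="left", on=["source", "target", "condition"])
        .fillna({"n_interactions": 0})
    )
    full["n_interactions"] = full["n_interactions"].astype(int)
    return full.sort_values(["source", "target", "condition"], kind="mergesort").reset_index(drop=True)
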