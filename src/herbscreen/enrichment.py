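"""Hypergeometric over-representation screening with BH correction.

The closeness between a target profile (herb, compound, or pathway) and an
effect gene set is the upper-tail hypergeometric probability of their overlap
inside a common gene universe: with N universe genes, K profile targets, n
set genes and k overlapping genes, p = P(X >= k), X ~ Hypergeom(N, K, n).
P-values are BH-adjusted within each set label across the panel, and entities
are ranked by how many sets they hit significantly, then by mean adjusted p,
then by total overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TargetProfile",
    "hypergeom_upper",
    "bh_adjust",
    "enrich_panel",
    "rank_entities",
    "pathway_enrich_standardize",
]

RESULT_COLUMNS = ["entity_id", "set_label", "k", "K", "n", "N", "p_raw", "p_adj"]


@dataclass(frozen=True)
class TargetProfile:
    entity_id: str
    targets: frozenset[str]
    entity_kind: str = "herb"

    def __post_init__(self):
        if not self.targets:
            raise ValueError("empty target set")


def profiles_from_table(table: pd.DataFrame, entity_kind: str = "herb") -> list[TargetProfile]:
    """Build profiles from a long (entity_id, gene) table."""
    return [
        TargetProfile(entity_id=str(eid), targets=frozenset(sub["gene"].astype(str)),
                      entity_kind=entity_kind)
        for eid, sub in table.groupby("entity_id", observed=True)
    ]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich_panel(
    panel: Iterable[TargetProfile],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One hypergeometric test per (entity, set label), BH within each label.

    Profiles and gene sets are intersected with the universe before counting;
    entities with no in-universe targets are dropped with a warning.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    set_genes = {label: frozenset(genes) & universe for label, genes in sets.items()}
    rows = []
    for profile in panel:
        targets = profile.targets & universe
        if not targets:
            logger.warning("entity %s has no in-universe targets; dropped", profile.entity_id)
            continue
        for label, genes in set_genes.items():
            k = len(targets & genes)
            rows.append(
                {
                    "entity_id": profile.entity_id,
                    "set_label": label,
                    "k": k,
                    "K": len(targets),
                    "n": len(genes),
                    "N": len(universe),
                    "p_raw": hypergeom_upper(k, len(targets), len(genes), len(universe)),
                }
            )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if results.empty:
        results["p_adj"] = []
        return results
    results["p_adj"] = np.nan
    for label, idx in results.groupby("set_label", observed=True).groups.items():
        results.loc[idx, "p_adj"] = bh_adjust(results.loc[idx, "p_raw"])
    return results.sort_values(["set_label", "entity_id"], kind="mergesort").reset_index(drop=True)


def rank_entities(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Screening table: entities ordered by significance and mapping count.

    Sort keys: number of set labels with p_adj < alpha (desc), mean p_adj
    (asc), total overlap k (desc), entity_id (lexicographic). Deterministic.
    """
    if results.empty:
        return pd.DataFrame(columns=["entity_id", "n_significant", "mean_p_adj", "total_k", "rank"])
    agg = (
        results.assign(significant=results["p_adj"] < alpha)
        .groupby("entity_id", observed=True)
        .agg(n_significant=("significant", "sum"),
             mean_p_adj=("p_adj", "mean"),
             total_k=("k", "sum"))
        .reset_index()
    )
    agg = agg.sort_values(
        by=["n_significant", "mean_p_adj", "total_k", "entity_id"],
        ascending=[False, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg


def pathway_enrich_standardize(results: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize -log10 p_raw within each set label across pathways.

    Larger -log10 p (stronger enrichment) maps to larger z.  A label with a
    single pathway is an error; zero variance yields all-zero z with a
    warning.
    """
    out = results.copy()
    out["neg_log10_p"] = -np.log10(out["p_raw"])
    out["z"] = np.nan
    for label, idx in out.groupby("set_label", observed=True).groups.items():
        vals = out.loc[idx, "neg_log10_p"].to_numpy()
        if vals.size < 2:
            raise ValueError(f"set label {label!r} has fewer than 2 pathways")
        sd = vals.std(ddof=1)
        if sd == 0:
            logger.warning("set label %r: zero variance, standardized values set to 0", label)
            out.loc[idx, "z"] = 0.0
        else:
            out.loc[idx, "z"] = (vals - vals.mean()) / sd
    return out
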