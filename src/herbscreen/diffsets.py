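"""Differential LR-pair sets A/B/C/D from condition contrasts.

An interaction entry (pair, source, target) "changes" between two conditions
when the absolute log2 fold-change of its score (with a pseudocount) meets a
threshold.  The four effect sets follow a fixed comparison scheme over a
five-condition design (reference Nor; disease stages A1, A2; disease +
dietary co-exposure stages F1, F2):

* A — contrasts among disease/exposure stages: (A2 vs A1), (F1 vs A1),
  (F2 vs F1), (F2 vs A2); pairs changing as exposure and stage progress.
* B — (F1 vs Nor), (F2 vs Nor); pairs altered under exposure relative to
  the healthy reference.
* C — (A1 vs Nor), (A2 vs Nor); pairs altered by the disease course alone.
* D = B \\ C — pairs whose alteration is attributable to the exposure.

Contrast lists combine by union (default) or intersection.  Membership is
tracked at (pair, source, target) granularity and projected to genes only
when an enrichment universe is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["ComparisonResult", "EffectGeneSet", "compare", "derive_sets", "project_to_genes", "SET_CONTRASTS"]

Entry = tuple[str, str, str]  # (pair_id, source, target)

SET_CONTRASTS: dict[str, tuple[tuple[str, str], ...]] = {
    "A": (("A2", "A1"), ("F1", "A1"), ("F2", "F1"), ("F2", "A2")),
    "B": (("F1", "Nor"), ("F2", "Nor")),
    "C": (("A1", "Nor"), ("A2", "Nor")),
}


@dataclass(frozen=True)
class ComparisonResult:
    contrast: tuple[str, str]
    changed: pd.DataFrame  # columns entry fields + score_x, score_y, log2fc

    @property
    def changed_pairs(self) -> frozenset[Entry]:
        return frozenset(
            self.changed[["pair_id", "source", "target"]].itertuples(index=False, name=None)
        )


@dataclass(frozen=True)
class EffectGeneSet:
    label: str
    pair_members: frozenset[Entry]
    gene_members: frozenset[str]

    @property
    def pair_ids(self) -> frozenset[str]:
        return frozenset(p for p, _, _ in self.pair_members)


def compare(
    records: pd.DataFrame,
    x: str,
    y: str,
    tau: float = 1.0,
    eps: float = 0.01,
) -> ComparisonResult:
    """Entries changed between condition ``x`` and condition ``y``.

    Changed iff |log2((score_x + eps) / (score_y + eps))| >= tau.  Entries
    scored in only one of the two conditions are compared against eps
    (i.e. a missing score counts as zero).
    """
    if x == y:
        raise ValueError("contrast conditions must differ")
    if tau < 0 or eps <= 0:
        raise ValueError("tau must be >= 0 and eps > 0")
    present = set(records["condition"].unique())
    for cond in (x, y):
        if cond not in present:
            raise ValueError(f"condition {cond!r} absent from records")
    keys = ["pair_id", "source", "target"]
    sx = records.loc[records["condition"] == x, keys + ["score"]].rename(columns={"score": "score_x"})
    sy = records.loc[records["condition"] == y, keys + ["score"]].rename(columns={"score": "score_y"})
    merged = sx.merge(sy, how="outer", on=keys).fillna({"score_x": 0.0, "score_y": 0.0})
    merged["log2fc"] = np.log2((merged["score_x"] + eps) / (merged["score_y"] + eps))
    changed = merged[np.abs(merged["log2fc"]) >= tau].reset_index(drop=True)
    return ComparisonResult(contrast=(x, y), changed=changed)


def _combine(results: Iterable[ComparisonResult], mode: str) -> frozenset[Entry]:
    sets = [r.changed_pairs for r in results]
    if not sets:
        return frozenset()
    if mode == "union":
        return frozenset().union(*sets)
    if mode == "intersection":
        return frozenset.intersection(*sets)
    raise ValueError(f"unknown combine mode {mode!r}")


def derive_sets(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    tau: float = 1.0,
    eps: float = 0.01,
    mode: str = "union",
    contrasts: Mapping[str, tuple[tuple[str, str], ...]] | None = None,
) -> dict[str, EffectGeneSet]:
    """Derive effect sets A, B, C and D = B \\ C at pair granularity.

    ``contrasts`` overrides the default five-condition scheme (keys A, B, C;
    D is always the subtraction).  Raises if any contrast condition is
    missing from the records, naming it.
    """
    scheme = dict(contrasts) if contrasts is not None else SET_CONTRASTS
    present = set(records["condition"].unique()) if not records.empty else set()
    needed = {c for pairs in scheme.values() for pair in pairs for c in pair}
    missing = sorted(needed - present)
    if missing:
        raise ValueError(f"records lack condition(s): {missing}")

    members: dict[str, frozenset[Entry]] = {}
    for label, contrast_list in scheme.items():
        results = [compare(records, cx, cy, tau=tau, eps=eps) for cx, cy in contrast_list]
        members[label] = _combine(results, mode)
    members["D"] = members["B"] - members["C"]
    assert members["D"] & members["C"] == frozenset()
    assert members["D"] == members["B"] - members["C"]

    out: dict[str, EffectGeneSet] = {}
    for label in ("A", "B", "C", "D"):
        pairs = members[label]
        out[label] = EffectGeneSet(
            label=label,
            pair_members=pairs,
            gene_members=project_to_genes(pairs, reference),
        )
    return out


def project_to_genes(pairs: Iterable[Entry | str], reference: pd.DataFrame) -> frozenset[str]:
    """Union of ligand and receptor genes over the given pair members."""
    lut = reference.set_index("pair_id")[["ligand", "receptor"]]
    genes: set[str] = set()
    for entry in pairs:
        pair_id = entry if isinstance(entry, str) else entry[0]
        if pair_id not in lut.index:
            raise KeyError(f"pair_id {pair_id!r} not resolvable in LR reference")
        row = lut.loc[pair_id]
        genes.add(str(row["ligand"]))
        genes.add(str(row["receptor"]))
    return frozenset(genes)
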