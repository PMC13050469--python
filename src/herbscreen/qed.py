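"""Quantitative estimate of drug-likeness (QED) from descriptor tables.

QED maps eight physicochemical descriptors (MW, ALOGP, HBA, HBD, PSA, ROTB,
AROM, ALERTS) through published asymmetric-double-sigmoid desirability
functions d_i, then combines them as a weighted geometric mean:

    QED = exp( sum_i w_i ln d_i / sum_i w_i )

The shipped parameter file carries the canonical published desirability
parameters and three weight variants ("mean" — the common default of
structure-based implementations, "max", and "unit" for the unweighted score).
Descriptors are plain table inputs here; no structures are required.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ADSParams", "load_qed_params", "desirability", "qed", "qed_frame", "filter_compounds", "DESCRIPTOR_NAMES"]

DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")
_FLOOR = 1e-6  # lower clamp keeps ln d finite


@dataclass(frozen=True)
class ADSParams:
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: float

    def __post_init__(self):
        if self.dmax <= 0 or self.e <= 0 or self.f <= 0:
            raise ValueError("malformed desirability parameters")


def load_qed_params() -> tuple[dict[str, ADSParams], dict[str, dict[str, float]]]:
    """Shipped desirability parameters and weight variants."""
    text = resources.files("herbscreen.data").joinpath("qed_params.json").read_text()
    raw = json.loads(text)
    params = {name: ADSParams(**vals) for name, vals in raw["ads_params"].items()}
    return params, raw["weights"]


_PARAMS, _WEIGHTS = None, None


def _shipped():
    global _PARAMS, _WEIGHTS
    if _PARAMS is None:
        _PARAMS, _WEIGHTS = load_qed_params()
    return _PARAMS, _WEIGHTS


def desirability(value: float, params: ADSParams) -> float:
    """Asymmetric double sigmoid normalized by its maximum, clamped to (0, 1]."""
    if not math.isfinite(value):
        raise ValueError("descriptor value must be finite")
    def _sigmoid(t: float) -> float:
        # overflow-safe logistic
        if t >= 0:
            return 1.0 / (1.0 + math.exp(-min(t, 700.0)))
        return math.exp(max(t, -700.0)) / (1.0 + math.exp(max(t, -700.0)))

    x = value
    ads = params.a + params.b * _sigmoid((x - params.c + params.d / 2) / params.e) * (
        1 - _sigmoid((x - params.c - params.d / 2) / params.f)
    )
    return min(max(ads / params.dmax, _FLOOR), 1.0)


def qed(
    descriptors: Mapping[str, float] | pd.Series,
    weights: str | Mapping[str, float] = "mean",
) -> float:
    """Weighted geometric mean of the eight descriptor desirabilities."""
    params, weight_sets = _shipped()
    if isinstance(weights, str):
        try:
            weights = weight_sets[weights]
        except KeyError:
            raise ValueError(f"unknown weight variant {weights!r}") from None
    w = np.array([float(weights[name]) for name in DESCRIPTOR_NAMES])
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    d = np.array([desirability(float(descriptors[name]), params[name]) for name in DESCRIPTOR_NAMES])
    return float(math.exp(np.dot(w, np.log(d)) / w.sum()))


def qed_frame(panel: pd.DataFrame, weights: str | Mapping[str, float] = "mean") -> pd.DataFrame:
    """Add a ``qed`` column to a descriptor table (one row per compound)."""
    missing = set(DESCRIPTOR_NAMES) - set(panel.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    out = panel.copy()
    out["qed"] = [qed(row, weights=weights) for _, row in panel.iterrows()]
    return out


def filter_compounds(
    panel: pd.DataFrame,
    threshold: float = 0.3,
    weights: str | Mapping[str, float] = "mean",
) -> pd.DataFrame:
    """Retain compounds with QED >= threshold (inclusive), order preserved.

    Returns the scored table with a boolean ``retained`` column; the kept
    subset is ``out[out.retained]``.
    """
    scored = qed_frame(panel, weights=weights)
    scored["retained"] = scored["qed"] >= threshold
    n_kept = int(scored["retained"].sum())
    logger.info("QED filter at %.2f: retained %d / %d compounds", threshold, n_kept, len(scored))
    return scored
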