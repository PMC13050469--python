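#!/usr/bin/env python
"""Derive the differential effect sets A/B/C/D from condition contrasts.

A: changes among disease/exposure stages; B: exposure vs healthy reference;
C: disease course vs reference; D = B minus C (exposure-attributable).
Reports set sizes and how many planted pairs were recovered where expected.
"""

import json

import pandas as pd

from _common import RUN_DIR, run_config
from herbscreen.pipeline import run


def main() -> None:
    run(run_config(), stages=["simulate", "score", "sets"])
    pairs = pd.read_csv(RUN_DIR / "effect_sets_pairs.tsv", sep="\t")
    truth = json.loads((RUN_DIR / "ground_truth.json").read_text())
    print("effect set sizes (pair entries / unique pairs):")
    for label, sub in pairs.groupby("set_label"):
        print(f"  {label}: {len(sub)} entries, {sub.pair_id.nunique()} pairs")
    print("planted-pair recovery:")
    for label, expected in truth["expected_set_membership"].items():
        got = set(pairs.loc[pairs.set_label == label, "pair_id"])
        hit = [p for p in expected if p in got]
        print(f"  set {label}: {len(hit)}/{len(expected)} expected planted pairs present")


if __name__ == "__main__":
    main()
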