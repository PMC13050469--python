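#!/usr/bin/env python
"""Score ligand-receptor communication between cell types in each condition.

The score for a pair from a source to a target type is the product of the
ligand's and receptor's mean log-normalized expression in the respective
types.  Writes interactions.tsv and per-channel interaction counts.
"""

import pandas as pd

from _common import RUN_DIR, run_config
from herbscreen.pipeline import run


def main() -> None:
    run(run_config(), stages=["simulate", "score"])
    rec = pd.read_csv(RUN_DIR / "interactions.tsv", sep="\t")
    counts = pd.read_csv(RUN_DIR / "interaction_counts.tsv", sep="\t")
    print(f"{len(rec)} interaction records "
          f"({rec.pair_id.nunique()} pairs x type pairs x {rec.condition.nunique()} conditions)")
    per_cond = (
        counts.groupby("condition")["n_interactions"].sum().reindex(
            ["Nor", "A1", "A2", "F1", "F2"])
    )
    print("total super-threshold interactions per condition:")
    print(per_cond.to_string())


if __name__ == "__main__":
    main()
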