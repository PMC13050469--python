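#!/usr/bin/env python
"""Network-target analysis: PPI subnetwork, proximity z-scores, pathways.

Builds the induced subnetwork over effect genes and the top herb's targets,
standardizes pathway enrichment (-log10 p z-scored within each effect set)
and summarizes the proximity of the herb's targets to each effect set.
Writes tables under results/ and, when matplotlib is available, a proximity
scatter (z vs overlap).
"""

import pandas as pd

import herbscreen as hs
from herbscreen import io
from herbscreen.enrichment import TargetProfile
from herbscreen.pipeline import run

from _common import RESULTS, RUN_DIR, run_config


def main() -> None:
    run(run_config(), stages=["simulate", "score", "sets", "enrich", "network"])
    prox = pd.read_csv(RUN_DIR / "proximity.tsv", sep="\t")
    print("proximity of the top herb's targets to each effect set (z < 0 = closer than chance):")
    print(prox.round(3).to_string(index=False))

    sets = io.read_gmt(RUN_DIR / "effect_sets_genes.gmt")
    pathways = io.read_gmt(RUN_DIR / "pathways.gmt")
    genes = pd.read_csv(RUN_DIR / "expression.genes.tsv", sep="\t")
    universe = set(genes["gene_id"].astype(str))
    panel = [TargetProfile(name, frozenset(g), entity_kind="pathway")
             for name, g in pathways.items()]
    res = hs.enrich_panel(panel, sets, universe)
    std = hs.pathway_enrich_standardize(res)
    std.to_csv(RESULTS / "pathway_enrichment_standardized.tsv", sep="\t", index=False)
    top = (std.sort_values("z", ascending=False).groupby("set_label").head(1)
           [["set_label", "entity_id", "p_raw", "z"]])
    print("most enriched pathway per effect set (standardized -log10 p):")
    print(top.round(3).to_string(index=False))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping proximity scatter")
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(prox["k_overlap"], prox["z"])
    for _, row in prox.iterrows():
        ax.annotate(row["set_label"], (row["k_overlap"], row["z"]))
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("overlap with herb targets (k)")
    ax.set_ylabel("proximity z")
    fig.tight_layout()
    fig.savefig(RESULTS / "proximity_scatter.png", dpi=150)
    print(f"scatter written to {RESULTS / 'proximity_scatter.png'}")


if __name__ == "__main__":
    main()
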