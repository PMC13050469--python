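#!/usr/bin/env python
"""Compound-level screen: QED filter, per-compound enrichment, expression-
pattern correlation and ontology similarity.

Druglikeness is computed from the descriptor table and compounds below
QED 0.3 are dropped.  The retained compounds are then given synthetic target
profiles (random splits of the top herb's target set plus decoy genes — a
labelled stand-in for external per-compound target predictions), and each is
tested against the effect sets the same way the herbs were.  Expression-
pattern agreement between each compound and its parent herb is the Spearman
correlation of their per-cell target-signature scores; functional agreement
is the Wang best-match-average similarity on a small synthetic ontology.
"""

import json

import numpy as np
import pandas as pd

import herbscreen as hs
from herbscreen import io
from herbscreen.enrichment import TargetProfile
from herbscreen.pipeline import run

from _common import RESULTS, RUN_DIR, SEED, run_config


def synthetic_compound_profiles(herb_targets, universe, n_compounds, rng):
    """Stand-in per-compound target sets: each compound inherits a random
    two-thirds of the herb's targets plus decoy genes (synthetic; real runs
    would use external target predictions)."""
    profiles = {}
    pool = sorted(set(universe) - set(herb_targets))
    for i in range(n_compounds):
        n_inherit = max(1, int(2 * len(herb_targets) / 3))
        inherit = rng.choice(sorted(herb_targets), size=n_inherit, replace=False)
        decoys = rng.choice(pool, size=max(0, 10), replace=False)
        profiles[f"CMP{i + 1:03d}"] = set(inherit) | set(decoys)
    return profiles


def synthetic_ontology(universe, rng, n_terms=30):
    """Small random DAG with genes annotated to leaf terms (synthetic)."""
    terms = [f"T{i:02d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        for parent in rng.choice(i, size=min(i, 2), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[i], terms[parent], rel))
    annotations = {g: {terms[int(t)] for t in rng.choice(n_terms, size=2, replace=False)}
                   for g in universe}
    return hs.OntologyDAG.from_edges(edges, annotations=annotations)


def main() -> None:
    config = run_config()
    run(config, stages=["simulate", "score", "sets", "enrich", "compounds"])
    rng = np.random.default_rng(SEED + 50)

    scored = pd.read_csv(RUN_DIR / "compounds_qed.tsv", sep="\t")
    kept = scored[scored.retained]
    print(f"QED >= 0.3 retained {len(kept)} / {len(scored)} compounds")

    truth = json.loads((RUN_DIR / "ground_truth.json").read_text())
    targets = pd.read_csv(RUN_DIR / "target_profiles.tsv", sep="\t")
    herb = truth["true_hit_herb"]
    herb_targets = set(targets.loc[targets.entity_id == herb, "gene"])
    adata = hs.normalize(io.read_expression(RUN_DIR / "expression"))
    universe = list(adata.var_names)
    sets = io.read_gmt(RUN_DIR / "effect_sets_genes.gmt")

    profiles = synthetic_compound_profiles(herb_targets, universe, min(5, len(kept)), rng)
    panel = [TargetProfile(cid, frozenset(genes), entity_kind="compound")
             for cid, genes in profiles.items()]
    res = hs.enrich_panel(panel, sets, universe)
    table = hs.rank_entities(res)
    table.to_csv(RESULTS / "compound_screening.tsv", sep="\t", index=False)
    print("compound screen (synthetic target profiles):")
    print(table.to_string(index=False))

    herb_sig = hs.signature_score(adata, herb_targets)
    dag = synthetic_ontology(universe, rng)
    rows = []
    for cid, genes in profiles.items():
        sig = hs.signature_score(adata, genes)
        rho, p = hs.spearman_correlation(sig, herb_sig)
        wang = hs.geneset_similarity(genes, herb_targets, dag)
        rows.append({"compound": cid, "spearman_rho": rho, "spearman_p": p, "wang_similarity": wang})
    corr = pd.DataFrame(rows)
    corr.to_csv(RESULTS / "compound_herb_agreement.tsv", sep="\t", index=False)
    print("expression-pattern and ontology agreement with the parent herb:")
    print(corr.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
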