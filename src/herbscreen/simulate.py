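"""Synthetic inputs with planted ground truth.

Every pipeline input — a five-condition annotated single-cell count matrix, a
ligand-receptor (LR) reference, herb target profiles, a protein-protein
interaction (PPI) graph, compound descriptor tables, and pathway gene sets —
is generated from one :class:`SimConfig` with known ground truth, so each
downstream stage can be tested for recovery of a planted signal.

The design emulates a five-group study (a healthy reference ``Nor``, a
disease model sampled at an early and a late stage ``A1``/``A2``, and the
same model under a dietary co-exposure ``F1``/``F2``).  Counts follow a
negative-binomial model with log-normal gene means and per-cell size
factors.  Planted LR pairs have their ligand mean shifted in a designated
source cell type and their receptor mean in a designated target cell type,
multiplicatively by ``2**effect_log2fc``, exactly in the conditions of their
assigned contrast pattern — which determines the differential set (A/B/C/D)
each pair is expected to land in.  One "true hit" herb carries a configurable
fraction of the planted genes among its targets; all other herbs are decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedPair",
    "generate_expression",
    "generate_lr_reference",
    "generate_target_profiles",
    "generate_ppi",
    "generate_descriptors",
    "generate_pathways",
]

# Contrast patterns planted pairs cycle through.  ``effect_conditions`` are the
# conditions whose ligand/receptor means are shifted; ``expected_sets`` are the
# differential sets the pair must land in under the union combination rule.
_PLANT_PATTERNS: tuple[tuple[str, frozenset[str], frozenset[str]], ...] = (
    ("fructose", frozenset({"F1", "F2"}), frozenset({"A", "B", "D"})),
    ("disease", frozenset({"A1", "A2", "F1", "F2"}), frozenset({"B", "C"})),
    ("late_fructose", frozenset({"F2"}), frozenset({"A", "B", "D"})),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for all generators."""

    n_genes: int = 200
    n_cells_per_condition: int = 300
    conditions: tuple[str, ...] = ("Nor", "A1", "A2", "F1", "F2")
    reference_condition: str = "Nor"
    cell_types: Mapping[str, float] = field(
        default_factory=lambda: {"Epithelial": 0.4, "Stromal": 0.35, "Myeloid": 0.25}
    )
    n_lr_pairs: int = 60
    n_planted_pairs: int = 6
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 1.0
    gene_mean_sigma: float = 0.6
    size_factor_sigma: float = 0.3
    n_herbs: int = 20
    targets_per_herb: int = 30
    planted_overlap_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cells_per_condition, self.n_lr_pairs + 1,
               self.n_herbs, self.targets_per_herb) <= 0:
            raise ValueError("all counts must be positive")
        if not self.cell_types:
            raise ValueError("cell_types must be a nonempty mapping")
        if any(p <= 0 for p in self.cell_types.values()):
            raise ValueError("cell-type proportions must be positive")
        if not 0.0 <= self.planted_overlap_fraction <= 1.0:
            raise ValueError("planted_overlap_fraction must lie in [0, 1]")
        if self.n_planted_pairs > self.n_lr_pairs:
            raise ValueError("n_planted_pairs cannot exceed n_lr_pairs")
        if self.reference_condition not in self.conditions:
            raise ValueError("conditions must contain the reference condition")
        if 2 * self.n_lr_pairs > self.n_genes:
            raise ValueError("gene pool exhausted: need 2*n_lr_pairs <= n_genes")
        if self.targets_per_herb > self.n_genes:
            raise ValueError("targets_per_herb cannot exceed n_genes")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion must be >= 0 and baseline_mean > 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PlantedPair:
    pair_id: str
    ligand: str
    receptor: str
    source: str
    target: str
    pattern: str
    effect_conditions: frozenset[str]
    expected_sets: frozenset[str]


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_pairs: dict[str, PlantedPair]
    true_hit_herb: str
    expected_set_membership: dict[str, frozenset[str]]

    @property
    def planted_genes(self) -> frozenset[str]:
        return frozenset(
            g for p in self.planted_pairs.values() for g in (p.ligand, p.receptor)
        )

    def to_dict(self) -> dict:
        return {
            "true_hit_herb": self.true_hit_herb,
            "planted_pairs": {
                k: {
                    "ligand": p.ligand,
                    "receptor": p.receptor,
                    "source": p.source,
                    "target": p.target,
                    "pattern": p.pattern,
                    "effect_conditions": sorted(p.effect_conditions),
                    "expected_sets": sorted(p.expected_sets),
                }
                for k, p in self.planted_pairs.items()
            },
            "expected_set_membership": {
                k: sorted(v) for k, v in self.expected_set_membership.items()
            },
        }


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_ids(config: SimConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def generate_lr_reference(config: SimConfig) -> pd.DataFrame:
    """Draw ``n_lr_pairs`` LR pairs over disjoint ligand and receptor genes.

    Deterministic in the config seed; the same table is used internally by
    :func:`generate_expression`, so the two stay consistent.
    """
    config.validate()
    rng = _rng(config, 1)
    genes = _gene_ids(config)
    chosen = rng.choice(config.n_genes, size=2 * config.n_lr_pairs, replace=False)
    ligands = [genes[i] for i in chosen[: config.n_lr_pairs]]
    receptors = [genes[i] for i in chosen[config.n_lr_pairs:]]
    width = max(3, len(str(config.n_lr_pairs)))
    return pd.DataFrame(
        {
            "pair_id": [f"LR{i:0{width}d}" for i in range(1, config.n_lr_pairs + 1)],
            "ligand": ligands,
            "receptor": receptors,
        }
    )


def _plant_plan(config: SimConfig, reference: pd.DataFrame) -> dict[str, PlantedPair]:
    """Assign planted pairs, their contrast pattern and source/target types."""
    rng = _rng(config, 2)
    types = list(config.cell_types)
    idx = rng.choice(len(reference), size=config.n_planted_pairs, replace=False)
    planted: dict[str, PlantedPair] = {}
    for j, i in enumerate(sorted(idx)):
        row = reference.iloc[i]
        name, eff, sets = _PLANT_PATTERNS[j % len(_PLANT_PATTERNS)]
        eff = frozenset(eff & set(config.conditions))
        source = types[int(rng.integers(len(types)))]
        target = types[int(rng.integers(len(types)))]
        planted[row.pair_id] = PlantedPair(
            pair_id=row.pair_id, ligand=row.ligand, receptor=row.receptor,
            source=source, target=target, pattern=name,
            effect_conditions=eff, expected_sets=sets,
        )
    return planted


def generate_expression(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the annotated count matrix and return it with its ground truth.

    Counts are NB(mean = gene mean x size factor x planted multiplier,
    dispersion = ``nb_dispersion``), drawn as a gamma-Poisson mixture.  With
    ``effect_log2fc = 0`` planted and background genes are exchangeable.
    """
    config.validate()
    reference = generate_lr_reference(config)
    planted = _plant_plan(config, reference)
    rng = _rng(config, 3)

    genes = _gene_ids(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_mu = rng.lognormal(mean=math.log(config.baseline_mean),
                            sigma=config.gene_mean_sigma, size=config.n_genes)

    types = list(config.cell_types)
    props = np.array([config.cell_types[t] for t in types], dtype=float)
    props = props / props.sum()

    n_cond = len(config.conditions)
    n_cells = n_cond * config.n_cells_per_condition
    cond_labels = np.repeat(config.conditions, config.n_cells_per_condition)
    type_labels = np.concatenate([
        np.asarray(types, dtype=object)[
            rng.choice(len(types), size=config.n_cells_per_condition, p=props)
        ]
        for _ in range(n_cond)
    ])
    size_factors = rng.lognormal(mean=0.0, sigma=config.size_factor_sigma, size=n_cells)

    mu = np.outer(size_factors, gene_mu)
    fold = 2.0 ** config.effect_log2fc
    for p in planted.values():
        in_eff = np.isin(cond_labels, list(p.effect_conditions))
        mu[in_eff & (type_labels == p.source), gene_index[p.ligand]] *= fold
        mu[in_eff & (type_labels == p.target), gene_index[p.receptor]] *= fold

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=shape, scale=mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.float64)

    width = len(str(n_cells))
    obs = pd.DataFrame(
        {"condition": pd.Categorical(cond_labels, categories=config.conditions),
         "cell_type": pd.Categorical(type_labels, categories=types)},
        index=[f"C{i:0{width}d}" for i in range(1, n_cells + 1)],
    )
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    adata.uns["normalized"] = False

    herb_rng = _rng(config, 4)
    hit_idx = int(herb_rng.integers(config.n_herbs))
    hwidth = max(2, len(str(config.n_herbs)))
    true_hit = f"HERB{hit_idx + 1:0{hwidth}d}"
    membership = {
        label: frozenset(
            pid for pid, p in planted.items() if label in p.expected_sets
        )
        for label in "ABCD"
    }
    truth = GroundTruth(planted_pairs=planted, true_hit_herb=true_hit,
                        expected_set_membership=membership)
    return adata, truth


def generate_target_profiles(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Herb target panel: one planted true hit, ``n_herbs - 1`` uniform decoys.

    The true hit receives ``floor(planted_overlap_fraction x n_planted_genes)``
    planted genes (sampled without replacement), padded with random non-planted
    genes to ``targets_per_herb``.  Returns a long table (entity_id, gene).
    """
    config.validate()
    rng = _rng(config, 5)
    genes = np.array(_gene_ids(config), dtype=object)
    planted_genes = np.array(sorted(truth.planted_genes), dtype=object)
    hwidth = max(2, len(str(config.n_herbs)))
    rows: list[tuple[str, str]] = []
    for i in range(1, config.n_herbs + 1):
        herb = f"HERB{i:0{hwidth}d}"
        if herb == truth.true_hit_herb:
            n_hit = int(math.floor(config.planted_overlap_fraction * len(planted_genes)))
            hit = rng.choice(planted_genes, size=n_hit, replace=False)
            n_fill = config.targets_per_herb - n_hit
            # filler excludes only already-chosen genes, so at overlap 0 the
            # true hit is exchangeable with the decoys
            pool = np.array([g for g in genes if g not in set(hit)], dtype=object)
            fill = rng.choice(pool, size=n_fill, replace=False)
            targets = np.concatenate([hit, fill])
        else:
            targets = rng.choice(genes, size=config.targets_per_herb, replace=False)
        rows.extend((herb, g) for g in sorted(targets))
    return pd.DataFrame(rows, columns=["entity_id", "gene"])


def generate_ppi(
    config: SimConfig,
    truth: GroundTruth,
    targets: pd.DataFrame | None = None,
    attachment: int = 2,
) -> nx.Graph:
    """Scale-free PPI over the gene universe with planted proximity.

    A preferential-attachment graph is built over all genes, then the true-hit
    herb's target genes are wired to within graph distance 2 of a planted LR
    gene (an edge to a random neighbor of a planted gene) where they are not
    already, so drug-target/gene-set closeness is recoverable by construction.
    """
    config.validate()
    if config.n_genes < 3:
        raise ValueError("PPI generation needs at least 3 nodes")
    rng = _rng(config, 6)
    seed_int = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(config.n_genes, attachment, seed=seed_int)
    genes = _gene_ids(config)
    order = rng.permutation(config.n_genes)
    g = nx.relabel_nodes(g, {i: genes[order[i]] for i in range(config.n_genes)})

    planted_genes = sorted(truth.planted_genes)
    if planted_genes:
        if targets is not None:
            hit_targets = sorted(
                set(targets.loc[targets.entity_id == truth.true_hit_herb, "gene"])
            )
        else:
            hit_targets = []
        dist_to_planted = _multi_source_distances(g, planted_genes)
        for t in hit_targets:
            if dist_to_planted.get(t, np.inf) > 2:
                anchor = planted_genes[int(rng.integers(len(planted_genes)))]
                nbrs = sorted(g[anchor])
                via = nbrs[int(rng.integers(len(nbrs)))] if nbrs else anchor
                g.add_edge(t, via)
    return g


def _multi_source_distances(g: nx.Graph, sources: Sequence[str]) -> dict[str, int]:
    return {
        node: int(d)
        for node, d in nx.multi_source_dijkstra_path_length(
            g, set(s for s in sources if s in g), weight=None
        ).items()
    }


_DESCRIPTOR_COLUMNS = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")


def generate_descriptors(n_compounds: int, seed: int, ugly_fraction: float = 0.4) -> pd.DataFrame:
    """Physicochemical descriptor table for a synthetic compound panel.

    A mixture of conventionally drug-like compounds and large, flexible,
    alert-laden ones (the latter mimicking polysaccharides and polyphenol
    oligomers common in food-derived panels), so a druglikeness filter at a
    moderate threshold splits the panel nontrivially.
    """
    if n_compounds < 0:
        raise ValueError("n_compounds must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    width = max(3, len(str(max(n_compounds, 1))))
    rows = []
    for i in range(n_compounds):
        ugly = rng.random() < ugly_fraction
        if ugly:
            row = dict(
                MW=float(rng.uniform(550, 1400)),
                ALOGP=float(rng.normal(1.0, 3.0)),
                HBA=int(rng.integers(8, 25)),
                HBD=int(rng.integers(5, 16)),
                PSA=float(rng.uniform(150, 400)),
                ROTB=int(rng.integers(10, 30)),
                AROM=int(rng.integers(0, 8)),
                ALERTS=int(rng.integers(1, 5)),
            )
        else:
            row = dict(
                MW=float(rng.uniform(160, 480)),
                ALOGP=float(rng.normal(2.5, 1.2)),
                HBA=int(rng.integers(1, 8)),
                HBD=int(rng.integers(0, 4)),
                PSA=float(rng.uniform(20, 120)),
                ROTB=int(rng.integers(0, 9)),
                AROM=int(rng.integers(0, 4)),
                ALERTS=int(rng.poisson(0.3)),
            )
        rows.append({"compound_id": f"CMP{i + 1:0{width}d}", **row})
    return pd.DataFrame(rows, columns=["compound_id", *_DESCRIPTOR_COLUMNS])


def generate_pathways(
    config: SimConfig,
    truth: GroundTruth,
    n_pathways: int = 12,
    size_range: tuple[int, int] = (10, 25),
) -> dict[str, set[str]]:
    """Pathway gene sets: random draws plus one set enriched in planted genes."""
    config.validate()
    rng = _rng(config, 8)
    genes = np.array(_gene_ids(config), dtype=object)
    out: dict[str, set[str]] = {}
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        out[f"PATH{i:02d}"] = set(rng.choice(genes, size=size, replace=False))
    planted = sorted(truth.planted_genes)
    if planted:
        size = max(len(planted), size_range[0])
        extra = rng.choice(
            [g for g in genes if g not in truth.planted_genes],
            size=max(0, size - len(planted)), replace=False,
        )
        out["PATH_PLANTED"] = set(planted) | set(extra)
    return out
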