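"""PPI network-target analysis and ontology-based gene-set similarity.

Two complementary notions of closeness between a drug-target set and an
effect gene set:

* **Network proximity** — the mean, over effect genes, of the shortest-path
  distance to the nearest target in a protein-protein interaction graph,
  standardized into a z-score against degree-binned random target sets of
  equal size (negative z = closer than degree-matched chance).
* **Wang semantic similarity** — DAG-based similarity between ontology
  terms in which each edge type contributes a fixed semantic factor
  (is_a 0.8, part_of 0.6), aggregated over gene sets by best-match
  averaging in both directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityResult",
    "OntologyDAG",
    "build_subnetwork",
    "proximity",
    "wang_term_similarity",
    "geneset_similarity",
]


# ---------------------------------------------------------------- proximity

@dataclass(frozen=True)
class ProximityResult:
    d_obs: float
    null_mean: float
    null_sd: float
    z: float | None
    n_random: int
    n_unreachable: int = 0


def build_subnetwork(
    network: nx.Graph,
    groups: Mapping[str, Iterable[str]],
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph over the union of node groups, with memberships.

    Unmapped identifiers are logged and dropped.  Returns the subgraph and a
    node table with one boolean column per group (multi-membership allowed).
    """
    mapped: dict[str, set[str]] = {}
    for name, genes in groups.items():
        genes = set(genes)
        inside = genes & set(network.nodes)
        missing = len(genes) - len(inside)
        if missing:
            logger.warning("group %r: %d identifier(s) not in network dropped", name, missing)
        mapped[name] = inside
    union = set().union(*mapped.values()) if mapped else set()
    if not union:
        raise ValueError("no group member maps into the network")
    sub = network.subgraph(union).copy()
    table = pd.DataFrame(
        {name: [node in members for node in sorted(union)] for name, members in mapped.items()},
        index=pd.Index(sorted(union), name="node"),
    )
    return sub, table


def _min_distances_to(network: nx.Graph, sources: set[str], queries: Iterable[str]) -> dict[str, float]:
    dist = nx.multi_source_dijkstra_path_length(network, sources, weight=None)
    return {q: float(dist[q]) if q in dist else math.inf for q in queries}


def _degree_bins(network: nx.Graph, min_bin_size: int = 20) -> tuple[dict[str, int], dict[int, list[str]]]:
    """log2-degree bins, short bins merged upward into the next bin."""
    degrees = dict(network.degree())
    raw_bin = {n: int(math.log2(d)) if d > 0 else -1 for n, d in degrees.items()}
    levels = sorted(set(raw_bin.values()))
    members: dict[int, list[str]] = {lvl: [] for lvl in levels}
    for n in sorted(network.nodes):
        members[raw_bin[n]].append(n)
    merged: dict[int, list[str]] = {}
    carry: list[str] = []
    for lvl in levels:
        carry.extend(members[lvl])
        if len(carry) >= min_bin_size or lvl == levels[-1]:
            merged[lvl] = carry
            carry = []
    if carry:  # leftover short top bin: fold into the highest merged bin
        top = max(merged)
        merged[top].extend(carry)
    node_bin: dict[str, int] = {}
    for lvl, nodes in merged.items():
        for n in nodes:
            node_bin[n] = lvl
    return node_bin, merged


def proximity(
    network: nx.Graph,
    targets: Iterable[str],
    gene_set: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
    min_bin_size: int = 20,
) -> ProximityResult:
    """Closest-distance proximity of a target set to a gene set with a
    degree-aware permutation z-score.

    d_obs = mean over g in gene_set of min over t in targets of d(g, t);
    the null resamples target sets of equal size within log2-degree bins.
    Unreachable gene-set members are excluded with a warning.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    targets = sorted(set(targets) & set(network.nodes))
    gene_set = sorted(set(gene_set) & set(network.nodes))
    if not targets or not gene_set:
        raise ValueError("targets and gene_set must be nonempty after mapping into the network")

    def mean_min_distance(target_nodes: set[str]) -> tuple[float, int]:
        dist = _min_distances_to(network, target_nodes, gene_set)
        finite = [d for d in dist.values() if math.isfinite(d)]
        if not finite:
            raise ValueError("all gene-set members unreachable from targets")
        return float(np.mean(finite)), len(gene_set) - len(finite)

    d_obs, n_unreachable = mean_min_distance(set(targets))
    if n_unreachable:
        logger.warning("proximity: %d unreachable gene-set member(s) excluded", n_unreachable)

    node_bin, bin_members = _degree_bins(network, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    bin_counts: dict[int, int] = {}
    for t in targets:
        bin_counts[node_bin[t]] = bin_counts.get(node_bin[t], 0) + 1
    for i in range(n_random):
        sample: list[str] = []
        for lvl, count in bin_counts.items():
            pool = bin_members[lvl]
            idx = rng.choice(len(pool), size=count, replace=False)
            sample.extend(pool[j] for j in idx)
        null[i], _ = mean_min_distance(set(sample))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):  # numerically degenerate
        null_sd = 0.0
    if null_sd == 0.0:
        logger.warning("proximity: degenerate null (sd = 0); z undefined")
        z = None
    else:
        z = float((d_obs - null_mean) / null_sd)
    return ProximityResult(d_obs=d_obs, null_mean=null_mean, null_sd=null_sd,
                           z=z, n_random=n_random, n_unreachable=n_unreachable)


# ------------------------------------------------------- Wang similarity

DEFAULT_FACTORS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """Term DAG (edges child -> parent, each with a relation kind) plus
    term -> gene annotations."""

    graph: nx.DiGraph
    factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)  # gene -> terms

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph must be acyclic")
        for rel, w in self.factors.items():
            if not 0 < w < 1:
                raise ValueError(f"semantic factor for {rel!r} must lie in (0, 1)")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],  # (term, parent, relation)
        annotations: Mapping[str, Iterable[str]] | None = None,
        factors: Mapping[str, float] | None = None,
    ) -> "OntologyDAG":
        g = nx.DiGraph()
        for child, parent, rel in edges:
            g.add_edge(child, parent, relation=rel)
        return cls(
            graph=g,
            factors=dict(factors) if factors else dict(DEFAULT_FACTORS),
            annotations={g_: frozenset(t) for g_, t in (annotations or {}).items()},
        )

    @classmethod
    def from_tsv(cls, path, annotations_gmt=None, factors=None) -> "OntologyDAG":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"term", "parent", "relation"} - set(df.columns)
        if need:
            raise ValueError(f"ontology TSV missing columns: {sorted(need)}")
        ann = None
        if annotations_gmt is not None:
            from .io import read_gmt

            term_genes = read_gmt(annotations_gmt)
            ann: dict[str, set[str]] = {}
            for term, genes in term_genes.items():
                for g_ in genes:
                    ann.setdefault(g_, set()).add(term)
        return cls.from_edges(df.itertuples(index=False, name=None), annotations=ann, factors=factors)

    def s_values(self, term: str) -> dict[str, float]:
        """Semantic contributions of ``term``'s ancestry (term itself = 1).

        S(parent) = max over child edges on paths from ``term`` of
        factor(edge) * S(child).
        """
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in DAG")
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt = []
            for node in frontier:
                for parent in self.graph.successors(node):
                    rel = self.graph.edges[node, parent].get("relation", "is_a")
                    w = self.factors.get(rel, min(self.factors.values()))
                    cand = w * s[node]
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return s


def wang_term_similarity(t1: str, t2: str, dag: OntologyDAG) -> float:
    """Wang similarity: shared-ancestry S-value overlap normalized by the
    terms' total semantic values."""
    s1 = dag.s_values(t1)
    s2 = dag.s_values(t2)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def _gene_similarity(g1: str, g2: str, dag: OntologyDAG) -> float:
    """Best-match-average over the two genes' annotation term sets."""
    t1 = dag.annotations.get(g1, frozenset())
    t2 = dag.annotations.get(g2, frozenset())
    if not t1 or not t2:
        raise ValueError(f"gene {g1 if not t1 else g2!r} has no ontology annotations")
    sims = np.array([[wang_term_similarity(a, b, dag) for b in sorted(t2)] for a in sorted(t1)])
    return float((sims.max(axis=1).mean() + sims.max(axis=0).mean()) / 2)


def geneset_similarity(
    set1: Iterable[str],
    set2: Iterable[str],
    dag: OntologyDAG,
    combine: str = "bma",
) -> float:
    """Best-match-average similarity between two gene sets in [0, 1]."""
    if combine != "bma":
        raise ValueError("only best-match-average ('bma') aggregation is supported")
    genes1 = sorted(g for g in set(set1) if dag.annotations.get(g))
    genes2 = sorted(g for g in set(set2) if dag.annotations.get(g))
    if not genes1 or not genes2:
        raise ValueError("each gene set must contain at least one annotated gene")
    sims = np.array([[_gene_similarity(a, b, dag) for b in genes2] for a in genes1])
    return float((sims.max(axis=1).mean() + sims.max(axis=0).mean()) / 2)
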