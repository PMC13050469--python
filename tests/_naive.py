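"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enum_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws from the universe."""
    hits = 0
    total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def step_up_bh(p: list[float]) -> list[float]:
    """Literal step-up BH: sort, scale, take running minima, restore order."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = math.inf
    for pos in range(m - 1, -1, -1):
        i = indexed[pos]
        running = min(running, p[i] * m / (pos + 1), 1.0)
        adj[i] = running
    return adj


def naive_type_means(values, cell_types, conditions, genes):
    """Per-(type, condition, gene) means via explicit cell loops."""
    out = {}
    strata = sorted(set(zip(cell_types, conditions)))
    for ct, cond in strata:
        idx = [i for i in range(len(cell_types)) if cell_types[i] == ct and conditions[i] == cond]
        for j, g in enumerate(genes):
            out[(g, ct, cond)] = sum(values[i][j] for i in idx) / len(idx)
    return out


def naive_interaction_scores(values, cell_types, conditions, genes, reference):
    """All (pair, source, target, condition) scores via the mean product."""
    means = naive_type_means(values, cell_types, conditions, genes)
    types = sorted(set(cell_types))
    conds = sorted(set(conditions))
    gene_set = set(genes)
    out = {}
    for _, row in reference.iterrows():
        if row["ligand"] not in gene_set or row["receptor"] not in gene_set:
            continue
        for src in types:
            for tgt in types:
                for cond in conds:
                    try:
                        lm = means[(row["ligand"], src, cond)]
                        rm = means[(row["receptor"], tgt, cond)]
                    except KeyError:
                        continue
                    out[(row["pair_id"], src, tgt, cond)] = lm * rm
    return out


def recursive_wang_s_values(term, dag):
    """S-values by memoized recursion over parents (independent of the
    implementation's frontier propagation)."""
    memo = {}

    def visit(node, weight):
        if weight <= memo.get(node, 0.0):
            return
        memo[node] = weight
        for parent in dag.graph.successors(node):
            rel = dag.graph.edges[node, parent].get("relation", "is_a")
            visit(parent, weight * dag.factors[rel])

    visit(term, 1.0)
    return memo


def naive_wang_similarity(t1, t2, dag):
    s1 = recursive_wang_s_values(t1, dag)
    s2 = recursive_wang_s_values(t2, dag)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def naive_geneset_similarity(set1, set2, dag):
    """Best-match-average over genes, gene similarity itself a BMA over terms."""

    def gene_sim(a, b):
        ta, tb = sorted(dag.annotations[a]), sorted(dag.annotations[b])
        mat = [[naive_wang_similarity(x, y, dag) for y in tb] for x in ta]
        row_best = sum(max(row) for row in mat) / len(ta)
        col_best = sum(max(mat[i][j] for i in range(len(ta))) for j in range(len(tb))) / len(tb)
        return (row_best + col_best) / 2

    g1 = sorted(g for g in set1 if dag.annotations.get(g))
    g2 = sorted(g for g in set2 if dag.annotations.get(g))
    mat = [[gene_sim(a, b) for b in g2] for a in g1]
    row_best = sum(max(row) for row in mat) / len(g1)
    col_best = sum(max(mat[i][j] for i in range(len(g1))) for j in range(len(g2))) / len(g2)
    return (row_best + col_best) / 2


def spearman_by_ranks(x, y):
    """Spearman rho from average ranks computed by exhaustive comparison."""

    def ranks(v):
        out = []
        for a in v:
            less = sum(1 for b in v if b < a)
            equal = sum(1 for b in v if b == a)
            out.append(less + (equal + 1) / 2)
        return out

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    cov = np.mean([(a - mx) * (b - my) for a, b in zip(rx, ry)])
    return cov / (np.std(rx) * np.std(ry))
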