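import anndata as ad
import numpy as np
import pandas as pd
import pytest

import herbscreen as hs


def make_adata(n_cells=50, n_genes=20, conditions=("Nor", "F1"), types=("T1", "T2", "T3"), seed=42):
    """Small random raw-count fixture with annotations, built independently
    of the package's generator."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(2.0, size=(n_cells, n_genes)).astype(float)
    counts[0] += 1  # guard against an all-zero first cell
    obs = pd.DataFrame(
        {
            "condition": rng.choice(conditions, size=n_cells),
            "cell_type": rng.choice(types, size=n_cells),
        },
        index=[f"c{i:03d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=pd.Index([f"g{j:02d}" for j in range(n_genes)], name="gene_id"))
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["normalized"] = False
    return adata


@pytest.fixture
def small_adata():
    return make_adata()


@pytest.fixture
def small_reference(small_adata):
    genes = list(small_adata.var_names)
    return pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(5)],
            "ligand": genes[0:10:2],
            "receptor": genes[1:11:2],
        }
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated study shared across tests."""
    cfg = hs.SimConfig(seed=7)
    adata, truth = hs.generate_expression(cfg)
    reference = hs.generate_lr_reference(cfg)
    return cfg, adata, truth, reference


@pytest.fixture(scope="session")
def default_records(default_sim):
    cfg, adata, truth, reference = default_sim
    norm = hs.normalize(adata)
    return hs.score_all(norm, reference)


@pytest.fixture
def toy_dag():
    """Six-term DAG with mixed edge kinds and gene annotations.

            ROOT
           /    \\
          M1     M2          (is_a)
         /  \\     \\
        T1   T2     T3       (T1 is_a M1, T2 part_of M1, T3 is_a M2)
    plus an isolated term X (its own component).
    """
    edges = [
        ("M1", "ROOT", "is_a"),
        ("M2", "ROOT", "is_a"),
        ("T1", "M1", "is_a"),
        ("T2", "M1", "part_of"),
        ("T3", "M2", "is_a"),
        ("X", "X_ROOT", "is_a"),
    ]
    annotations = {
        "geneA": {"T1"},
        "geneB": {"T2"},
        "geneC": {"T3", "M2"},
        "geneX": {"X"},
    }
    return hs.OntologyDAG.from_edges(edges, annotations=annotations)
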