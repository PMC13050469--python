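"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as MatrixMarket (cells x genes) plus gene/cell
annotation TSVs; gene sets as GMT; everything else as TSV or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

ANNOTATION_COLUMNS = ("cell_id", "condition", "cell_type")


def write_expression(adata: ad.AnnData, prefix: str | Path) -> list[Path]:
    """Write an annotated matrix as <prefix>.mtx / <prefix>.genes.tsv / <prefix>.cells.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx = prefix.with_suffix(".mtx")
    x = adata.X
    scipy.io.mmwrite(str(mtx), sp.coo_matrix(x))
    genes = prefix.parent / (prefix.name + ".genes.tsv")
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(genes, sep="\t", index=False)
    cells = prefix.parent / (prefix.name + ".cells.tsv")
    pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "condition": adata.obs["condition"].astype(str),
            "cell_type": adata.obs["cell_type"].astype(str),
        }
    ).to_csv(cells, sep="\t", index=False)
    return [mtx, genes, cells]


def read_expression(prefix: str | Path) -> ad.AnnData:
    """Read a matrix written by :func:`write_expression`."""
    prefix = Path(prefix)
    x = scipy.io.mmread(str(prefix.with_suffix(".mtx")))
    genes = pd.read_csv(prefix.parent / (prefix.name + ".genes.tsv"), sep="\t")
    cells = pd.read_csv(prefix.parent / (prefix.name + ".cells.tsv"), sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell annotation TSV missing columns: {sorted(missing)}")
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=np.asarray(sp.coo_matrix(x).todense(), dtype=np.float64),
        obs=obs[["condition", "cell_type"]],
        var=pd.DataFrame(index=genes["gene_id"].astype(str)),
    )
    adata.uns["normalized"] = False
    return adata


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = set(fields[2:])
    return out


def write_lr_reference(reference: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    reference[["pair_id", "ligand", "receptor"]].to_csv(path, sep="\t", index=False)
    return path


def read_lr_reference(path: str | Path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"pair_id", "ligand", "receptor"} - set(ref.columns)
    if missing:
        raise ValueError(f"LR reference missing columns: {sorted(missing)}")
    return ref


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(edges), columns=["node_a", "node_b"]).to_csv(path, sep="\t", index=False)
    return path


def read_edge_list(path: str | Path):
    import networkx as nx

    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    return g


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonify)
    return path


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
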