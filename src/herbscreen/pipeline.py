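"""Config-driven orchestration of the screening stages.

Stages (dependency order): simulate -> score -> sets -> enrich -> compounds
-> network.  A YAML config validates into :class:`RunConfig`; every run
writes a JSON manifest recording effective parameters and SHA-256 hashes of
all outputs, so deterministic stages are idempotent (a stage whose config and
outputs already match its manifest entry is skipped).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import diffsets, enrichment, interactions, io, netsim, simulate
from .qed import filter_compounds
from .expression import normalize, type_means

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "sets", "enrich", "compounds", "network")

__all__ = ["RunConfig", "SimulateBlock", "ParamsBlock", "validate_config", "run", "STAGES"]


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes: int = 200
    n_cells_per_condition: int = 300
    conditions: tuple[str, ...] = ("Nor", "A1", "A2", "F1", "F2")
    reference_condition: str = "Nor"
    cell_types: dict[str, float] = Field(
        default_factory=lambda: {"Epithelial": 0.4, "Stromal": 0.35, "Myeloid": 0.25}
    )
    n_lr_pairs: int = 60
    n_planted_pairs: int = 6
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 1.0
    n_herbs: int = 20
    targets_per_herb: int = 30
    planted_overlap_fraction: float = 0.7
    n_compounds: int = 50

    def to_sim_config(self, seed: int) -> simulate.SimConfig:
        kwargs = self.model_dump()
        kwargs.pop("n_compounds")
        return simulate.SimConfig(**kwargs, seed=seed)


class InputsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    expression_prefix: Optional[str] = None
    lr_reference: Optional[str] = None
    targets: Optional[str] = None
    descriptors: Optional[str] = None
    ppi_edges: Optional[str] = None
    pathways: Optional[str] = None
    ground_truth: Optional[str] = None


class ParamsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scale: float = Field(default=1e4, gt=0)
    min_cells: int = Field(default=10, ge=1)
    tau: float = Field(default=1.0, ge=0)
    eps: float = Field(default=0.01, gt=0)
    mode: Literal["union", "intersection"] = "union"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    qed_threshold: float = Field(default=0.3, ge=0, le=1)
    qed_weights: Literal["mean", "max", "unit"] = "mean"
    score_threshold: float = Field(default=0.0, ge=0)
    n_perm: int = Field(default=0, ge=0)
    n_random: int = Field(default=200, ge=100)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    simulate: Optional[SimulateBlock] = None
    inputs: InputsBlock = Field(default_factory=InputsBlock)
    params: ParamsBlock = Field(default_factory=ParamsBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def resolved_input(self, key: str) -> Path:
        """Path of an input: explicit, else the simulate stage's output."""
        explicit = getattr(self.inputs, key)
        if explicit is not None:
            return Path(explicit)
        defaults = {
            "expression_prefix": "expression",
            "lr_reference": "lr_reference.tsv",
            "targets": "target_profiles.tsv",
            "descriptors": "descriptors.tsv",
            "ppi_edges": "ppi_edges.tsv",
            "pathways": "pathways.gmt",
            "ground_truth": "ground_truth.json",
        }
        return Path(self.outdir) / defaults[key]


def validate_config(raw: dict | RunConfig) -> list[str]:
    """Schema, range and file-existence check; empty list = valid."""
    errors: list[str] = []
    if isinstance(raw, RunConfig):
        config = raw
    else:
        try:
            config = RunConfig.model_validate(raw)
        except ValidationError as exc:
            return [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
    if config.simulate is None:
        for key in ("lr_reference", "targets", "ppi_edges"):
            path = getattr(config.inputs, key)
            if path is None:
                errors.append(f"inputs.{key}: required when no simulate block is given")
            elif not Path(path).exists():
                errors.append(f"inputs.{key}: file not found: {path}")
        prefix = config.inputs.expression_prefix
        if prefix is None:
            errors.append("inputs.expression_prefix: required when no simulate block is given")
        elif not Path(prefix).with_suffix(".mtx").exists():
            errors.append(f"inputs.expression_prefix: matrix not found: {prefix}.mtx")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_digest(config: RunConfig, stage: str) -> str:
    payload = {"stage": stage, "seed": config.seed,
               "params": config.params.model_dump(),
               "simulate": config.simulate.model_dump() if config.simulate else None}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"package": "herbscreen", "version": _safe_version(), "stages": {}}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)
            self.data.setdefault("stages", {})

    def stage_current(self, stage: str, digest: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry or entry.get("config_digest") != digest:
            return False
        return all(
            Path(p).exists() and _sha256(Path(p)) == h for p, h in entry["outputs"].items()
        )

    def record(self, stage: str, digest: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "config_digest": digest,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _safe_version() -> str:
    try:
        return pkg_version("herbscreen")
    except Exception:
        return "unknown"


def run(config: RunConfig, stages: list[str] | None = None, force: bool = False) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    for stage in requested:
        digest = _config_digest(config, stage)
        if not force and manifest.stage_current(stage, digest):
            logger.info("stage %s up to date; skipped", stage)
            continue
        logger.info("running stage %s", stage)
        outputs = _STAGE_FUNCS[stage](config, outdir)
        manifest.record(stage, digest, outputs)
    return manifest.data


# ------------------------------------------------------------------ stages

def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    if config.simulate is None:
        raise ValueError("simulate stage requested without a simulate block")
    sim = config.simulate.to_sim_config(config.seed)
    adata, truth = simulate.generate_expression(sim)
    reference = simulate.generate_lr_reference(sim)
    targets = simulate.generate_target_profiles(sim, truth)
    ppi = simulate.generate_ppi(sim, truth, targets=targets)
    descriptors = simulate.generate_descriptors(config.simulate.n_compounds, seed=config.seed)
    pathways = simulate.generate_pathways(sim, truth)
    outputs = []
    outputs += io.write_expression(adata, outdir / "expression")
    outputs.append(io.write_lr_reference(reference, outdir / "lr_reference.tsv"))
    tpath = outdir / "target_profiles.tsv"
    targets.to_csv(tpath, sep="\t", index=False)
    outputs.append(tpath)
    dpath = outdir / "descriptors.tsv"
    descriptors.to_csv(dpath, sep="\t", index=False)
    outputs.append(dpath)
    outputs.append(io.write_edge_list(ppi.edges, outdir / "ppi_edges.tsv"))
    outputs.append(io.write_gmt(pathways, outdir / "pathways.gmt"))
    outputs.append(io.write_json(truth.to_dict(), outdir / "ground_truth.json"))
    return outputs


def _load_normalized(config: RunConfig):
    adata = io.read_expression(config.resolved_input("expression_prefix"))
    return normalize(adata, scale=config.params.scale)


def _stage_score(config: RunConfig, outdir: Path) -> list[Path]:
    adata = _load_normalized(config)
    reference = io.read_lr_reference(config.resolved_input("lr_reference"))
    records = interactions.score_all(adata, reference, min_cells=config.params.min_cells)
    if config.params.n_perm > 0:
        pvals = [
            interactions.permutation_test(adata, row, n_perm=config.params.n_perm,
                                          seed=config.seed + i)
            for i, (_, row) in enumerate(records.iterrows())
        ]
        records["permutation_p"] = pvals
    path = outdir / "interactions.tsv"
    records.to_csv(path, sep="\t", index=False)
    counts = interactions.interaction_counts(records, threshold=config.params.score_threshold,
                                             alpha=config.params.alpha)
    cpath = outdir / "interaction_counts.tsv"
    counts.to_csv(cpath, sep="\t", index=False)
    return [path, cpath]


def _stage_sets(config: RunConfig, outdir: Path) -> list[Path]:
    records = pd.read_csv(outdir / "interactions.tsv", sep="\t")
    if records.empty:
        raise ValueError("sets stage: no upstream interaction records")
    reference = io.read_lr_reference(config.resolved_input("lr_reference"))
    sets = diffsets.derive_sets(records, reference, tau=config.params.tau,
                                eps=config.params.eps, mode=config.params.mode)
    rows = [
        {"set_label": label, "pair_id": p, "source": s, "target": t}
        for label, es in sets.items()
        for (p, s, t) in sorted(es.pair_members)
    ]
    ppath = outdir / "effect_sets_pairs.tsv"
    pd.DataFrame(rows, columns=["set_label", "pair_id", "source", "target"]).to_csv(
        ppath, sep="\t", index=False
    )
    gpath = io.write_gmt({label: es.gene_members for label, es in sets.items()},
                         outdir / "effect_sets_genes.gmt")
    return [ppath, gpath]


def _effect_sets_genes(outdir: Path) -> dict[str, set[str]]:
    return io.read_gmt(outdir / "effect_sets_genes.gmt")


def _universe(config: RunConfig) -> set[str]:
    genes = pd.read_csv(
        Path(str(config.resolved_input("expression_prefix"))).parent
        / (Path(str(config.resolved_input("expression_prefix"))).name + ".genes.tsv"),
        sep="\t",
    )
    return set(genes["gene_id"].astype(str))


def _stage_enrich(config: RunConfig, outdir: Path) -> list[Path]:
    targets = pd.read_csv(config.resolved_input("targets"), sep="\t", dtype=str)
    panel = enrichment.profiles_from_table(targets)
    sets = _effect_sets_genes(outdir)
    results = enrichment.enrich_panel(panel, sets, _universe(config))
    rpath = outdir / "herb_enrichment.tsv"
    results.to_csv(rpath, sep="\t", index=False)
    table = enrichment.rank_entities(results, alpha=config.params.alpha)
    spath = outdir / "herb_screening.tsv"
    table.to_csv(spath, sep="\t", index=False)
    return [rpath, spath]


def _stage_compounds(config: RunConfig, outdir: Path) -> list[Path]:
    descriptors = pd.read_csv(config.resolved_input("descriptors"), sep="\t")
    scored = filter_compounds(descriptors, threshold=config.params.qed_threshold,
                              weights=config.params.qed_weights)
    path = outdir / "compounds_qed.tsv"
    scored.to_csv(path, sep="\t", index=False)
    return [path]


def _stage_network(config: RunConfig, outdir: Path) -> list[Path]:
    network = io.read_edge_list(config.resolved_input("ppi_edges"))
    sets = _effect_sets_genes(outdir)
    targets = pd.read_csv(config.resolved_input("targets"), sep="\t", dtype=str)
    screening = pd.read_csv(outdir / "herb_screening.tsv", sep="\t")
    top_herb = str(screening.iloc[0]["entity_id"])
    herb_targets = set(targets.loc[targets.entity_id == top_herb, "gene"])
    union_genes = set().union(*sets.values()) if sets else set()
    groups = {"effect_genes": union_genes, "herb_targets": herb_targets}
    sub, table = netsim.build_subnetwork(network, groups)
    npath = outdir / "subnetwork_nodes.tsv"
    table.reset_index().to_csv(npath, sep="\t", index=False)
    epath = io.write_edge_list(sub.edges, outdir / "subnetwork_edges.tsv")
    rows = []
    for label, genes in sorted(sets.items()):
        if not genes:
            continue
        try:
            res = netsim.proximity(network, herb_targets, genes,
                                   n_random=config.params.n_random, seed=config.seed)
        except ValueError as exc:
            logger.warning("proximity for set %s skipped: %s", label, exc)
            continue
        rows.append({"set_label": label, "entity_id": top_herb, "d_obs": res.d_obs,
                     "null_mean": res.null_mean, "null_sd": res.null_sd,
                     "z": res.z, "n_random": res.n_random, "k_overlap": len(genes & herb_targets)})
    ppath = outdir / "proximity.tsv"
    pd.DataFrame(rows, columns=["set_label", "entity_id", "d_obs", "null_mean",
                                "null_sd", "z", "n_random", "k_overlap"]).to_csv(
        ppath, sep="\t", index=False
    )
    return [npath, epath, ppath]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "score": _stage_score,
    "sets": _stage_sets,
    "enrich": _stage_enrich,
    "compounds": _stage_compounds,
    "network": _stage_network,
}
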