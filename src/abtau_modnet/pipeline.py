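"""End-to-end orchestration with a reproducibility manifest.

Stages run in dependency order, each reading its inputs from and writing
its outputs to the run directory, so a run can be resumed after deleting
an intermediate file: only stages whose outputs are missing (or downstream
of a rerun stage) are recomputed.  A JSON manifest records, per stage, the
parameters used and SHA-256 hashes of inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cellenrich, embed, mindy, modulemap, netbuild, subnet, synthio, validate
from .containers import Abundance, CellData, WeightedNetwork

__all__ = ["RunConfig", "run_all", "PAPER_DEFAULTS"]

log = logging.getLogger("abtau_modnet")

#: printed defaults of the study: BH alpha, STRING confidence cutoff,
#: kNN k, Louvain resolution, embedding dimension, proximity quantile,
#: stratification fraction, resampling iterations
PAPER_DEFAULTS = dict(
    alpha=0.05, ppi_threshold=0.7, k=25, resolution=1.0, d=512, q=0.05, fraction=0.35, B=1000
)


@dataclass
class RunConfig:
    """All stage parameters plus the synthetic-data configuration."""

    synth: synthio.SynthConfig = field(default_factory=synthio.SynthConfig)
    mmse_min: int = 21
    alpha: float = 0.05
    ppi_threshold: float = 0.7
    use_absolute_r: bool = False
    d: int = 512
    k: int = 25
    resolution: float = 1.0
    q: float = 0.05
    fraction: float = 0.35
    B: int = 1000
    n_bins: int | None = None
    subnet_anchors: tuple[str, ...] = ()  # default: anchor pair + moderators
    composition_subtype: str = "S1"
    seed: int = 0

    def resolved_anchors(self) -> list[str]:
        if self.subnet_anchors:
            return list(self.subnet_anchors)
        return list(self.synth.anchor_pair) + list(self.synth.moderator_names)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        synth_d = d.pop("synth", {})
        for key in ("module_sizes", "anchor_pair", "moderator_names", "histo_betas"):
            if key in synth_d and isinstance(synth_d[key], list):
                synth_d[key] = tuple(synth_d[key])
        if "interaction_strata" in synth_d:
            synth_d["interaction_strata"] = tuple(tuple(x) for x in synth_d["interaction_strata"])
        if "subnet_anchors" in d and isinstance(d["subnet_anchors"], list):
            d["subnet_anchors"] = tuple(d["subnet_anchors"])
        return cls(synth=synthio.SynthConfig(**synth_d), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---- stages -------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    paths = synthio.write_all(cfg.synth, out / "inputs")
    return {name: str(p) for name, p in paths.items()}


def _stage_networks(cfg: RunConfig, out: Path) -> dict:
    ab = Abundance.from_tsv(out / "inputs" / "abundance.tsv")
    ab = netbuild.select_cohort(ab, cfg.mmse_min)
    ab = netbuild.aggregate_by_symbol(ab)
    ab.to_tsv(out / "cohort_abundance.tsv")
    func = netbuild.correlation_network(ab, alpha=cfg.alpha, use_absolute_r=cfg.use_absolute_r)
    ppi_raw = pd.read_csv(out / "inputs" / "ppi.tsv", sep="\t")
    ppi = netbuild.filter_ppi(ppi_raw, threshold=cfg.ppi_threshold)
    func, ppi = netbuild.intersect_nodes(func, ppi)
    func.to_tsv(out / "func_net.tsv")
    ppi.to_tsv(out / "ppi_net.tsv")
    return {"func_net": str(out / "func_net.tsv"), "ppi_net": str(out / "ppi_net.tsv")}


def _stage_embed(cfg: RunConfig, out: Path) -> dict:
    func = WeightedNetwork.from_tsv(out / "func_net.tsv")
    ppi = WeightedNetwork.from_tsv(out / "ppi_net.tsv")
    nodes = sorted(set(func.nodes) | set(ppi.nodes))
    func.nodes = ppi.nodes = nodes
    d = min(cfg.d, len(nodes) - 1)
    emb = embed.fuse_embed([func, ppi], d=d)
    emb.to_tsv(out / "embedding.tsv")
    return {"embedding": str(out / "embedding.tsv")}


def _stage_cluster(cfg: RunConfig, out: Path) -> dict:
    emb = embed.load_embedding(out / "embedding.tsv")
    g = modulemap.knn_graph(emb, k=min(cfg.k, len(emb.node_ids) - 1))
    clusters = modulemap.louvain_cluster(g, resolution=cfg.resolution, seed=cfg.seed)
    clusters.labels.rename_axis("node").to_csv(out / "clusters.tsv", sep="\t")
    cents = modulemap.centroids(emb, clusters)
    cents.to_csv(out / "centroids.tsv", sep="\t")
    modulemap.centroid_relations(cents).to_csv(out / "module_relations.tsv", sep="\t", index=False)
    modulemap.closeness_network(cents).to_tsv(out / "module_net.tsv")
    anchors = clusters.anchor_modules(cfg.resolved_anchors())
    (out / "anchor_modules.json").write_text(json.dumps(anchors, sort_keys=True))
    return {
        "clusters": str(out / "clusters.tsv"),
        "centroids": str(out / "centroids.tsv"),
        "module_relations": str(out / "module_relations.tsv"),
        "module_net": str(out / "module_net.tsv"),
        "anchor_modules": str(out / "anchor_modules.json"),
    }


def _stage_moderators(cfg: RunConfig, out: Path) -> dict:
    ab = Abundance.from_tsv(out / "cohort_abundance.tsv")
    emb = embed.load_embedding(out / "embedding.tsv")
    anchors = tuple(cfg.synth.anchor_pair)
    table = mindy.run_mindy(
        ab, emb, anchors, q=cfg.q, fraction=cfg.fraction, B=cfg.B, n_bins=cfg.n_bins, seed=cfg.seed
    )
    table.to_csv(out / "moderators.tsv", sep="\t", index=False)
    sidecar = {
        "anchors": list(anchors),
        "q": cfg.q,
        "fraction": cfg.fraction,
        "B": cfg.B,
        "n_bins": cfg.n_bins,
        "null": "stratum-permutation",
        "seed": cfg.seed,
    }
    (out / "moderators.json").write_text(json.dumps(sidecar, sort_keys=True))
    return {"moderators": str(out / "moderators.tsv"), "moderators_meta": str(out / "moderators.json")}


def _stage_subnet(cfg: RunConfig, out: Path) -> dict:
    emb = embed.load_embedding(out / "embedding.tsv")
    anchors = [a for a in cfg.resolved_anchors() if a in emb.features.index]
    sim = subnet.similarity_network(emb, q=cfg.q)
    sub = subnet.anchored_subnetwork(sim, emb, anchors, q=cfg.q)
    part = subnet.leading_eigenvector_communities(sub)
    sub.to_tsv(out / "subnet_edges.tsv")
    part.labels.rename_axis("node").to_csv(out / "subnet_communities.tsv", sep="\t")
    return {
        "subnet_edges": str(out / "subnet_edges.tsv"),
        "subnet_communities": str(out / "subnet_communities.tsv"),
    }


def _stage_cellenrich(cfg: RunConfig, out: Path) -> dict:
    values = pd.read_csv(out / "inputs" / "cells.tsv", sep="\t", index_col="cell_id")
    labels = pd.read_csv(out / "inputs" / "cell_labels.tsv", sep="\t", index_col="cell_id")
    cells = CellData(values=values, labels=labels)
    comms = pd.read_csv(out / "subnet_communities.tsv", sep="\t", index_col="node")["community"]
    recs = []
    for cid in sorted(comms.unique()):
        genes = [g for g in comms.index[comms == cid] if g in cells.values.columns]
        if len(genes) < 3:
            continue
        score = cellenrich.module_score(cells, genes, seed=cfg.seed)
        tab = cellenrich.combined_score(cells, score).reset_index()
        tab.insert(0, "community", cid)
        recs.append(tab)
    scores = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame()
    scores.to_csv(out / "community_cell_scores.tsv", sep="\t", index=False)
    comp = cellenrich.composition_test(cells, cfg.composition_subtype)
    payload = {
        "subtype": cfg.composition_subtype,
        "anova": comp["anova"],
        "tukey": None if comp["tukey"] is None else comp["tukey"].to_dict(orient="records"),
    }
    (out / "composition.json").write_text(json.dumps(payload, sort_keys=True, default=str))
    return {
        "community_cell_scores": str(out / "community_cell_scores.tsv"),
        "composition": str(out / "composition.json"),
    }


def _stage_validate(cfg: RunConfig, out: Path) -> dict:
    histo = pd.read_csv(out / "inputs" / "histo.tsv", sep="\t")
    fits = validate.fit_interaction(histo, "tau2_pct", "abeta_pct", "gfap_pct")
    fits.to_csv(out / "interaction_fits.tsv", sep="\t", index=False)
    donor = histo.drop_duplicates("donor").set_index("donor")
    top, bottom = validate.severity_crosstab(
        donor["gpnmb_fpkm"], donor["cerad"], donor["braak"], fraction=cfg.fraction
    )
    top.to_csv(out / "crosstab_top.tsv", sep="\t")
    bottom.to_csv(out / "crosstab_bottom.tsv", sep="\t")
    return {
        "interaction_fits": str(out / "interaction_fits.tsv"),
        "crosstab_top": str(out / "crosstab_top.tsv"),
        "crosstab_bottom": str(out / "crosstab_bottom.tsv"),
    }


STAGES = [
    ("simulate", _stage_simulate),
    ("networks", _stage_networks),
    ("embed", _stage_embed),
    ("cluster", _stage_cluster),
    ("moderators", _stage_moderators),
    ("subnet", _stage_subnet),
    ("cellenrich", _stage_cellenrich),
    ("validate", _stage_validate),
]


def run_all(config: RunConfig, outdir, resume: bool = False) -> dict:
    """Execute every stage in order; returns the manifest dict.

    With ``resume=True``, a stage whose outputs all exist (and with no
    upstream stage rerun) is skipped; downstream stages of any rerun stage
    are recomputed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    cfg_dict = dataclasses.asdict(config)
    manifest: dict = {"config": cfg_dict, "stages": {}}
    upstream_rerun = False
    for name, fn in STAGES:
        prev = previous.get(name)
        can_skip = (
            resume
            and not upstream_rerun
            and prev is not None
            and all(Path(p).exists() for p in prev["outputs"].values())
        )
        if can_skip:
            log.info("stage %s: outputs present, skipped", name)
            manifest["stages"][name] = prev
            continue
        log.info("stage %s: running", name)
        try:
            outputs = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {name!r}: {exc}") from exc
        upstream_rerun = True
        manifest["stages"][name] = {
            "outputs": outputs,
            "hashes": {k: _sha256(Path(p)) for k, p in outputs.items()},
            "seed": config.seed,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
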