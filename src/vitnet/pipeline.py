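"""End-to-end orchestration: abundances -> correlations -> network ->
pathway roles -> hubness and null -> ecology, with a machine-readable report.

The pipeline is a pure function of (inputs, config, seeds): reruns with the
same configuration produce identical reports. The resolved configuration is
serialized into the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from vitnet import correlation as corr_mod
from vitnet import ecology as eco_mod
from vitnet import hubness as hub_mod
from vitnet import network as net_mod
from vitnet import pathways as path_mod
from vitnet.io import (
    AbundanceTable,
    AnnotationSet,
    CorrelationMatrix,
    PathwayCatalog,
    SampleMetadata,
    read_abundance_table,
    read_annotations,
    read_correlation_matrix,
    read_sample_metadata,
    write_correlation_matrix,
    write_network,
)

logger = logging.getLogger("vitnet")


@dataclass
class PipelineConfig:
    """One config for every stage; defaults follow the analysis defaults
    (correlation threshold 0.35, positive edges only, Louvain modules,
    1000 null simulations)."""

    abundance_path: str | None = None
    abundance_unit: str = "fraction"
    annotations_path: str | None = None
    lengths_path: str | None = None
    metadata_path: str | None = None
    catalog_path: str | None = None  # None -> shipped default catalog
    correlation_path: str | None = None  # precomputed matrix bypasses backend

    correlation_method: str = "sparcc"  # sparcc | pearson | spearman
    sparcc: corr_mod.SparccParams = field(default_factory=corr_mod.SparccParams)
    n_perm: int = 0  # permutation p-values off by default
    p_max: float | None = None

    threshold: float = 0.35
    positive_only: bool = True

    hub_method: str = "top_k"
    hub_k: int | None = None
    hub_sd_mult: float = 2.0
    module_method: str = "louvain"

    vitamins: list[str] | None = None  # None -> all catalog vitamins
    near_complete_policy: str = "producer"

    n_sim: int = 1000
    focal_policy: str = "focal_forced_producer"
    focal_nodes: list[str] | None = None  # None -> top-ranked producer per vitamin

    presence_threshold: float = 0.0
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not (0 < self.threshold <= 1):
            raise ValueError(f"threshold {self.threshold} outside (0, 1]")
        if self.correlation_method not in ("sparcc", "pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.near_complete_policy not in ("producer", "auxotroph"):
            raise ValueError(f"unknown policy {self.near_complete_policy!r}")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.abundance_path is None and self.correlation_path is None:
            raise ValueError("need an abundance table or a precomputed correlation")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _compute_correlations(cfg: PipelineConfig, tab: AbundanceTable | None):
    if cfg.correlation_path is not None:
        return read_correlation_matrix(cfg.correlation_path)
    if cfg.correlation_method == "sparcc":
        corr = corr_mod.sparcc_correlations(tab, cfg.sparcc, seed=cfg.seed)
    else:
        corr = corr_mod.naive_correlations(tab, cfg.correlation_method)
    if cfg.n_perm > 0:
        backend = None
        if cfg.correlation_method == "sparcc":
            backend = lambda t: corr_mod.sparcc_correlations(t, cfg.sparcc, cfg.seed)
        corr = corr_mod.permutation_pvalues(
            tab, corr, cfg.n_perm, seed=cfg.seed + 1, backend=backend
        )
    return corr


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage and return the report dictionary.

    When ``cfg.out_dir`` is set, the report, the network (GraphML), the
    correlation matrix and per-stage TSVs are written there as well.
    """
    cfg.validate()
    tab = meta = ann = None
    if cfg.abundance_path is not None:
        tab = read_abundance_table(cfg.abundance_path, cfg.abundance_unit)
    if cfg.metadata_path is not None:
        meta = read_sample_metadata(cfg.metadata_path)
        meta.check_against(tab)
    cat = (
        PathwayCatalog.from_json(cfg.catalog_path)
        if cfg.catalog_path
        else PathwayCatalog.default()
    )
    if cfg.annotations_path is not None:
        ann = read_annotations(cfg.annotations_path, cfg.lengths_path)
        if tab is not None:
            missing = set(tab.genome_ids) - set(ann.genome_ids)
            if missing:
                raise ValueError(
                    "genomes in the abundance table lack annotations: "
                    f"{sorted(missing)}"
                )

    corr = _compute_correlations(cfg, tab)
    net = net_mod.build_network(
        corr, cfg.threshold, cfg.positive_only, cfg.p_max
    )
    report: dict = {"config": cfg.to_dict()}
    if net.number_of_nodes() == 0:
        report["network"] = net_mod.NetworkSummary(0, 0, 0.0, 0.0).to_dict()
        report["warning"] = "empty network: no correlation passed the threshold"
        _write_outputs(cfg, report, corr, net)
        return report

    cent = net_mod.betweenness(net)
    part = net_mod.detect_modules(net, cfg.module_method, seed=cfg.seed)
    hubs = net_mod.delineate_hubs(cent, cfg.hub_method, cfg.hub_k, cfg.hub_sd_mult)
    summary = net_mod.summarize(net, cent, part)
    report["network"] = summary.to_dict()
    report["hubs"] = hubs
    report["centrality"] = {
        v: {
            "betweenness": cent.b[v],
            "betweenness_normalized": cent.b_normalized[v],
            "degree": cent.degree[v],
        }
        for v in sorted(net.nodes, key=str)
    }
    report["modules"] = part.assignment

    if ann is not None:
        vitamins = cfg.vitamins or cat.vitamin_names
        calls = path_mod.call_all_pathways(ann, cat)
        report["capability_calls"] = [
            {
                "genome_id": c.genome_id,
                "vitamin": c.vitamin,
                "status": c.status,
                "missing_kos": sorted(c.missing_kos),
            }
            for c in calls
            if c.vitamin in vitamins
        ]
        report["roles"] = {}
        report["hub_scores"] = {}
        report["null"] = {}
        for vit in vitamins:
            labels = path_mod.classify_roles(calls, vit, cfg.near_complete_policy)
            net_labels = labels.restricted_to(net.nodes)
            report["roles"][vit] = {
                "n_producers": net_labels.n_producers,
                "n_auxotrophs": net_labels.n_auxotrophs,
                "roles": net_labels.roles,
            }
            ranked = hub_mod.rank_hub_scores(net, net_labels)
            report["hub_scores"][vit] = [s.to_dict() for s in ranked]
            focals = cfg.focal_nodes
            if focals is None:
                focals = [ranked[0].node] if ranked else []
            report["null"][vit] = {}
            for focal in focals:
                null = hub_mod.randomization_null(
                    net,
                    net_labels,
                    focal,
                    n_sim=cfg.n_sim,
                    seed=cfg.seed,
                    focal_policy=cfg.focal_policy,
                )
                report["null"][vit][focal] = null.to_dict()
        if ann.lengths:
            size = path_mod.vitamin_count_vs_size(ann, calls)
            report["vitamin_count_vs_size"] = {
                "bins": {
                    k: {kk: vv for kk, vv in v.items() if kk != "lengths"}
                    for k, v in size.bins.items()
                },
                "tests": {
                    f"{a}_vs_{b}": res for (a, b), res in size.tests.items()
                },
            }

    if meta is not None and tab is not None:
        report["ecology"] = {}
        entities: dict[str, list[str]] = {v: [v] for v in net.nodes}
        for mod, members in part.modules().items():
            entities[f"module_{mod}"] = members
        for axis in ("lifestyle", "scn_level"):
            if axis not in meta.table.columns:
                continue
            comps = eco_mod.compare_categories(
                tab, meta, axis, entities, cfg.presence_threshold
            )
            report["ecology"][axis] = [dataclasses.asdict(c) for c in comps]

    _write_outputs(cfg, report, corr, net)
    return report


def _write_outputs(cfg, report, corr: CorrelationMatrix, net: nx.Graph) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_correlation_matrix(
        corr,
        out / "correlations.tsv",
        out / "correlations.pvals.tsv" if corr.p is not None else None,
    )
    write_network(net, out / "network.graphml", "graphml")
    write_network(net, out / "network.edges.tsv", "edge_tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
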