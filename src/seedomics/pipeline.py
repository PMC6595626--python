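"""Configuration-driven orchestration of the full integration pipeline.

Stages run in dependency order: simulate/load -> stage-wise DE -> K-means
clustering + coexpression -> bin enrichment -> metabolite calls -> TCNA.
Every stage writes its TSV/JSON interface files under the output directory
and the run ends with a machine-readable report of paths, counts and the
parameters actually applied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, coexpression, de, enrichment, metabolomics, tcna
from .enrichment import AnnotationTable
from .synthetic import SimConfig, SimDataset, generate_dataset, load_dataset

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERICAL_ERROR = 4


class ConfigError(ValueError):
    """Invalid or out-of-range pipeline configuration."""


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults are the published thresholds."""

    input_dir: str | None = None  # dataset directory (write_dataset layout)
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    output_dir: str = "seedomics_out"
    seed: int = 0
    # differential expression
    fc_threshold: float = 2.0
    q_threshold: float = 0.8
    de_mode: str = "vs_first"
    # clustering
    k: int = 24
    n_super: int = 9
    kmeans_restarts: int = 10
    raw_scale: bool = False
    single_stage_tau: float = 1.0
    # coexpression
    beta: int | None = None  # None -> scale-free pick
    cut_height: float = 0.25
    min_module_size: int = 30
    module_r_threshold: float = 0.75
    module_p_threshold: float = 0.05
    export_weight_threshold: float = 0.1
    n_hubs: int = 10
    # enrichment
    enrichment_alpha: float = 0.05
    enrichment_adjust: str = "none"
    # metabolomics
    vip_min: float = 1.0
    metab_alpha: float = 0.05
    metab_mode: str = "vs_reference"
    # tcna
    tcna_r_min: float = 0.25
    tcna_alpha: float = 0.05

    def validate(self) -> "PipelineConfig":
        if self.input_dir is not None and self.simulate:
            raise ConfigError("give either input_dir or a simulate block, not both")
        checks = [
            ("fc_threshold", self.fc_threshold > 0),
            ("q_threshold", 0 < self.q_threshold <= 1),
            ("k", self.k >= 2),
            ("n_super", 1 <= self.n_super <= self.k),
            ("kmeans_restarts", self.kmeans_restarts >= 1),
            ("cut_height", 0 < self.cut_height <= 1),
            ("min_module_size", self.min_module_size >= 2),
            ("module_r_threshold", 0 <= self.module_r_threshold <= 1),
            ("module_p_threshold", 0 < self.module_p_threshold <= 1),
            ("export_weight_threshold", 0 <= self.export_weight_threshold <= 1),
            ("enrichment_alpha", 0 <= self.enrichment_alpha <= 1),
            ("vip_min", self.vip_min >= 0),
            ("metab_alpha", 0 < self.metab_alpha <= 1),
            ("tcna_r_min", 0 <= self.tcna_r_min <= 1),
            ("tcna_alpha", 0 < self.tcna_alpha <= 1),
            ("de_mode", self.de_mode in ("vs_first", "successive")),
            ("metab_mode", self.metab_mode in ("vs_reference", "successive")),
            ("enrichment_adjust", self.enrichment_adjust in ("none", "BH")),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"{name} out of range: {getattr(self, name)!r}")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and normalize a YAML config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        config = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return config.validate()


def _load_or_simulate(config: PipelineConfig) -> SimDataset:
    if config.input_dir is not None:
        return load_dataset(config.input_dir)
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    return generate_dataset(SimConfig(**sim_kwargs))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
        "counts": {},
    }

    dataset = _load_or_simulate(config)
    expr = dataset.expression

    # --- differential expression ---
    de_results = de.stagewise_degs(
        expr, mode=config.de_mode,
        fc_threshold=config.fc_threshold, q_threshold=config.q_threshold,
    )
    for name, (table, degset) in de_results.items():
        path = out / f"deg_{name}.tsv"
        t = table.table.copy()
        t["called"] = (t["fold_change"] >= config.fc_threshold) & (
            t["q"] >= config.q_threshold
        )
        t.to_csv(path, sep="\t")
        report["outputs"][path.name] = str(path)
        report["counts"][f"degs_{name}"] = {
            "up": len(degset.up), "down": len(degset.down)
        }
    union = de.deg_union(de_results)
    report["counts"]["deg_union"] = len(union)
    if len(union) < max(config.k, config.min_module_size):
        raise RuntimeError(
            f"only {len(union)} DEGs called; too few for clustering"
        )

    # --- K-means stage clustering ---
    profiles = clustering.preprocess_profiles(expr, union, raw_scale=config.raw_scale)
    clusters = clustering.kmeans_cluster(
        profiles, k=config.k, seed=config.seed, n_restarts=config.kmeans_restarts
    )
    clustering.merge_superclusters(clusters, n_super=config.n_super)
    single = clustering.single_stage_genes(expr, tau_fpkm=config.single_stage_tau)
    cluster_table = pd.DataFrame(
        {
            "cluster": clusters.cluster_of_gene,
            "stage": clusters.cluster_of_gene.map(clusters.stage_of_cluster),
            "supercluster": clusters.cluster_of_gene.map(
                clusters.supercluster_of_cluster
            ),
        }
    )
    cluster_table.to_csv(out / "clusters.tsv", sep="\t")
    clusters.centroids.to_csv(out / "centroids.tsv", sep="\t")
    report["outputs"]["clusters.tsv"] = str(out / "clusters.tsv")
    report["counts"]["clustered_genes"] = len(cluster_table)
    report["counts"]["single_stage_genes"] = len(single)

    # --- coexpression network ---
    log_expr = np.log2(expr.data.loc[union] + 1.0)
    if config.beta is None:
        beta, _ = coexpression.pick_soft_threshold(log_expr)
    else:
        beta = config.beta
    adj = coexpression.adjacency(log_expr, beta)
    tom = coexpression.tom_similarity(adj)
    modules = coexpression.detect_modules(
        tom, cut_height=config.cut_height, min_size=config.min_module_size
    )
    modules = coexpression.summarize_modules(log_expr.loc[adj.index], modules)
    report["counts"]["modules"] = len(modules.modules)
    report["parameters"]["beta_used"] = int(beta)

    stage_stats = pd.DataFrame()
    if len(modules.modules):
        stage_stats = coexpression.module_stage_correlation(
            modules.eigengenes, expr.design
        )
        stage_stats.to_csv(out / "module_stage_stats.tsv", sep="\t", index=False)
        modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        report["outputs"]["module_stage_stats.tsv"] = str(out / "module_stage_stats.tsv")
        hit = stage_stats[
            (stage_stats["r"] >= config.module_r_threshold)
            & (stage_stats["p"] <= config.module_p_threshold)
        ]
        report["counts"]["module_stage_associations"] = len(hit)

    module_rows = []
    for mod in modules.modules:
        members = modules.genes_in(mod)
        kw = coexpression.intramodular_connectivity(adj, members)
        hubs = coexpression.top_hubs(kw, n=config.n_hubs)
        modules.hubs[mod] = hubs
        for gene in members:
            module_rows.append(
                {
                    "gene_id": gene,
                    "module": mod,
                    "k_within": float(kw[gene]),
                    "hub_rank": hubs.index(gene) + 1 if gene in hubs else 0,
                }
            )
    pd.DataFrame(
        module_rows, columns=["gene_id", "module", "k_within", "hub_rank"]
    ).to_csv(out / "modules.tsv", sep="\t", index=False)
    report["outputs"]["modules.tsv"] = str(out / "modules.tsv")
    node_attrs = pd.DataFrame(
        {
            "module": modules.module_of_gene,
            "hub": modules.module_of_gene.index.isin(
                [g for hs in modules.hubs.values() for g in hs]
            ),
            "transcription_factor": modules.module_of_gene.index.isin(single),
        }
    )
    net_paths = coexpression.export_network(
        tom, out, weight_threshold=config.export_weight_threshold,
        node_attributes=node_attrs,
    )
    report["outputs"].update({k: str(v) for k, v in net_paths.items()})

    # --- bin enrichment of clusters and superclusters ---
    annotation = AnnotationTable(dataset.annotation)
    enrich_frames = []
    universe = set(annotation.universe)
    for sc in sorted(set(clusters.supercluster_of_cluster.values())):
        members = [
            g
            for g, c in clusters.cluster_of_gene.items()
            if clusters.supercluster_of_cluster[c] == sc and g in universe
        ]
        if not members:
            continue
        enrich_frames.append(
            enrichment.enrich_all(
                set(members), annotation,
                alpha=config.enrichment_alpha, adjust=config.enrichment_adjust,
                set_label=f"SC{sc}",
            )
        )
    enrich_table = (
        pd.concat(enrich_frames, ignore_index=True)
        if enrich_frames
        else pd.DataFrame()
    )
    enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report["outputs"]["enrichment.tsv"] = str(out / "enrichment.tsv")
    if len(enrich_table):
        report["counts"]["significant_enrichments"] = int(
            enrich_table["significant"].sum()
        )

    # --- metabolite significance ---
    metab_calls = metabolomics.call_changed_metabolites(
        dataset.metabolites,
        vip_min=config.vip_min, alpha=config.metab_alpha, mode=config.metab_mode,
    )
    metab_calls.to_csv(out / "metabolite_calls.tsv", sep="\t", index=False)
    report["outputs"]["metabolite_calls.tsv"] = str(out / "metabolite_calls.tsv")
    report["counts"]["significant_metabolite_calls"] = int(
        metab_calls["significant"].sum()
    )
    report["counts"]["changed_metabolites"] = int(
        metab_calls.loc[metab_calls["significant"], "metabolite"].nunique()
    )

    # --- TCNA ---
    expr_profiles = tcna.stage_mean_profiles(expr.data, expr.design)
    metab_profiles = tcna.stage_mean_profiles(
        dataset.metabolites.data, dataset.metabolites.design
    )
    graph = tcna.build_tcna(
        expr_profiles,
        metab_profiles,
        dataset.metabolites.enzyme_map,
        dataset.metabolites.pathway_edges,
        r_min=config.tcna_r_min,
        alpha=config.tcna_alpha,
    )
    tcna_paths = tcna.export_graph(graph, out)
    report["outputs"].update({f"tcna_{k}": str(v) for k, v in tcna_paths.items()})
    candidates = []
    for metab in sorted(dataset.metabolites.enzyme_map["metabolite_id"].unique()):
        if metab in graph and any(
            graph.edges[metab, nbr]["kind"] == "gene-metabolite"
            for nbr in graph.neighbors(metab)
        ):
            candidates.append(tcna.rank_candidates(graph, metab))
    cand_table = (
        pd.concat(candidates, ignore_index=True) if candidates else pd.DataFrame()
    )
    cand_table.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    report["outputs"]["candidate_genes.tsv"] = str(out / "candidate_genes.tsv")
    report["counts"]["tcna_edges"] = graph.number_of_edges()
    report["counts"]["tcna_significant_edges"] = sum(
        1 for _, _, d in graph.edges(data=True) if d["significant"]
    )

    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
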