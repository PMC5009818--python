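"""End-to-end orchestration of the three-level clustering pipeline.

Order of stages: genome dereplication within clades -> abundant-clade
selection -> per-clade in-clade clustering (near-identical collapse,
sequence clusters, genomic-context refinement, clustroids, conservative
flags) -> seed clustering of conservative clustroids at the global
thresholds, run per connected component of the relatedness graph via the
disjoint-set partitioner -> the global cascade (direct assignment, tight
grouping, liberal filtering, seed extension, propagation).

The result bundle carries every intermediate product plus a machine-
readable report with per-stage counts, compression ratios and a membership
conservation check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Dataset, Thresholds, edge_key
from .derep import DerepResult, dereplicate, genome_similarity_proxy
from .globalcluster import (
    GlobalResult,
    SeedCluster,
    base_hierarchical,
    run_global_pipeline,
)
from .inclade import InCladeResult, abundant_clades, cluster_clade
from .io import PipelineConfig
from .partition import LoadReport, cluster_by_partition, partition
from .similarity import ScoringConfig, all_vs_all


@dataclass
class PipelineResult:
    derep: DerepResult
    abundant: list[str]
    inclade: dict[str, InCladeResult]
    conservative_clustroids: list[str]
    seed_partition: dict[str, str]
    seed_load: LoadReport | None
    seeds: list[SeedCluster]
    global_result: GlobalResult
    report: dict = field(default_factory=dict)


def seed_clustering_partitioned(
    clustroids: dict[str, str],
    edges,
    t: Thresholds,
    linkage: str = "average",
    n_workers: int = 1,
) -> tuple[list[SeedCluster], dict[str, str], LoadReport]:
    """Seed clustering run independently per relatedness-graph component.

    Cross-component pairs have no related edge, so per-partition clustering
    equals whole-set clustering; the partitioner makes that structure
    explicit and bounds the work of each task.
    """
    part_map = partition(list(edges), clustroids)
    members_of: dict[str, list[str]] = {}
    for pid, comp in part_map.items():
        members_of.setdefault(comp, []).append(pid)
    edges_of: dict[str, dict] = {comp: {} for comp in members_of}
    for (a, b), hit in edges.items():
        edges_of[part_map[a]][edge_key(a, b)] = hit

    def cluster_fn(ids):
        comp = part_map[ids[0]]
        return base_hierarchical(ids, edges_of[comp], t, linkage=linkage)

    parts, load = cluster_by_partition(part_map, cluster_fn, n_workers=n_workers)
    seeds = [
        SeedCluster(cluster_id=f"seed:{min(p)}", clustroid_members=set(p))
        for p in parts
    ]
    return seeds, part_map, load


def run_all(
    dataset: Dataset,
    config: PipelineConfig = PipelineConfig(),
    genome_similarities=None,
) -> PipelineResult:
    """Run every stage on a validated dataset and assemble the report."""
    scoring = ScoringConfig(min_score=config.min_score)

    if genome_similarities is None:
        genome_similarities = genome_similarity_proxy(
            dataset, scoring, word_length=config.word_length
        )
    derep = dereplicate(dataset, genome_similarities, cutoff=config.derep_cutoff)
    rep_counts = {clade: derep.n_nonclonal(clade) for clade in derep.representatives}
    abundant = abundant_clades(rep_counts, min_nonclonal=config.min_nonclonal)

    inclade_results: dict[str, InCladeResult] = {}
    for clade in abundant:
        inclade_results[clade] = cluster_clade(
            dataset,
            clade,
            derep.representatives[clade],
            scoring=scoring,
            t=config.thresholds("inclade"),
            collapse=config.thresholds("collapse"),
            conservative_fraction=config.conservative_fraction,
            linkage=config.linkage,
            word_length=config.word_length,
            min_matches=config.min_context_matches,
        )

    clustroids = sorted(
        pid
        for res in inclade_results.values()
        for pid in res.conservative_clustroids
    )
    clustroid_seqs = {pid: dataset.proteins[pid].sequence for pid in clustroids}
    if clustroid_seqs:
        seed_edges = all_vs_all(clustroid_seqs, config.thresholds("seed"), scoring)
        seeds, part_map, load = seed_clustering_partitioned(
            clustroid_seqs,
            seed_edges,
            config.thresholds("seed"),
            linkage=config.linkage,
            n_workers=config.n_workers,
        )
    else:
        seeds, part_map, load = [], {}, None

    global_proteins = {
        pid: p.sequence
        for pid, p in dataset.proteins.items()
        if dataset.protein_is_complete(pid)
    }
    global_result = run_global_pipeline(
        global_proteins,
        seeds,
        scoring=scoring,
        tight=config.thresholds("tight"),
        liberal=config.thresholds("liberal"),
        extension=config.thresholds("extension"),
        word_length=config.word_length,
        max_accepts=config.max_accepts,
        max_rejects=config.max_rejects,
        exhaustive_filter_check=config.exhaustive_filter_check,
    )

    # region-level compression of the extended seed clusters
    member_cluster: dict[str, str] = {}
    for sc in global_result.seeds:
        for pid in sc.members:
            member_cluster[pid] = sc.cluster_id
    regions_in_seeds = sum(
        len(dataset.proteins[pid].regions) for pid in member_cluster
    )
    report = {
        "n_genomes": len(dataset.genomes),
        "n_clades": len(dataset.clades()),
        "n_abundant_clades": len(abundant),
        "n_nonclonal_by_clade": rep_counts,
        "inclade": {c: r.report for c, r in inclade_results.items()},
        "n_conservative_clustroids": len(clustroids),
        "n_seed_clusters": len(seeds),
        "seed_partitions": load.n_partitions if load else 0,
        "seed_load_imbalance": load.imbalance if load else 0.0,
        "global": global_result.report,
        "regions_in_extended_seed_clusters": regions_in_seeds,
        "seed_region_compression": (
            regions_in_seeds / len(seeds) if seeds else float("nan")
        ),
    }
    return PipelineResult(
        derep=derep,
        abundant=abundant,
        inclade=inclade_results,
        conservative_clustroids=clustroids,
        seed_partition=part_map,
        seed_load=load,
        seeds=global_result.seeds,
        global_result=global_result,
        report=report,
    )
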