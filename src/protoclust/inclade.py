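"""In-clade clustering: sequence similarity combined with local genome context.

Tight clusters (80 % identity / 85 % coverage) are built inside each
abundant clade from the complete proteins of its representative
(non-clonal) genomes.  Sequence-similarity clusters are computed first;
then the genomic neighborhood of every coding region is examined with a
moving window of five gene slots centered on the focal gene (offsets -2..+2
in gene order, orientation-normalized for minus-strand genes).  Two regions
are context-consistent when at least 3 of the 5 window positions carry the
same, present sequence-cluster id; the connected components of this
relation split a sequence cluster into sub-clusters, separating paralogs
that are sequence-similar but live in different genomic neighborhoods.

Each final cluster gets a *clustroid*: the member minimizing the weighted
average distance to the other members, where a member's weight is the
number of coding regions in non-clonal genomes encoding it.  Clusters
present in (by default) at least 90 % of the clade's representative genomes
are flagged *conservative*; their clustroids seed the global stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .core import (
    COLLAPSE_THRESHOLDS,
    INCLADE_THRESHOLDS,
    Cluster,
    Dataset,
    EdgeMap,
    Thresholds,
    edge_key,
    is_related,
)
from .globalcluster import DISTANCE_CAP, base_hierarchical
from .kmer import GreedyParams, greedy_cluster
from .partition import DisjointSet
from .similarity import ScoringConfig, all_vs_all, pair_hit

WINDOW = 5
MIN_CONTEXT_MATCHES = 3

ContextWindow = tuple  # length-5 tuple of cluster ids or None (absent slot)


def sequence_clusters(
    proteins: Mapping[str, str],
    edges: EdgeMap,
    t: Thresholds = INCLADE_THRESHOLDS,
    linkage: str = "average",
) -> list[set[str]]:
    """Sequence-similarity clusters at the in-clade thresholds."""
    return base_hierarchical(sorted(proteins), edges, t, linkage=linkage)


def build_context_vectors(
    dataset: Dataset,
    cluster_of: Mapping[str, str],
    genome_ids: Iterable[str] | None = None,
    window: int = WINDOW,
) -> dict[str, ContextWindow]:
    """Window of sequence-cluster ids around every coding region.

    Offsets -2..+2 in gene order along the contig; slots beyond the contig
    end, or occupied by a gene whose protein has no cluster id, are absent
    (None).  Windows of minus-strand focal genes are reversed, so conserved
    neighborhoods match regardless of contig orientation.  The center slot
    is the focal region's own cluster id.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    keep = set(genome_ids) if genome_ids is not None else None
    vectors: dict[str, ContextWindow] = {}
    for (gid, _cid), order in sorted(dataset.contig_gene_orders().items()):
        if keep is not None and gid not in keep:
            continue
        n = len(order)
        for i, region in enumerate(order):
            focal_cluster = cluster_of.get(region.protein_id)
            if focal_cluster is None:
                continue
            slots: list[str | None] = []
            for off in range(-half, half + 1):
                j = i + off
                if 0 <= j < n:
                    slots.append(cluster_of.get(order[j].protein_id))
                else:
                    slots.append(None)
            if region.strand == "-":
                slots.reverse()
            vectors[region.region_id] = tuple(slots)
    return vectors


def context_consistent(
    a: ContextWindow, b: ContextWindow, min_matches: int = MIN_CONTEXT_MATCHES
) -> bool:
    """True when >= min_matches window positions carry equal, present ids.

    The rule is evaluated over all window slots (absent slots never match),
    so a contig-end gene with only three present, matching slots passes.
    """
    matches = sum(1 for x, y in zip(a, b) if x is not None and x == y)
    return matches >= min_matches


def context_refine(
    members: Iterable[str],
    protein_regions: Mapping[str, Sequence[str]],
    vectors: Mapping[str, ContextWindow],
    min_matches: int = MIN_CONTEXT_MATCHES,
) -> list[set[str]]:
    """Split one sequence cluster into context-consistent sub-clusters.

    Builds the consistency graph over the members' coding regions, takes
    connected components, and assigns each protein to the component holding
    the plurality of its regions (ties: the component containing the
    smallest minimal region id).  The result is a partition of the members.
    """
    members = sorted(set(members))
    region_ids: list[str] = []
    region_owner: dict[str, str] = {}
    for pid in members:
        regs = protein_regions.get(pid)
        if not regs:
            raise ValueError(f"protein {pid} has no regions in scope")
        for rid in regs:
            if rid not in vectors:
                raise ValueError(f"missing context vector for region {rid}")
            region_ids.append(rid)
            region_owner[rid] = pid
    region_ids.sort()
    dsu = DisjointSet(region_ids)
    for i, ra in enumerate(region_ids):
        va = vectors[ra]
        for rb in region_ids[i + 1 :]:
            if context_consistent(va, vectors[rb], min_matches):
                dsu.union(ra, rb)
    comp_min: dict[str, str] = {}
    for rid in region_ids:
        root = dsu.find(rid)
        if root not in comp_min or rid < comp_min[root]:
            comp_min[root] = rid
    assignments: dict[str, str] = {}
    for pid in members:
        counts: dict[str, int] = {}
        for rid in protein_regions[pid]:
            root = dsu.find(rid)
            counts[root] = counts.get(root, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], comp_min[c]))
        assignments[pid] = best
    groups: dict[str, set[str]] = {}
    for pid, comp in assignments.items():
        groups.setdefault(comp, set()).add(pid)
    out = list(groups.values())
    out.sort(key=lambda g: min(g))
    return out


def select_clustroid(
    members: Iterable[str],
    weights: Mapping[str, int],
    dist: Callable[[str, str], float],
    cap: float = DISTANCE_CAP,
) -> str:
    """Member with minimal weighted average distance to the other members.

    Unrelated intra-cluster pairs are capped at ``cap`` (1.0), so clusters
    formed by transitivity remain scoreable.  Ties go to the member with
    the larger own weight, then the smallest id.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    best_key = None
    best_pid = None
    for p in members:
        num = 0.0
        den = 0.0
        for q in members:
            if q == p:
                continue
            w = weights.get(q, 1)
            num += w * min(dist(p, q), cap)
            den += w
        score = num / den if den else cap
        key = (score, -weights.get(p, 1), p)
        if best_key is None or key < best_key:
            best_key, best_pid = key, p
    assert best_pid is not None
    return best_pid


def flag_conservative(
    members: Iterable[str],
    protein_genomes: Mapping[str, set[str]],
    rep_genomes: Sequence[str],
    conservative_fraction: float = 0.9,
) -> bool:
    """True iff the cluster spans >= the fraction of representative genomes."""
    if not rep_genomes:
        raise ValueError("clade has no representative genomes")
    covered: set[str] = set()
    reps = set(rep_genomes)
    for pid in members:
        covered |= protein_genomes.get(pid, set()) & reps
    return len(covered) >= conservative_fraction * len(reps) - 1e-9


def abundant_clades(
    clade_rep_counts: Mapping[str, int], min_nonclonal: int = 10
) -> list[str]:
    """Clades with at least min_nonclonal representative genomes (default 10)."""
    return sorted(c for c, n in clade_rep_counts.items() if n >= min_nonclonal)


@dataclass
class InCladeResult:
    clade_id: str
    clusters: list[Cluster]
    assignment: dict[str, str]  # protein -> cluster id
    weights: dict[str, int]
    collapse_assignment: dict[str, str]  # protein -> near-identical representative
    context: dict[str, ContextWindow] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def conservative_clustroids(self) -> list[str]:
        return sorted(
            c.clustroid_id
            for c in self.clusters
            if c.is_conservative and c.clustroid_id is not None
        )


def cluster_clade(
    dataset: Dataset,
    clade_id: str,
    rep_genomes: Sequence[str],
    scoring: ScoringConfig = ScoringConfig(),
    t: Thresholds = INCLADE_THRESHOLDS,
    collapse: Thresholds = COLLAPSE_THRESHOLDS,
    conservative_fraction: float = 0.9,
    linkage: str = "average",
    word_length: int = 5,
    min_matches: int = MIN_CONTEXT_MATCHES,
) -> InCladeResult:
    """Full in-clade stage for one clade.

    Near-identical collapse (98 %/100 %) -> sequence clusters over the
    collapse representatives -> expansion back to all proteins -> context
    refinement -> clustroid selection and conservative flagging.
    """
    rep_set = set(rep_genomes)
    regions_in_scope: dict[str, list[str]] = {}
    for r in dataset.regions.values():
        if r.genome_id in rep_set and r.is_complete:
            regions_in_scope.setdefault(r.protein_id, []).append(r.region_id)
    proteins = {
        pid: dataset.proteins[pid].sequence
        for pid in regions_in_scope
        if dataset.protein_is_complete(pid)
    }
    for regs in regions_in_scope.values():
        regs.sort()
    if not proteins:
        raise ValueError(f"clade {clade_id}: no complete proteins in scope")

    # 1. near-identical collapse
    collapse_params = GreedyParams(word_length=word_length, thresholds=collapse)
    greedy = greedy_cluster(proteins, collapse_params, scoring)
    rep_seqs = {pid: proteins[pid] for pid in greedy.representatives}

    # 2. sequence clusters over collapse representatives, then expansion
    edges = all_vs_all(rep_seqs, t, scoring)
    seq_parts = sequence_clusters(rep_seqs, edges, t, linkage=linkage)
    seq_cluster_of: dict[str, str] = {}
    for part in seq_parts:
        label = f"sc:{min(part)}"
        for pid in part:
            seq_cluster_of[pid] = label
    for pid, rep in greedy.assignment.items():
        seq_cluster_of[pid] = seq_cluster_of[rep]

    # 3. genomic-context refinement
    vectors = build_context_vectors(dataset, seq_cluster_of, rep_set)
    weights = {pid: len(regs) for pid, regs in regions_in_scope.items()}
    protein_genomes = {
        pid: {dataset.regions[rid].genome_id for rid in regs}
        for pid, regs in regions_in_scope.items()
    }

    members_by_seq_cluster: dict[str, set[str]] = {}
    for pid, label in seq_cluster_of.items():
        if pid in proteins:
            members_by_seq_cluster.setdefault(label, set()).add(pid)

    clusters: list[Cluster] = []
    assignment: dict[str, str] = {}
    hit_cache: dict[tuple[str, str], float] = {}

    def member_distance(a: str, b: str) -> float:
        key = edge_key(a, b)
        d = hit_cache.get(key)
        if d is None:
            hit = pair_hit(key[0], proteins[key[0]], key[1], proteins[key[1]], scoring)
            if hit is not None and is_related(hit, t):
                d = 1.0 - hit.identity_pct / 100.0
            else:
                d = DISTANCE_CAP
            hit_cache[key] = d
        return d

    for label in sorted(members_by_seq_cluster):
        seq_members = members_by_seq_cluster[label]
        for sub in context_refine(seq_members, regions_in_scope, vectors, min_matches):
            cid = f"{clade_id}|ic:{min(sub)}"
            clustroid = select_clustroid(sub, weights, member_distance)
            conservative = flag_conservative(
                sub, protein_genomes, rep_genomes, conservative_fraction
            )
            roles = {
                pid: ("clustroid" if pid == clustroid else "plain") for pid in sub
            }
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    level="inclade",
                    members=set(sub),
                    clustroid_id=clustroid,
                    is_conservative=conservative,
                    clade_id=clade_id,
                    member_roles=roles,
                )
            )
            for pid in sub:
                assignment[pid] = cid
    clusters.sort(key=lambda c: c.cluster_id)

    n_regions = sum(len(r) for r in regions_in_scope.values())
    report = {
        "clade_id": clade_id,
        "n_rep_genomes": len(rep_set),
        "n_coding_regions": n_regions,
        "n_proteins": len(proteins),
        "n_collapse_representatives": len(rep_seqs),
        "n_sequence_clusters": len(seq_parts),
        "n_clusters": len(clusters),
        "n_conservative": sum(c.is_conservative for c in clusters),
        "compression_ratio": n_regions / len(clusters) if clusters else float("nan"),
    }
    return InCladeResult(
        clade_id=clade_id,
        clusters=clusters,
        assignment=assignment,
        weights=weights,
        collapse_assignment=dict(greedy.assignment),
        context=vectors,
        report=report,
    )
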