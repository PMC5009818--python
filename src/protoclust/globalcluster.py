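"""Hierarchical clustering engine and the two global clustering algorithms.

The base engine is graph-restricted agglomerative clustering: starting from
singletons, the closest pair of clusters is merged repeatedly, provided the
pair is connected by at least one related edge and its linkage distance is
within the cutoff implied by the identity threshold (``1 - min_identity/100``).
Pairs with no hit contribute a capped distance of 1.0 to the linkage, so
clusters formed by transitivity remain comparable.  Linkage is size-weighted
average by default (complete and single are selectable).  Ties are broken by
the smallest member id, making the procedure deterministic.

Two global algorithms build on it:

* **seed clustering** — the clustroids of conservative in-clade clusters are
  agglomerated at the global thresholds (50 % identity / 70 % coverage) into
  *seed* clusters;
* **seed extension** — non-seed proteins are attached to the nearest seed
  cluster (by identity to its clustroids) without ever being compared to
  each other.

The *modified* hierarchical variant implements the seed-protecting rule:
when a seed-containing cluster absorbs a seed-free cluster, the distances of
the merged cluster to everything else are those of the seed-containing part
alone, so chains of drifting homologs cannot drag a seed's distance profile.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    GLOBAL_THRESHOLDS,
    EdgeMap,
    HitRecord,
    Thresholds,
    edge_key,
    is_related,
)

Linkage = str  # "average" | "complete" | "single"
DISTANCE_CAP = 1.0


@dataclass
class SeedCluster:
    """A global cluster seeded by in-clade clustroids, later extended."""

    cluster_id: str
    clustroid_members: set[str]
    extension_members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.clustroid_members:
            raise ValueError(f"seed cluster {self.cluster_id} has no clustroids")
        if self.clustroid_members & self.extension_members:
            raise ValueError(
                f"seed cluster {self.cluster_id}: extension members overlap "
                "clustroid members"
            )

    @property
    def members(self) -> set[str]:
        return self.clustroid_members | self.extension_members


class _State:
    """Active clusters plus incrementally maintained pair statistics."""

    __slots__ = (
        "members",
        "eff_size",
        "has_seed",
        "min_id",
        "stat",
        "edges",
        "alive",
        "linkage",
    )

    def __init__(self, linkage: Linkage) -> None:
        self.linkage = linkage
        self.members: dict[int, list[str]] = {}
        self.eff_size: dict[int, int] = {}
        self.has_seed: dict[int, bool] = {}
        self.min_id: dict[int, str] = {}
        # stat[(i,j)] with i<j: sum of capped distances (average) or max/min
        self.stat: dict[tuple[int, int], float] = {}
        self.edges: dict[tuple[int, int], int] = {}
        self.alive: set[int] = set()

    def pair(self, i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def linkage_distance(self, i: int, j: int) -> float:
        p = self.pair(i, j)
        s = self.stat.get(p)
        if s is None:
            return math.inf
        if self.linkage == "average":
            return s / (self.eff_size[i] * self.eff_size[j])
        return s

    def n_edges(self, i: int, j: int) -> int:
        return self.edges.get(self.pair(i, j), 0)


def _capped_distance(hit: HitRecord | None, t: Thresholds) -> tuple[float, bool]:
    """(capped distance, related?) for one pair."""
    if hit is not None and is_related(hit, t):
        return min(1.0 - hit.identity_pct / 100.0, DISTANCE_CAP), True
    return DISTANCE_CAP, False


def _agglomerate(
    ids: Sequence[str],
    edges: EdgeMap,
    t: Thresholds,
    linkage: Linkage = "average",
    seed_ids: set[str] | None = None,
) -> list[set[str]]:
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    ids = sorted(set(ids))
    cutoff = 1.0 - t.min_identity_pct / 100.0
    seed_ids = seed_ids or set()

    st = _State(linkage)
    index_of = {pid: k for k, pid in enumerate(ids)}
    for k, pid in enumerate(ids):
        st.members[k] = [pid]
        st.eff_size[k] = 1
        st.has_seed[k] = pid in seed_ids
        st.min_id[k] = pid
        st.alive.add(k)

    heap: list[tuple[float, str, str, int, int]] = []

    def push(i: int, j: int) -> None:
        if st.n_edges(i, j) < 1:
            return
        d = st.linkage_distance(i, j)
        if d <= cutoff + 1e-12:
            a, b = sorted((st.min_id[i], st.min_id[j]))
            heapq.heappush(heap, (d, a, b, *st.pair(i, j)))

    # initial pair stats: only pairs with at least one related edge can ever
    # merge while both are singletons, but merged clusters need capped stats
    # for *all* cross pairs — for average/complete those default to the cap,
    # reconstructed lazily below via the `stat` default handling.
    for (a, b), hit in edges.items():
        if a not in index_of or b not in index_of:
            raise ValueError(f"edge endpoint outside input: {(a, b)}")
        if a == b:
            continue
        d, related = _capped_distance(hit, t)
        if not related:
            continue
        p = st.pair(index_of[a], index_of[b])
        st.stat[p] = d
        st.edges[p] = 1
        push(*p)

    def stat_or_cap(i: int, j: int) -> float:
        # absent stat between singleton-derived groups means "all pairs capped"
        s = st.stat.get(st.pair(i, j))
        if s is not None:
            return s
        if linkage == "average":
            return DISTANCE_CAP * st.eff_size[i] * st.eff_size[j]
        return DISTANCE_CAP

    next_idx = len(ids)
    while heap:
        d, _, _, i, j = heapq.heappop(heap)
        if i not in st.alive or j not in st.alive:
            continue
        # stale entries for surviving pairs cannot occur: stats of a pair
        # never change while both clusters are alive
        new = next_idx
        next_idx += 1
        seed_i, seed_j = st.has_seed[i], st.has_seed[j]
        st.members[new] = sorted(st.members[i] + st.members[j])
        st.min_id[new] = st.members[new][0]
        st.has_seed[new] = seed_i or seed_j

        # the seed-protecting modification: a seed+nonseed merge keeps the
        # seed part's distance profile (and effective size / connectivity)
        if seed_i != seed_j and (seed_i or seed_j):
            keeper, dropped = (i, j) if seed_i else (j, i)
        else:
            keeper = dropped = -1

        st.eff_size[new] = (
            st.eff_size[keeper] if keeper >= 0 else st.eff_size[i] + st.eff_size[j]
        )
        others = [k for k in st.alive if k not in (i, j)]
        for k in others:
            if keeper >= 0:
                s_new = stat_or_cap(keeper, k)
                e_new = st.n_edges(keeper, k)
            else:
                si = stat_or_cap(i, k)
                sj = stat_or_cap(j, k)
                if linkage == "average":
                    s_new = si + sj
                elif linkage == "complete":
                    s_new = max(si, sj)
                else:
                    s_new = min(si, sj)
                e_new = st.n_edges(i, k) + st.n_edges(j, k)
            p = st.pair(new, k)
            st.stat[p] = s_new
            if e_new:
                st.edges[p] = e_new

        for k in (i, j):
            st.alive.discard(k)
            for p in [q for q in st.stat if k in q]:
                del st.stat[p]
            for p in [q for q in st.edges if k in q]:
                del st.edges[p]
        st.alive.add(new)
        for k in others:
            push(new, k)

    out = [set(st.members[k]) for k in st.alive]
    out.sort(key=lambda c: min(c))
    return out


def base_hierarchical(
    ids: Iterable[str],
    edges: EdgeMap,
    t: Thresholds,
    linkage: Linkage = "average",
) -> list[set[str]]:
    """Graph-restricted agglomerative clustering; returns a partition of ids.

    Merges the closest pair of clusters whose linkage distance is at most
    ``1 - t.min_identity_pct/100`` and which share at least one related
    edge; unrelated pairs contribute the capped distance 1.0 to average and
    complete linkage.  Deterministic: ties broken by smallest member id.
    """
    return _agglomerate(list(ids), edges, t, linkage=linkage)


def modified_hierarchical(
    ids: Iterable[str],
    edges: EdgeMap,
    t: Thresholds,
    seed_ids: set[str],
    linkage: Linkage = "average",
) -> list[set[str]]:
    """base_hierarchical with the seed-protecting distance rule.

    When a cluster containing seed proteins absorbs one that does not, the
    absorbed part is not used when the merged cluster's distances to the
    rest are determined.  With an empty seed set this equals
    :func:`base_hierarchical` exactly.
    """
    return _agglomerate(list(ids), edges, t, seed_ids=set(seed_ids), linkage=linkage)


def seed_clustering(
    clustroid_ids: Iterable[str],
    edges: EdgeMap,
    t: Thresholds = GLOBAL_THRESHOLDS,
    linkage: Linkage = "average",
) -> list[SeedCluster]:
    """Agglomerate conservative in-clade clustroids into seed clusters."""
    parts = base_hierarchical(clustroid_ids, edges, t, linkage=linkage)
    return [
        SeedCluster(cluster_id=f"seed:{min(p)}", clustroid_members=set(p))
        for p in parts
    ]


@dataclass(frozen=True)
class NeighborLink:
    """Best sub-threshold hit of a leftover protein to any seed clustroid."""

    protein_id: str
    clustroid_id: str
    cluster_id: str
    identity_pct: float
    coverage_pct: float


def extend_seeds(
    candidates: Iterable[str],
    seeds: Sequence[SeedCluster],
    hits: Mapping[str, Sequence[HitRecord]],
    t: Thresholds = GLOBAL_THRESHOLDS,
    compat: str = "any",
) -> tuple[list[SeedCluster], dict[str, NeighborLink | None]]:
    """Attach each candidate to the nearest compatible seed cluster.

    ``hits[candidate]`` holds the candidate's aggregated hits against seed
    clustroids (subject = clustroid).  A candidate joins the cluster of the
    related clustroid with the highest identity (ties: higher coverage, then
    smallest cluster id); with ``compat="all"`` it must additionally be
    related to every clustroid of that cluster.  Candidates related to no
    clustroid become leftovers, carrying their best sub-threshold hit as a
    neighbor link.  Seed clusters are never merged and clustroid membership
    never changes; the assignment is independent of candidate order.
    """
    if compat not in ("any", "all"):
        raise ValueError("compat must be 'any' or 'all'")
    clustroid_cluster: dict[str, SeedCluster] = {}
    for sc in seeds:
        for cid in sc.clustroid_members:
            clustroid_cluster[cid] = sc
    extended = [
        SeedCluster(sc.cluster_id, set(sc.clustroid_members), set()) for sc in seeds
    ]
    by_id = {sc.cluster_id: sc for sc in extended}
    leftovers: dict[str, NeighborLink | None] = {}

    for cand in sorted(set(candidates)):
        best: tuple[float, float, str] | None = None  # (-id, -cov, cluster_id)
        best_neighbor: tuple[float, float, str, str] | None = None
        related_per_cluster: dict[str, set[str]] = {}
        cand_hits = hits.get(cand, ())
        for h in cand_hits:
            sc = clustroid_cluster.get(h.subject_id)
            if sc is None:
                raise ValueError(f"hit subject {h.subject_id} is not a clustroid")
            cov = min(h.coverage_query_pct, h.coverage_subject_pct)
            if is_related(h, t):
                related_per_cluster.setdefault(sc.cluster_id, set()).add(h.subject_id)
                key = (-h.identity_pct, -cov, sc.cluster_id)
                if best is None or key < best:
                    best = key
            else:
                nkey = (-h.identity_pct, -cov, sc.cluster_id, h.subject_id)
                if best_neighbor is None or nkey < best_neighbor:
                    best_neighbor = nkey
        if best is not None and compat == "all":
            target = by_id[best[2]]
            if related_per_cluster.get(best[2], set()) != target.clustroid_members:
                best = None
        if best is not None:
            by_id[best[2]].extension_members.add(cand)
        elif best_neighbor is not None:
            neg_id, neg_cov, cl_id, sub_id = best_neighbor
            leftovers[cand] = NeighborLink(cand, sub_id, cl_id, -neg_id, -neg_cov)
        else:
            leftovers[cand] = None
    return extended, leftovers


@dataclass
class GlobalResult:
    """Bundle returned by :func:`run_global_pipeline`."""

    seeds: list[SeedCluster]
    direct_assigned: dict[str, str]  # protein -> seed cluster_id (tight match)
    group_assignment: dict[str, str]  # protein -> tight-group representative
    extension_assigned: dict[str, str]  # protein -> seed cluster_id
    leftovers: dict[str, NeighborLink | None]
    report: dict


def run_global_pipeline(
    proteins: Mapping[str, str],
    seeds: Sequence[SeedCluster],
    *,
    scoring=None,
    tight: Thresholds | None = None,
    liberal: Thresholds | None = None,
    extension: Thresholds = GLOBAL_THRESHOLDS,
    word_length: int = 5,
    max_accepts: int = 8,
    max_rejects: int = 64,
    exhaustive_filter_check: bool = False,
) -> GlobalResult:
    """The global cascade around fixed seed clusters.

    Stages: (a) direct assignment of proteins tightly matching a seed
    clustroid; (b) greedy tight-grouping of the remainder and selection of
    group representatives; (c) liberal k-mer filtering of the
    representatives against the clustroids; (d) seed extension of the
    retained representatives; (e) propagation of representative assignments
    back to tight-group members.  Emits per-stage counts and compression
    ratios in ``report``.
    """
    from .core import LIBERAL_FILTER_THRESHOLDS, TIGHT_GROUP_THRESHOLDS
    from .kmer import GreedyParams, KmerIndex, filter_seed_neighbors, greedy_cluster, search
    from .similarity import ScoringConfig, pair_hit

    scoring = scoring or ScoringConfig()
    tight = tight or TIGHT_GROUP_THRESHOLDS
    liberal = liberal or LIBERAL_FILTER_THRESHOLDS

    seed_protein_ids = set()
    clustroid_cluster: dict[str, str] = {}
    for sc in seeds:
        seed_protein_ids |= sc.clustroid_members
        for cid in sc.clustroid_members:
            clustroid_cluster[cid] = sc.cluster_id
    missing = seed_protein_ids - set(proteins)
    if missing:
        raise ValueError(
            f"seed clustroids missing from protein set: {sorted(missing)[:5]}"
        )
    clustroid_seqs = {cid: proteins[cid] for cid in sorted(seed_protein_ids)}
    candidates = {p: s for p, s in proteins.items() if p not in seed_protein_ids}

    # (a) direct assignment at tight thresholds
    tight_params = GreedyParams(
        word_length=word_length,
        max_accepts=max_accepts,
        max_rejects=max_rejects,
        thresholds=tight,
    )
    index = KmerIndex(word_length)
    for cid, seq in clustroid_seqs.items():
        index.add(cid, seq)
    direct_assigned: dict[str, str] = {}
    remainder: dict[str, str] = {}
    for pid in sorted(candidates):
        found = search(pid, candidates[pid], index, tight_params, scoring)
        if found:
            best = min(
                found,
                key=lambda rh: (
                    -rh[1].identity_pct,
                    -min(rh[1].coverage_query_pct, rh[1].coverage_subject_pct),
                    clustroid_cluster[rh[0]],
                ),
            )
            direct_assigned[pid] = clustroid_cluster[best[0]]
        else:
            remainder[pid] = candidates[pid]

    # (b) tight grouping of the remainder
    if remainder:
        greedy = greedy_cluster(remainder, tight_params, scoring)
        group_assignment = dict(greedy.assignment)
        representatives = {r: remainder[r] for r in greedy.representatives}
    else:
        group_assignment = {}
        representatives = {}

    # (c) liberal filtering of representatives against clustroids
    liberal_params = GreedyParams(
        word_length=word_length,
        max_accepts=max_accepts,
        max_rejects=max_rejects,
        thresholds=liberal,
    )
    retained, filter_report = filter_seed_neighbors(
        representatives, clustroid_seqs, liberal_params, scoring
    )

    # (d) extension: aggregated hits of retained representatives vs clustroids
    hits: dict[str, list[HitRecord]] = {}
    for pid in retained:
        row: list[HitRecord] = []
        for cid, cseq in clustroid_seqs.items():
            h = pair_hit(pid, representatives[pid], cid, cseq, scoring)
            if h is not None:
                row.append(h)
        hits[pid] = row
    extended, rep_leftovers = extend_seeds(retained, seeds, hits, extension)
    rep_cluster: dict[str, str] = {}
    for sc in extended:
        for pid in sc.extension_members:
            rep_cluster[pid] = sc.cluster_id

    # dropped representatives are leftovers with no neighbor link
    retained_set = set(retained)
    for pid in sorted(representatives):
        if pid not in retained_set and pid not in rep_leftovers:
            rep_leftovers[pid] = None

    # optional loss audit: dropped representatives that the extension stage
    # would in fact have assigned (the relevant loss, as a fraction of all
    # extension-assignable representatives)
    filter_loss_pct = None
    if exhaustive_filter_check:
        lost = 0
        for pid in sorted(representatives):
            if pid in retained_set:
                continue
            for cid, cseq in clustroid_seqs.items():
                h = pair_hit(pid, representatives[pid], cid, cseq, scoring)
                if h is not None and is_related(h, extension):
                    lost += 1
                    break
        assignable = len(rep_cluster) + lost
        filter_loss_pct = 100.0 * lost / assignable if assignable else 0.0

    # (e) propagate to tight-group members
    extension_assigned: dict[str, str] = {}
    leftovers: dict[str, NeighborLink | None] = {}
    for pid, rep in group_assignment.items():
        if rep in rep_cluster:
            extension_assigned[pid] = rep_cluster[rep]
        else:
            leftovers[pid] = rep_leftovers.get(rep) if pid == rep else None
    final = [
        SeedCluster(sc.cluster_id, set(sc.clustroid_members), set()) for sc in extended
    ]
    by_id = {sc.cluster_id: sc for sc in final}
    for pid, cl in list(direct_assigned.items()) + list(extension_assigned.items()):
        by_id[cl].extension_members.add(pid)

    n_ext = sum(len(sc.extension_members) for sc in final)
    n_total = len(proteins)
    report = {
        "n_input_proteins": n_total,
        "n_seed_clusters": len(seeds),
        "n_seed_clustroids": len(seed_protein_ids),
        "n_direct_assigned": len(direct_assigned),
        "n_tight_group_members": len(group_assignment),
        "n_tight_group_representatives": len(representatives),
        "n_filter_retained": filter_report.n_retained,
        "n_filter_dropped": filter_report.n_dropped,
        "filter_loss_pct": filter_loss_pct,
        "n_extension_members": n_ext,
        "n_leftovers": len(leftovers),
        "conserved": len(seed_protein_ids) + n_ext + len(leftovers) == n_total,
        "proteins_per_extended_seed_cluster": (
            (len(seed_protein_ids) + n_ext) / len(seeds) if seeds else float("nan")
        ),
    }
    return GlobalResult(
        seeds=final,
        direct_assigned=direct_assigned,
        group_assignment=group_assignment,
        extension_assigned=extension_assigned,
        leftovers=leftovers,
        report=report,
    )
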