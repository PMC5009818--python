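"""Disjoint-set partitioning of the relatedness graph for parallel clustering.

Clustering only ever merges clusters connected by a related edge, so the
connected components of the relatedness graph can be clustered
independently — per-partition clustering provably equals whole-set
clustering for every linkage on offer.  Components are found with a
disjoint-set forest using union by rank plus path compression (the latter a
pure optimization; component semantics are unchanged).

Concurrency is a contract, not a backend: the per-partition cluster
function must be deterministic and share no mutable state, so the merged
output is identical for any worker count and execution order.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence


class DisjointSet:
    """Union-find forest with union by rank and path compression."""

    def __init__(self, elements: Iterable[str] = ()) -> None:
        self.parent: dict[str, str] = {}
        self.rank: dict[str, int] = {}
        for e in elements:
            self.add(e)

    def add(self, e: str) -> None:
        if e not in self.parent:
            self.parent[e] = e
            self.rank[e] = 0

    def find(self, e: str) -> str:
        root = e
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[e] != root:  # path compression
            self.parent[e], e = root, self.parent[e]
        return root

    def union(self, a: str, b: str) -> str:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return ra


def partition(
    edges: Iterable[tuple[str, str]],
    universe: Iterable[str],
) -> dict[str, str]:
    """Map every id to its partition id (the smallest member of its component).

    Partitions are the connected components of the related-pair graph;
    isolated ids form singleton partitions.  Edge endpoints outside the
    universe are an error.
    """
    universe = set(universe)
    dsu = DisjointSet(sorted(universe))
    for a, b in edges:
        if a not in universe or b not in universe:
            raise ValueError(f"edge endpoint outside universe: {(a, b)}")
        dsu.union(a, b)
    comp_min: dict[str, str] = {}
    for e in sorted(universe):
        root = dsu.find(e)
        if root not in comp_min:
            comp_min[root] = e  # sorted scan: first seen is the smallest
    return {e: comp_min[dsu.find(e)] for e in universe}


@dataclass(frozen=True)
class LoadReport:
    """Per-partition sizes and imbalance of the parallel stage."""

    n_partitions: int
    sizes: tuple[int, ...]
    max_size: int
    mean_size: float

    @property
    def imbalance(self) -> float:
        """max/mean partition size; 1.0 is a perfectly balanced load."""
        return self.max_size / self.mean_size if self.mean_size else 0.0


def cluster_by_partition(
    partition_map: Mapping[str, str],
    cluster_fn: Callable[[Sequence[str]], list[set[str]]],
    n_workers: int = 1,
) -> tuple[list[set[str]], LoadReport]:
    """Run the cluster function in every partition and merge the outputs.

    The result is the concatenation of per-partition cluster lists in
    deterministic partition order and is independent of ``n_workers``.  A
    partition whose cluster function raises aborts the run with the
    partition id named.
    """
    groups: dict[str, list[str]] = {}
    for e, pid in partition_map.items():
        groups.setdefault(pid, []).append(e)
    ordered = sorted(groups)
    for pid in ordered:
        groups[pid].sort()

    def run_one(pid: str) -> list[set[str]]:
        try:
            return cluster_fn(groups[pid])
        except Exception as exc:  # noqa: BLE001 - re-raise with partition id
            raise RuntimeError(f"clustering failed in partition {pid}") from exc

    if n_workers <= 1 or len(ordered) <= 1:
        results = [run_one(pid) for pid in ordered]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(run_one, ordered))
    merged: list[set[str]] = []
    for r in results:
        merged.extend(r)
    merged.sort(key=lambda c: min(c) if c else "")
    sizes = tuple(len(groups[pid]) for pid in ordered)
    report = LoadReport(
        n_partitions=len(ordered),
        sizes=sizes,
        max_size=max(sizes) if sizes else 0,
        mean_size=sum(sizes) / len(sizes) if sizes else 0.0,
    )
    return merged, report
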