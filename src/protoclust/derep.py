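"""Genome dereplication: clonal grouping and representative selection.

Within each clade, near-clonal genomes are grouped by complete-linkage
agglomerative clustering on whole-genome identity with a 95 % cutoff, so
that every pair inside a group is at least 95 % identical.  One
representative is kept per group, preferring (1) the clade reference or
representative genome, (2) membership in a curated pathway database, (3) an
annotated genome, with ties broken by smallest genome id.

Whole-genome identity is normally an input (e.g. from genomic BLAST or any
average-nucleotide-identity tool).  For self-contained synthetic runs a
proteome proxy is provided: the coding-region-weighted mean of each
protein's best identity against the other genome's proteome, symmetrized by
averaging the two directions.  It is a stand-in for nucleotide-level genome
comparison, not a re-implementation of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import Dataset, Genome, HitRecord, Thresholds, edge_key
from .globalcluster import base_hierarchical
from .kmer import GreedyParams, KmerIndex, search
from .similarity import ScoringConfig

GenomeSimilarities = Mapping[tuple[str, str], float]  # canonical pair -> identity %


def clonal_groups(
    genome_ids: Sequence[str],
    similarities: GenomeSimilarities,
    cutoff: float = 95.0,
) -> list[set[str]]:
    """Complete-linkage grouping at the identity cutoff.

    Missing pairs are treated as identity 0.  The complete-linkage
    guarantee holds: every within-group pair has identity >= cutoff.
    Merge ties are broken by smallest member id.
    """
    in_scope = set(genome_ids)
    edges: dict[tuple[str, str], HitRecord] = {}
    for (a, b), ident in similarities.items():
        if not 0.0 <= ident <= 100.0:
            raise ValueError(f"identity out of range for pair {(a, b)}: {ident}")
        if a == b or a not in in_scope or b not in in_scope:
            continue
        key = edge_key(a, b)
        prev = edges.get(key)
        if prev is not None and prev.identity_pct != ident:
            raise ValueError(f"conflicting identities for pair {key}")
        edges[key] = HitRecord(key[0], key[1], ident, 100.0, 100.0)
    edges = {
        k: h for k, h in edges.items() if h.identity_pct >= cutoff
    }  # sub-cutoff pairs are unrelated; complete linkage caps them anyway
    return base_hierarchical(
        genome_ids, edges, Thresholds(cutoff, 0.0), linkage="complete"
    )


def pick_representative(group: Sequence[Genome]) -> str:
    """Preference-ranked representative of one clonal group."""
    if not group:
        raise ValueError("empty group")
    best = min(
        group,
        key=lambda g: (
            not g.is_reference_or_representative,
            not g.in_curated_pathway_db,
            not g.is_annotated,
            g.genome_id,
        ),
    )
    return best.genome_id


def genome_similarity_proxy(
    dataset: Dataset,
    scoring: ScoringConfig = ScoringConfig(),
    word_length: int = 5,
    within_clades_only: bool = True,
) -> dict[tuple[str, str], float]:
    """Proteome-proxy whole-genome identity for genome pairs.

    For a pair (A, B): index B's proteins, look up each of A's proteins
    (best verified identity, 0 when nothing verifies), average weighted by
    the number of coding regions of the protein in A, then average the two
    directions.  Only same-clade pairs are computed by default — the
    dereplication cutoff only ever applies within a clade.
    """
    params = GreedyParams(
        word_length=word_length,
        max_accepts=4,
        max_rejects=16,
        thresholds=Thresholds(10.0, 0.0),
    )
    regions_by_genome = dataset.regions_by_genome()

    def genome_proteins(gid: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in regions_by_genome.get(gid, []):
            counts[r.protein_id] = counts.get(r.protein_id, 0) + 1
        return counts

    indices: dict[str, KmerIndex] = {}

    def index_for(gid: str) -> KmerIndex:
        idx = indices.get(gid)
        if idx is None:
            idx = KmerIndex(word_length)
            for pid in sorted(genome_proteins(gid)):
                idx.add(pid, dataset.proteins[pid].sequence)
            indices[gid] = idx
        return idx

    def directed(a: str, b: str) -> float:
        counts = genome_proteins(a)
        idx = index_for(b)
        total_w = 0
        acc = 0.0
        for pid in sorted(counts):
            w = counts[pid]
            total_w += w
            if pid in idx.sequences:  # shared protein: identical sequence
                acc += 100.0 * w
                continue
            found = search(pid, dataset.proteins[pid].sequence, idx, params, scoring)
            if found:
                acc += max(h.identity_pct for _, h in found) * w
        return acc / total_w if total_w else 0.0

    out: dict[tuple[str, str], float] = {}
    clades = dataset.clades()
    pairs: list[tuple[str, str]] = []
    if within_clades_only:
        for genome_ids in clades.values():
            for i, a in enumerate(genome_ids):
                for b in genome_ids[i + 1 :]:
                    pairs.append((a, b))
    else:
        ids = sorted(dataset.genomes)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    for a, b in pairs:
        out[edge_key(a, b)] = 0.5 * (directed(a, b) + directed(b, a))
    return out


@dataclass
class DerepResult:
    groups: dict[str, list[set[str]]]  # clade -> clonal groups
    representative_of_group: dict[str, str]  # group id (min member) -> rep genome
    genome_group: dict[str, str]  # genome -> group id
    representatives: dict[str, list[str]] = field(default_factory=dict)  # per clade

    def n_nonclonal(self, clade_id: str) -> int:
        return len(self.representatives.get(clade_id, []))


def dereplicate(
    dataset: Dataset,
    similarities: GenomeSimilarities,
    cutoff: float = 95.0,
) -> DerepResult:
    """Clonal-group every clade and pick one representative per group."""
    result = DerepResult(groups={}, representative_of_group={}, genome_group={})
    for clade_id, genome_ids in sorted(dataset.clades().items()):
        groups = clonal_groups(genome_ids, similarities, cutoff)
        result.groups[clade_id] = groups
        reps: list[str] = []
        for grp in groups:
            gid = min(grp)
            rep = pick_representative([dataset.genomes[g] for g in sorted(grp)])
            result.representative_of_group[gid] = rep
            for g in grp:
                result.genome_group[g] = gid
            reps.append(rep)
        result.representatives[clade_id] = sorted(reps)
    return result
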