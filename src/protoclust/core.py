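"""Domain model shared by every clustering stage.

The pipeline reasons about four kinds of objects: genomes grouped into
species-level clades, coding regions (gene occurrences on contigs, addressed
by 0-based gene-order ordinals rather than nucleotide coordinates), unique
amino-acid sequences (one :class:`ProteinRecord` per distinct sequence, so
identical proteins from clonal genomes share a record), and aggregated
pairwise similarity measurements (:class:`HitRecord`).

Two primitives defined here drive every merge decision downstream:

* :func:`is_related` — the thresholded relatedness predicate ("at least X %
  identity with Y % coverage").  Coverage is required of *both* sequences by
  default so that relatedness is symmetric; a shorter-sequence-only variant
  is available via ``coverage_mode``.
* :func:`distance` — ``1 - identity/100`` for related pairs, ``+inf``
  otherwise.  Merge decisions are threshold-driven; identity is the only
  graded quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*")

CoverageMode = Literal["both", "shorter"]


@dataclass(frozen=True)
class Thresholds:
    """A (minimum identity %, minimum coverage %) pair gating relatedness."""

    min_identity_pct: float
    min_coverage_pct: float

    def __post_init__(self) -> None:
        for name in ("min_identity_pct", "min_coverage_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


#: Published threshold presets, by pipeline stage.
INCLADE_THRESHOLDS = Thresholds(80.0, 85.0)
GLOBAL_THRESHOLDS = Thresholds(50.0, 70.0)
COLLAPSE_THRESHOLDS = Thresholds(98.0, 100.0)
TIGHT_GROUP_THRESHOLDS = Thresholds(80.0, 85.0)
LIBERAL_FILTER_THRESHOLDS = Thresholds(10.0, 70.0)
GENOME_DEREP_CUTOFF = 95.0


@dataclass(frozen=True)
class Genome:
    genome_id: str
    clade_id: str
    is_annotated: bool = True
    is_reference_or_representative: bool = False
    in_curated_pathway_db: bool = False
    contigs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id}")


@dataclass(frozen=True)
class CodingRegion:
    region_id: str
    genome_id: str
    contig_id: str
    ordinal: int  # 0-based gene-order index along the contig
    strand: str  # "+" or "-"
    protein_id: str
    is_complete: bool = True

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ValueError(f"ordinal must be >= 0 in region {self.region_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or - in region {self.region_id}")


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: residues outside amino-acid "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """Aggregated pairwise similarity of two sequences.

    ``identity_pct`` is percent identity over the aggregated alignment
    columns; the two coverage fields are the percent of each sequence spanned
    by the (pruned) alignment blocks.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    coverage_query_pct: float
    coverage_subject_pct: float

    def swapped(self) -> "HitRecord":
        return HitRecord(
            self.subject_id,
            self.query_id,
            self.identity_pct,
            self.coverage_subject_pct,
            self.coverage_query_pct,
        )


@dataclass
class Cluster:
    cluster_id: str
    level: str  # "inclade" | "seed" | "global"
    members: set[str] = field(default_factory=set)
    clustroid_id: str | None = None
    is_conservative: bool = False
    clade_id: str | None = None
    member_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clustroid_id is not None and self.clustroid_id not in self.members:
            raise ValueError(
                f"cluster {self.cluster_id}: clustroid {self.clustroid_id} "
                "is not a member"
            )


def is_related(
    hit: HitRecord, t: Thresholds, coverage_mode: CoverageMode = "both"
) -> bool:
    """True iff the hit satisfies the minimum identity and coverage conditions.

    Both bounds are closed (``>=``, "at least").  ``coverage_mode="both"``
    requires the coverage of both sequences to pass (min of the two), keeping
    the predicate symmetric under query/subject swap; ``"shorter"`` requires
    only the better-covered (shorter) sequence to pass.
    """
    if hit.identity_pct < t.min_identity_pct:
        return False
    if coverage_mode == "both":
        cov = min(hit.coverage_query_pct, hit.coverage_subject_pct)
    else:
        cov = max(hit.coverage_query_pct, hit.coverage_subject_pct)
    return cov >= t.min_coverage_pct


def distance(
    hit: HitRecord | None, t: Thresholds, coverage_mode: CoverageMode = "both"
) -> float:
    """Clustering distance: ``1 - identity/100`` if related, else ``+inf``."""
    if hit is None or not is_related(hit, t, coverage_mode):
        return math.inf
    return 1.0 - hit.identity_pct / 100.0


class Dataset:
    """A validated collection of genomes, coding regions and proteins.

    Enforces the structural invariants every stage relies on: unique genome
    ids, one coding region per (genome, contig, ordinal) slot, consecutive
    0-based ordinals along each contig, a protein-id <-> sequence bijection,
    and region lists consistent between proteins and coding regions.
    """

    def __init__(
        self,
        genomes: Iterable[Genome],
        regions: Iterable[CodingRegion],
        proteins: Iterable[ProteinRecord],
    ) -> None:
        self.genomes: dict[str, Genome] = {}
        for g in genomes:
            if g.genome_id in self.genomes:
                raise ValueError(f"duplicate genome id {g.genome_id}")
            self.genomes[g.genome_id] = g

        self.regions: dict[str, CodingRegion] = {}
        slots: set[tuple[str, str, int]] = set()
        for r in regions:
            if r.region_id in self.regions:
                raise ValueError(f"duplicate region id {r.region_id}")
            slot = (r.genome_id, r.contig_id, r.ordinal)
            if slot in slots:
                raise ValueError(f"duplicate gene slot {slot}")
            slots.add(slot)
            self.regions[r.region_id] = r

        by_contig: dict[tuple[str, str], list[int]] = {}
        for r in self.regions.values():
            by_contig.setdefault((r.genome_id, r.contig_id), []).append(r.ordinal)
        for (gid, cid), ords in by_contig.items():
            ords.sort()
            if ords != list(range(len(ords))):
                raise ValueError(
                    f"ordinals on contig {cid} of genome {gid} are not "
                    "consecutive from 0"
                )

        self.proteins: dict[str, ProteinRecord] = {}
        seq_to_id: dict[str, str] = {}
        for p in proteins:
            if p.protein_id in self.proteins:
                raise ValueError(f"duplicate protein id {p.protein_id}")
            prev = seq_to_id.get(p.sequence)
            if prev is not None:
                raise ValueError(
                    f"proteins {prev} and {p.protein_id} share a sequence; "
                    "identical sequences must share one record"
                )
            seq_to_id[p.sequence] = p.protein_id
            if not p.regions:
                raise ValueError(f"protein {p.protein_id} has no coding regions")
            self.proteins[p.protein_id] = p

        for p in self.proteins.values():
            for rid in p.regions:
                r = self.regions.get(rid)
                if r is None:
                    raise ValueError(
                        f"protein {p.protein_id} references unknown region {rid}"
                    )
                if r.protein_id != p.protein_id:
                    raise ValueError(
                        f"region {rid} belongs to protein {r.protein_id}, "
                        f"not {p.protein_id}"
                    )

    # -- convenience views ------------------------------------------------

    def protein_is_complete(self, protein_id: str) -> bool:
        p = self.proteins[protein_id]
        return all(self.regions[rid].is_complete for rid in p.regions)

    def clades(self) -> dict[str, list[str]]:
        """Map clade_id -> sorted genome ids."""
        out: dict[str, list[str]] = {}
        for g in self.genomes.values():
            out.setdefault(g.clade_id, []).append(g.genome_id)
        for v in out.values():
            v.sort()
        return out

    def regions_by_genome(self) -> dict[str, list[CodingRegion]]:
        out: dict[str, list[CodingRegion]] = {}
        for r in self.regions.values():
            out.setdefault(r.genome_id, []).append(r)
        for v in out.values():
            v.sort(key=lambda r: (r.contig_id, r.ordinal))
        return out

    def contig_gene_orders(self) -> dict[tuple[str, str], list[CodingRegion]]:
        """Map (genome_id, contig_id) -> regions in gene order."""
        out: dict[tuple[str, str], list[CodingRegion]] = {}
        for r in self.regions.values():
            out.setdefault((r.genome_id, r.contig_id), []).append(r)
        for v in out.values():
            v.sort(key=lambda r: r.ordinal)
        return out


def check_partition(
    clusters: Iterable[Cluster] | Iterable[set[str]], universe: set[str]
) -> None:
    """Raise if the clusters do not partition ``universe`` exactly."""
    seen: set[str] = set()
    for c in clusters:
        members = c.members if isinstance(c, Cluster) else set(c)
        dup = seen & members
        if dup:
            raise AssertionError(f"overlapping cluster members: {sorted(dup)[:5]}")
        seen |= members
    if seen != universe:
        missing = universe - seen
        extra = seen - universe
        raise AssertionError(
            f"not a partition: missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
        )


EdgeMap = Mapping[tuple[str, str], HitRecord]


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair key."""
    return (a, b) if a <= b else (b, a)
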