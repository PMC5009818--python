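"""Interchange formats: FASTA, TSV tables, tabular hits, reports, config.

All tables are tab-separated with a header row; ids are opaque strings.
Alignment coordinates in the tabular hit format are 1-based inclusive (the
de facto 12-column standard of local aligners); gene ordinals are 0-based
gene-order indices internally — the conversion lives here.  Every writer's
output is re-readable by the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Cluster,
    CodingRegion,
    Dataset,
    Genome,
    HitRecord,
    ProteinRecord,
    Thresholds,
    edge_key,
)
from .globalcluster import NeighborLink, SeedCluster
from .similarity import RawHSP, aggregate_hsps

HITS_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read an amino-acid FASTA into an id -> sequence map.

    Duplicate ids with differing sequences are a hard error (the protein-id
    to sequence mapping must be a bijection); exact duplicate records are
    tolerated and collapsed.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        prev = out.get(rec.id)
        if prev is not None and prev != seq:
            raise ValueError(f"duplicate id {rec.id} with differing sequences")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(sequences[pid]), id=pid, description="")
        for pid in sorted(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# TSV helpers


def _write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _read_tsv(path: str | Path, expected_header: Sequence[str]) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(expected_header):
            raise ValueError(
                f"{path}: expected columns {list(expected_header)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(expected_header):
                raise ValueError(f"{path}:{lineno}: expected {len(expected_header)} fields")
            rows.append(fields)
    return rows


_BOOL = {"true": True, "1": True, "false": False, "0": False}


def _parse_bool(value: str, where: str) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise ValueError(f"{where}: not a boolean: {value!r}") from None


# --------------------------------------------------------------------------
# gene / clade / similarity tables

GENE_COLUMNS = ["genome_id", "contig_id", "ordinal", "strand", "protein_id", "is_complete"]
CLADE_COLUMNS = ["genome_id", "clade_id", "is_annotated", "is_rep_pref", "in_pathway_db"]
SIMILARITY_COLUMNS = ["genome_a", "genome_b", "identity_pct"]


def write_gene_table(path: str | Path, regions: Iterable[CodingRegion]) -> None:
    rows = sorted(
        (r.genome_id, r.contig_id, r.ordinal, r.strand, r.protein_id, str(r.is_complete).lower())
        for r in regions
    )
    _write_tsv(path, GENE_COLUMNS, rows)


def read_gene_table(path: str | Path) -> list[CodingRegion]:
    """Read coding regions; region_id is derived as ``contig_id:ordinal``."""
    regions = []
    seen: set[tuple[str, str, int]] = set()
    for lineno, f in enumerate(_read_tsv(path, GENE_COLUMNS), start=2):
        genome_id, contig_id, ordinal_s, strand, protein_id, complete_s = f
        try:
            ordinal = int(ordinal_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: ordinal not an integer: {ordinal_s!r}")
        slot = (genome_id, contig_id, ordinal)
        if slot in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene slot {slot}")
        seen.add(slot)
        regions.append(
            CodingRegion(
                region_id=f"{contig_id}:{ordinal}",
                genome_id=genome_id,
                contig_id=contig_id,
                ordinal=ordinal,
                strand=strand,
                protein_id=protein_id,
                is_complete=_parse_bool(complete_s, f"{path}:{lineno}"),
            )
        )
    return regions


def write_clade_table(path: str | Path, genomes: Iterable[Genome]) -> None:
    rows = sorted(
        (
            g.genome_id,
            g.clade_id,
            str(g.is_annotated).lower(),
            str(g.is_reference_or_representative).lower(),
            str(g.in_curated_pathway_db).lower(),
        )
        for g in genomes
    )
    _write_tsv(path, CLADE_COLUMNS, rows)


def read_clade_table(path: str | Path) -> dict[str, Genome]:
    """Genomes keyed by id; contig lists are filled in by :func:`load_dataset`."""
    out: dict[str, Genome] = {}
    for lineno, f in enumerate(_read_tsv(path, CLADE_COLUMNS), start=2):
        gid, clade, ann, rep, kegg = f
        if gid in out:
            raise ValueError(f"{path}:{lineno}: duplicate genome id {gid}")
        out[gid] = Genome(
            genome_id=gid,
            clade_id=clade,
            is_annotated=_parse_bool(ann, f"{path}:{lineno}"),
            is_reference_or_representative=_parse_bool(rep, f"{path}:{lineno}"),
            in_curated_pathway_db=_parse_bool(kegg, f"{path}:{lineno}"),
        )
    return out


def write_genome_similarities(
    path: str | Path, sims: Mapping[tuple[str, str], float]
) -> None:
    rows = sorted((a, b, f"{v:.4f}") for (a, b), v in sims.items())
    _write_tsv(path, SIMILARITY_COLUMNS, rows)


def read_genome_similarities(path: str | Path) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for lineno, (a, b, v) in enumerate(_read_tsv(path, SIMILARITY_COLUMNS), start=2):
        out[edge_key(a, b)] = float(v)
    return out


def load_dataset(
    fasta_path: str | Path, gene_table_path: str | Path, clade_table_path: str | Path
) -> Dataset:
    """Assemble and validate a :class:`Dataset` from the three input files."""
    sequences = read_fasta(fasta_path)
    regions = read_gene_table(gene_table_path)
    genomes_by_id = read_clade_table(clade_table_path)
    contig_order: dict[str, list[str]] = {}
    protein_regions: dict[str, list[str]] = {}
    for r in sorted(regions, key=lambda r: (r.genome_id, r.contig_id, r.ordinal)):
        if r.genome_id not in genomes_by_id:
            raise ValueError(f"gene table references unknown genome {r.genome_id}")
        if r.protein_id not in sequences:
            raise ValueError(f"gene table references unknown protein {r.protein_id}")
        contigs = contig_order.setdefault(r.genome_id, [])
        if r.contig_id not in contigs:
            contigs.append(r.contig_id)
        protein_regions.setdefault(r.protein_id, []).append(r.region_id)
    orphans = sorted(set(sequences) - set(protein_regions))
    if orphans:
        raise ValueError(f"proteins without coding regions: {orphans[:5]}")
    genomes = [
        dataclasses.replace(g, contigs=tuple(contig_order.get(gid, ())))
        for gid, g in sorted(genomes_by_id.items())
    ]
    proteins = [
        ProteinRecord(pid, sequences[pid], regions=protein_regions[pid])
        for pid in sorted(protein_regions)
    ]
    return Dataset(genomes, regions, proteins)


# --------------------------------------------------------------------------
# tabular hits (12-column), one row per HSP


def read_hits_tabular(
    path: str | Path,
    lengths: Mapping[str, int],
    overlap_prune_fraction: float = 0.5,
) -> dict[tuple[str, str], HitRecord]:
    """Aggregate a 12-column tabular hit file into per-pair HitRecords.

    Rows sharing an ordered (query, subject) pair are HSPs of one hit and
    are aggregated; self-hits are dropped; when both orientations of a pair
    are present, the canonical orientation wins.  Ids absent from
    ``lengths`` are collected and reported in one error.
    """
    per_pair: dict[tuple[str, str], list[RawHSP]] = {}
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            q, s = f[0], f[1]
            for pid in (q, s):
                if pid not in lengths:
                    unknown.add(pid)
            if q == s:
                continue
            pident, length = float(f[2]), int(f[3])
            per_pair.setdefault((q, s), []).append(
                RawHSP(
                    query_id=q,
                    subject_id=s,
                    q_start=int(f[6]),
                    q_end=int(f[7]),
                    s_start=int(f[8]),
                    s_end=int(f[9]),
                    n_identities=round(pident / 100.0 * length),
                    n_columns=length,
                    score=float(f[11]),
                )
            )
    if unknown:
        raise ValueError(f"hit file references unknown ids: {sorted(unknown)}")
    out: dict[tuple[str, str], HitRecord] = {}
    for (q, s), hsps in sorted(per_pair.items()):
        hit = aggregate_hsps(hsps, lengths[q], lengths[s], overlap_prune_fraction)
        key = edge_key(q, s)
        if key in out:
            continue  # canonical orientation already aggregated
        out[key] = hit if (q, s) == key else hit.swapped()
    return out


def write_hits_tabular(
    path: str | Path, hits: Iterable[HitRecord], lengths: Mapping[str, int]
) -> None:
    """Write aggregated hits as single-HSP 12-column rows (coverage-faithful)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            lq = lengths[h.query_id]
            ls = lengths[h.subject_id]
            q_span = max(1, round(h.coverage_query_pct / 100.0 * lq))
            s_span = max(1, round(h.coverage_subject_pct / 100.0 * ls))
            ncols = max(q_span, s_span)
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, f"{h.identity_pct:.2f}", ncols,
                        ncols - round(h.identity_pct / 100.0 * ncols), 0,
                        1, q_span, 1, s_span, "1e-9", "0.0",
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# clusters / assignments / reports

CLUSTER_COLUMNS = ["cluster_id", "level", "clade_id", "protein_id", "role", "is_conservative"]


def write_clusters(path: str | Path, clusters: Iterable[Cluster]) -> None:
    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        for pid in sorted(c.members):
            rows.append(
                (
                    c.cluster_id,
                    c.level,
                    c.clade_id or "-",
                    pid,
                    c.member_roles.get(pid, "plain"),
                    str(c.is_conservative).lower(),
                )
            )
    _write_tsv(path, CLUSTER_COLUMNS, rows)


def read_clusters(path: str | Path) -> list[Cluster]:
    by_id: dict[str, Cluster] = {}
    for lineno, f in enumerate(_read_tsv(path, CLUSTER_COLUMNS), start=2):
        cid, level, clade, pid, role, conservative = f
        c = by_id.get(cid)
        if c is None:
            c = Cluster(
                cluster_id=cid,
                level=level,
                clade_id=None if clade == "-" else clade,
                is_conservative=_parse_bool(conservative, f"{path}:{lineno}"),
            )
            by_id[cid] = c
        c.members.add(pid)
        c.member_roles[pid] = role
        if role == "clustroid":
            c.clustroid_id = pid
    return [by_id[k] for k in sorted(by_id)]


def write_seed_clusters(path: str | Path, seeds: Iterable[SeedCluster]) -> None:
    rows = []
    for sc in sorted(seeds, key=lambda s: s.cluster_id):
        for pid in sorted(sc.clustroid_members):
            rows.append((sc.cluster_id, pid, "clustroid"))
        for pid in sorted(sc.extension_members):
            rows.append((sc.cluster_id, pid, "extension"))
    _write_tsv(path, ["cluster_id", "protein_id", "role"], rows)


def read_seed_clusters(path: str | Path) -> list[SeedCluster]:
    clustroids: dict[str, set[str]] = {}
    extensions: dict[str, set[str]] = {}
    for f in _read_tsv(path, ["cluster_id", "protein_id", "role"]):
        cid, pid, role = f
        if role == "clustroid":
            clustroids.setdefault(cid, set()).add(pid)
            extensions.setdefault(cid, set())
        elif role == "extension":
            extensions.setdefault(cid, set()).add(pid)
        else:
            raise ValueError(f"unknown role {role!r} in {path}")
    return [
        SeedCluster(cid, clustroids[cid], extensions.get(cid, set()))
        for cid in sorted(clustroids)
    ]


def write_assignment(
    path: str | Path, assignment: Mapping[str, str], hits: Mapping[str, HitRecord] = {}
) -> None:
    """member_id, representative_id, identity, coverage (self rows: 100/100)."""
    rows = []
    for pid in sorted(assignment):
        rep = assignment[pid]
        h = hits.get(pid)
        if h is None:
            ident, cov = (100.0, 100.0) if pid == rep else (float("nan"),) * 2
        else:
            ident = h.identity_pct
            cov = min(h.coverage_query_pct, h.coverage_subject_pct)
        rows.append((pid, rep, f"{ident:.2f}", f"{cov:.2f}"))
    _write_tsv(path, ["member_id", "representative_id", "identity", "coverage"], rows)


def write_leftovers(
    path: str | Path, leftovers: Mapping[str, NeighborLink | None]
) -> None:
    rows = []
    for pid in sorted(leftovers):
        link = leftovers[pid]
        if link is None:
            rows.append((pid, "-", "-", "-", "-"))
        else:
            rows.append(
                (
                    pid,
                    link.clustroid_id,
                    link.cluster_id,
                    f"{link.identity_pct:.2f}",
                    f"{link.coverage_pct:.2f}",
                )
            )
    _write_tsv(
        path,
        ["protein_id", "neighbor_clustroid", "neighbor_cluster", "neighbor_identity", "neighbor_coverage"],
        rows,
    )


def write_partition_map(path: str | Path, partition_map: Mapping[str, str]) -> None:
    rows = sorted(partition_map.items())
    _write_tsv(path, ["protein_id", "partition_id"], rows)


def write_neighborhood_map(path: str | Path, inclade_result, dataset: Dataset) -> None:
    """Fig-style neighborhood table: cluster, genome, offset -2..+2, neighbor."""
    rows = []
    half = 2
    for c in inclade_result.clusters:
        for pid in sorted(c.members):
            for rid in sorted(dataset.proteins[pid].regions):
                window = inclade_result.context.get(rid)
                if window is None:
                    continue
                genome = dataset.regions[rid].genome_id
                for off, neighbor in zip(range(-half, half + 1), window):
                    rows.append((c.cluster_id, genome, off, neighbor or "-"))
    _write_tsv(path, ["cluster_id", "genome_id", "offset", "neighbor_cluster_id"], rows)


def write_report(path_base: str | Path, report: Mapping) -> None:
    """Write a report as JSON plus a flat key-value text twin."""
    base = Path(path_base)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    def flatten(prefix: str, obj) -> Iterable[tuple[str, str]]:
        if isinstance(obj, Mapping):
            for k in sorted(obj):
                yield from flatten(f"{prefix}{k}." if prefix else f"{k}.", obj[k])
        else:
            yield prefix.rstrip("."), str(obj)

    with open(base.with_suffix(".txt"), "w") as fh:
        for key, value in flatten("", report):
            fh.write(f"{key}\t{value}\n")


# --------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class PipelineConfig:
    """Stage thresholds and knobs; defaults are the published settings."""

    inclade_identity: float = 80.0
    inclade_coverage: float = 85.0
    seed_identity: float = 50.0
    seed_coverage: float = 70.0
    extension_identity: float = 50.0
    extension_coverage: float = 70.0
    collapse_identity: float = 98.0
    collapse_coverage: float = 100.0
    tight_identity: float = 80.0
    tight_coverage: float = 85.0
    liberal_identity: float = 10.0
    liberal_coverage: float = 70.0
    derep_cutoff: float = 95.0
    conservative_fraction: float = 0.9
    min_nonclonal: int = 10
    linkage: str = "average"
    word_length: int = 5
    max_accepts: int = 8
    max_rejects: int = 64
    min_score: float = 40.0
    context_window: int = 5
    min_context_matches: int = 3
    n_workers: int = 1
    exhaustive_filter_check: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in [f.name for f in dataclasses.fields(self) if f.name.endswith(("_identity", "_coverage"))]:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0,100], got {v}")

    def thresholds(self, stage: str) -> Thresholds:
        return Thresholds(
            getattr(self, f"{stage}_identity"), getattr(self, f"{stage}_coverage")
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
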