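"""Deterministic synthetic pan-genomes with planted ground truth.

The generator emulates the structure every pipeline stage assumes: a few
species-level clades, each containing clonal genome groups (near-identical
copies of a founder), core protein families present once per genome at
conserved gene-order positions, accessory families present in a subset of
genomes, unique proteins found nowhere else, and paralog pairs — two
sequence-similar families planted at loci whose five-gene neighborhoods
share at most the focal position, so that sequence-only clustering merges
them and genomic-context refinement must separate them.

Core, paralog and accessory families descend from shared global ancestor
sequences, so homologous families recur across clades at a clade-level
divergence (default 80 % identity, i.e. cross-clade variants around 60 %)
that sits inside the global 50 %/70 % seed band but outside the in-clade
80 %/85 % band.  Mutations are substitution-only so that identity targets
are exact; an indel knob exists for robustness checks but is excluded from
exact-identity guarantees.

Small clades (below the abundant-clade genome minimum) are generated too:
their proteins enter the global stage directly, populating the extension
and leftover paths the way rare genomes do in real collections.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from .core import CodingRegion, Dataset, Genome, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_clades: int = 3
    genomes_per_clade: int = 12
    clonal_group_sizes: tuple[int, ...] = (2, 2)
    n_small_clades: int = 1
    genomes_per_small_clade: int = 3
    n_core_families: int = 20
    n_accessory_families: int = 8
    accessory_presence_prob: float = 0.5
    n_unique_per_genome: int = 2
    paralog_pairs: int = 2
    within_family_identity: tuple[float, float] = (95.0, 99.0)
    between_family_identity_ceiling: float = 30.0
    clade_identity: float = 80.0
    fast_core_fraction: float = 0.0
    fast_clade_identity: float = 68.0
    paralog_partner_identity: float = 94.0
    clonal_identity: float = 99.5
    mean_protein_length: int = 120
    genes_per_contig: int = 40
    contigs_per_genome: int = 1

    def validate(self) -> None:
        if any(
            n < 0
            for n in (
                self.n_clades,
                self.n_small_clades,
                self.n_core_families,
                self.n_accessory_families,
                self.n_unique_per_genome,
                self.paralog_pairs,
            )
        ):
            raise ValueError("counts must be non-negative")
        lo, hi = self.within_family_identity
        if not (0 < lo <= hi <= 100):
            raise ValueError("within_family_identity must be an increasing pair in (0,100]")
        if lo <= self.between_family_identity_ceiling:
            raise ValueError(
                "within-family identity floor must exceed the between-family ceiling"
            )
        if self.paralog_pairs and self.n_core_families < 4 * self.paralog_pairs + 4:
            raise ValueError(
                "n_core_families too small to separate the paralog loci; need "
                f">= {4 * self.paralog_pairs + 4}"
            )
        spare = sum(s - 1 for s in self.clonal_group_sizes)
        if any(s < 2 for s in self.clonal_group_sizes):
            raise ValueError("clonal group sizes must be >= 2")
        if self.genomes_per_clade - spare < len(self.clonal_group_sizes):
            raise ValueError("not enough genomes per clade for the clonal groups")
        genes = (
            self.n_core_families
            + 2 * self.paralog_pairs
            + self.n_accessory_families
            + self.n_unique_per_genome
        )
        if genes > self.genes_per_contig * self.contigs_per_genome:
            raise ValueError(
                f"{genes} genes per genome exceed genes_per_contig x contigs_per_genome"
            )
        if self.contigs_per_genome < 1:
            raise ValueError("contigs_per_genome must be >= 1")


@dataclass
class GroundTruth:
    protein_family: dict[str, str] = field(default_factory=dict)
    region_locus: dict[str, str] = field(default_factory=dict)
    genome_clonal_group: dict[str, str] = field(default_factory=dict)
    core_families: list[str] = field(default_factory=list)
    fast_core_families: list[str] = field(default_factory=list)
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    accessory_families: list[str] = field(default_factory=list)
    abundant_clades: list[str] = field(default_factory=list)
    small_clades: list[str] = field(default_factory=list)


@dataclass
class SimResult:
    dataset: Dataset
    truth: GroundTruth
    config: SimConfig


def mutate(
    sequence: str,
    target_identity_pct: float,
    seed: int | random.Random,
    n_indels: int = 0,
) -> str:
    """Substitution-only mutant with exact identity floor(target*len/100)/len.

    Positions are sampled without replacement and substituted with a
    different residue, so the trivially counted identity to the parent is
    exactly ``floor(target_identity_pct/100 * len) / len``.  ``n_indels``
    optionally deletes that many residues afterwards (which voids the exact
    identity guarantee; off by default).
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must be in (0, 100]")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    n = len(sequence)
    n_match = int(target_identity_pct / 100.0 * n)
    n_sub = n - n_match
    out = list(sequence)
    for pos in sorted(rng.sample(range(n), n_sub)):
        choices = [a for a in AA20 if a != sequence[pos]]
        out[pos] = rng.choice(choices)
    for _ in range(n_indels):
        if len(out) > 1:
            del out[rng.randrange(len(out))]
    return "".join(out)


def _make_patch(
    reference: str, target_identity_pct: float, rng: random.Random
) -> list[tuple[int, str]]:
    """Substitution patch (position, new residue) lowering identity to target."""
    n = len(reference)
    n_sub = n - int(target_identity_pct / 100.0 * n)
    patch = []
    for pos in sorted(rng.sample(range(n), n_sub)):
        patch.append((pos, rng.choice([a for a in AA20 if a != reference[pos]])))
    return patch


def _apply_patch(sequence: str, patch: list[tuple[int, str]]) -> str:
    out = list(sequence)
    for pos, res in patch:
        out[pos] = res
    return "".join(out)


def _random_seq(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


class _Builder:
    """Accumulates genomes/regions/proteins with sequence deduplication."""

    def __init__(self) -> None:
        self.genomes: list[Genome] = []
        self.regions: list[CodingRegion] = []
        self.seq_pid: dict[str, str] = {}
        self.protein_regions: dict[str, list[str]] = {}
        self.truth = GroundTruth()

    def protein_for(self, seq: str, family: str) -> str:
        pid = self.seq_pid.get(seq)
        if pid is None:
            pid = f"P{len(self.seq_pid):06d}"
            self.seq_pid[seq] = pid
            self.protein_regions[pid] = []
            self.truth.protein_family[pid] = family
        return pid

    def add_genome(
        self,
        genome_id: str,
        clade_id: str,
        genes: list[tuple[str, str, str]],  # (sequence, family, locus)
        contigs_per_genome: int,
        is_reference: bool = False,
    ) -> None:
        n = len(genes)
        per = -(-n // contigs_per_genome)  # ceil
        contig_ids = []
        idx = 0
        ci = 0
        while idx < n:
            chunk = genes[idx : idx + per]
            contig_id = f"{genome_id}.c{ci}"
            contig_ids.append(contig_id)
            for ordinal, (seq, family, locus) in enumerate(chunk):
                pid = self.protein_for(seq, family)
                rid = f"{contig_id}:{ordinal}"
                self.regions.append(
                    CodingRegion(rid, genome_id, contig_id, ordinal, "+", pid, True)
                )
                self.protein_regions[pid].append(rid)
                self.truth.region_locus[rid] = locus
            idx += per
            ci += 1
        self.genomes.append(
            Genome(
                genome_id=genome_id,
                clade_id=clade_id,
                is_annotated=True,
                is_reference_or_representative=is_reference,
                contigs=tuple(contig_ids),
            )
        )

    def dataset(self) -> Dataset:
        proteins = [
            ProteinRecord(pid, seq, regions=self.protein_regions[pid])
            for seq, pid in self.seq_pid.items()
        ]
        return Dataset(self.genomes, self.regions, proteins)


def generate(config: SimConfig = SimConfig()) -> SimResult:
    """Generate a toy pan-genome dataset; byte-reproducible for a fixed seed."""
    config.validate()
    rng = random.Random(config.seed)
    b = _Builder()

    # --- global ancestor families -------------------------------------
    def flen() -> int:
        return max(30, config.mean_protein_length + rng.randint(-10, 10))

    core_ids = [f"core{i:02d}" for i in range(config.n_core_families)]
    ancestors: dict[str, str] = {f: _random_seq(flen(), rng) for f in core_ids}
    pair_ids: list[tuple[str, str]] = []
    for j in range(config.paralog_pairs):
        fa, fb = f"par{j}a", f"par{j}b"
        ancestors[fa] = _random_seq(flen(), rng)
        ancestors[fb] = mutate(ancestors[fa], config.paralog_partner_identity, rng)
        pair_ids.append((fa, fb))
    acc_ids = [f"acc{i:02d}" for i in range(config.n_accessory_families)]
    for f in acc_ids:
        ancestors[f] = _random_seq(flen(), rng)

    n_fast = round(config.fast_core_fraction * config.n_core_families)
    fast_ids = set(core_ids[len(core_ids) - n_fast :]) if n_fast else set()
    b.truth.core_families = list(core_ids)
    b.truth.fast_core_families = sorted(fast_ids)
    b.truth.paralog_pairs = list(pair_ids)
    b.truth.accessory_families = list(acc_ids)

    # --- gene-order template: paralog loci planted with disjoint flanks
    after: dict[int, list[str]] = {}
    for j, (fa, fb) in enumerate(pair_ids):
        after.setdefault(2 * j + 1, []).append(fa)
        after.setdefault(config.n_core_families - 2 - 2 * j, []).append(fb)
    template: list[str] = []
    for i, f in enumerate(core_ids):
        template.append(f)
        template.extend(after.get(i, []))
    template.extend(acc_ids)

    clade_names = [f"clade{chr(ord('A') + i)}" for i in range(config.n_clades)] + [
        f"small{chr(ord('A') + i)}" for i in range(config.n_small_clades)
    ]
    b.truth.abundant_clades = clade_names[: config.n_clades]
    b.truth.small_clades = clade_names[config.n_clades :]

    lo, hi = config.within_family_identity
    for c_idx, clade in enumerate(clade_names):
        small = c_idx >= config.n_clades
        # clade founders: one patch per ancestor; paralog partners share the
        # patch of their 'a' member so the within-clade pair identity stays
        # at the planted partner divergence
        founders: dict[str, str] = {}
        for f in core_ids + acc_ids:
            divergence = (
                config.fast_clade_identity if f in fast_ids else config.clade_identity
            )
            founders[f] = _apply_patch(
                ancestors[f], _make_patch(ancestors[f], divergence, rng)
            )
        for fa, fb in pair_ids:
            patch = _make_patch(ancestors[fa], config.clade_identity, rng)
            founders[fa] = _apply_patch(ancestors[fa], patch)
            founders[fb] = _apply_patch(ancestors[fb], patch)

        if small:
            n_founder_genomes = config.genomes_per_small_clade
            group_sizes: tuple[int, ...] = ()
        else:
            n_founder_genomes = config.genomes_per_clade - sum(
                s - 1 for s in config.clonal_group_sizes
            )
            group_sizes = config.clonal_group_sizes

        acc_rank = {f: k for k, f in enumerate(acc_ids)}
        for g in range(n_founder_genomes):
            genome_id = f"{clade}g{g:02d}"
            # nested accessory gradient: a genome carries the first m genes of
            # the accessory block, so shared accessories always share their
            # upstream neighborhood (and gene frequencies fall off along the
            # block, core-to-rare)
            m_acc = sum(
                rng.random() < config.accessory_presence_prob for _ in acc_ids
            )
            genes: list[tuple[str, str, str]] = []
            for slot, f in enumerate(template):
                if f in acc_rank and acc_rank[f] >= m_acc:
                    continue
                variant = mutate(founders[f], rng.uniform(lo, hi), rng)
                genes.append((variant, f, f"{f}@{slot}"))
            for u in range(config.n_unique_per_genome):
                fam = f"uniq:{genome_id}:{u}"
                genes.append((_random_seq(flen(), rng), fam, f"{fam}@u{u}"))
            b.add_genome(
                genome_id, clade, genes, config.contigs_per_genome, is_reference=(g == 0)
            )
            b.truth.genome_clonal_group[genome_id] = genome_id
            # clonal copies of the first len(group_sizes) founder genomes
            if g < len(group_sizes):
                for c in range(1, group_sizes[g]):
                    copy_id = f"{genome_id}c{c}"
                    copy_genes = [
                        (mutate(seq, config.clonal_identity, rng), fam, locus)
                        for seq, fam, locus in genes
                    ]
                    b.add_genome(copy_id, clade, copy_genes, config.contigs_per_genome)
                    b.truth.genome_clonal_group[copy_id] = genome_id

    return SimResult(dataset=b.dataset(), truth=b.truth, config=config)
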