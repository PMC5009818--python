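"""Greedy incremental k-mer clustering and search.

A word index over representative sequences supports the three filtering
steps of the pipeline: near-identical collapse before in-clade clustering
(98 % identity / 100 % coverage), tight grouping before global clustering
(80 % / 85 %), and the liberal search that finds distant neighbors of the
seed clustroids (identity as low as 10 % at 70 % coverage).

Sequences are processed in decreasing length order (ties by id).  For each
query, candidate representatives are scanned by shared-word count
(descending); each candidate is verified by the built-in aligner against
the requested thresholds.  Scanning stops after ``max_accepts`` verified
acceptances (the best is taken) or ``max_rejects`` failed verifications —
the published parameterization uses maxaccepts 8 and maxrejects 64.  The
default word length is 5 (amino-acid alphabet); the published word length
16 remains available through the configuration, but shares almost no words
below ~95 % identity on protein sequences, so 5 is the practical default at
this scale.

The verifier clamps a requested identity threshold below 10 % up to 10 %,
so the liberal filter cannot accept arbitrarily weak hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import HitRecord, ProteinRecord, Thresholds, is_related
from .similarity import ScoringConfig, pair_hit

IDENTITY_FLOOR_PCT = 10.0


@dataclass(frozen=True)
class GreedyParams:
    word_length: int = 5
    max_accepts: int = 8
    max_rejects: int = 64
    thresholds: Thresholds = Thresholds(98.0, 100.0)

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word_length must be >= 1")
        if self.max_accepts < 1 or self.max_rejects < 1:
            raise ValueError("max_accepts and max_rejects must be >= 1")

    def effective_thresholds(self) -> Thresholds:
        """Thresholds with the identity floor applied."""
        if self.thresholds.min_identity_pct < IDENTITY_FLOOR_PCT:
            return Thresholds(IDENTITY_FLOOR_PCT, self.thresholds.min_coverage_pct)
        return self.thresholds


def sequence_words(seq: str, w: int) -> list[str]:
    """All overlapping words; a sequence shorter than w is its own word."""
    if len(seq) < w:
        return [seq]
    return [seq[i : i + w] for i in range(len(seq) - w + 1)]


class KmerIndex:
    """Word -> representative-id postings over indexed sequences."""

    def __init__(self, word_length: int = 5) -> None:
        if word_length < 1:
            raise ValueError("word_length must be >= 1")
        self.word_length = word_length
        self.postings: dict[str, list[str]] = {}
        self.sequences: dict[str, str] = {}

    def add(self, rep_id: str, seq: str) -> None:
        if rep_id in self.sequences:
            raise ValueError(f"representative {rep_id} already indexed")
        self.sequences[rep_id] = seq
        for word in set(sequence_words(seq, self.word_length)):
            self.postings.setdefault(word, []).append(rep_id)

    def candidates(self, seq: str) -> list[tuple[str, int]]:
        """(rep_id, shared distinct word count), by count desc then id."""
        counts: dict[str, int] = {}
        for word in set(sequence_words(seq, self.word_length)):
            for rep in self.postings.get(word, ()):
                counts[rep] = counts.get(rep, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def search(
    query_id: str,
    query_seq: str,
    index: KmerIndex,
    p: GreedyParams,
    scoring: ScoringConfig = ScoringConfig(),
) -> list[tuple[str, HitRecord]]:
    """Verified hits of a query against the index, up to max_accepts.

    Candidates are scanned in shared-word-count order; each is verified by
    alignment against the (floor-clamped) thresholds.  Scanning stops after
    ``max_accepts`` acceptances or ``max_rejects`` rejections.  An empty
    list is a valid result.
    """
    t = p.effective_thresholds()
    accepted: list[tuple[str, HitRecord]] = []
    rejects = 0
    for rep_id, _count in index.candidates(query_seq):
        if rep_id == query_id:
            continue
        hit = pair_hit(query_id, query_seq, rep_id, index.sequences[rep_id], scoring)
        if hit is not None and is_related(hit, t):
            accepted.append((rep_id, hit))
            if len(accepted) >= p.max_accepts:
                break
        else:
            rejects += 1
            if rejects >= p.max_rejects:
                break
    return accepted


@dataclass
class GreedyResult:
    representatives: list[str]  # in creation order
    assignment: dict[str, str]  # member -> representative (reps map to self)
    hits: dict[str, HitRecord] = field(default_factory=dict)  # member -> verifying hit


def greedy_cluster(
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
    p: GreedyParams,
    scoring: ScoringConfig = ScoringConfig(),
) -> GreedyResult:
    """Greedy incremental clustering in decreasing length order.

    Each sequence joins the best verified representative among up to
    ``max_accepts`` acceptances (best by identity; ties by more shared
    words, then lexicographic id), or becomes a new representative after
    ``max_rejects`` failed verifications or candidate exhaustion.
    """
    if isinstance(proteins, Mapping):
        seqs = dict(proteins)
    else:
        seqs = {pr.protein_id: pr.sequence for pr in proteins}
    if not seqs:
        raise ValueError("non-empty input required")
    order = sorted(seqs, key=lambda pid: (-len(seqs[pid]), pid))
    t = p.effective_thresholds()
    index = KmerIndex(p.word_length)
    result = GreedyResult(representatives=[], assignment={})
    for pid in order:
        seq = seqs[pid]
        accepted: list[tuple[str, HitRecord, int]] = []
        rejects = 0
        for rep_id, count in index.candidates(seq):
            hit = pair_hit(pid, seq, rep_id, index.sequences[rep_id], scoring)
            if hit is not None and is_related(hit, t):
                accepted.append((rep_id, hit, count))
                if len(accepted) >= p.max_accepts:
                    break
            else:
                rejects += 1
                if rejects >= p.max_rejects:
                    break
        if accepted:
            rep_id, hit, _ = min(
                accepted, key=lambda a: (-a[1].identity_pct, -a[2], a[0])
            )
            result.assignment[pid] = rep_id
            result.hits[pid] = hit
        else:
            index.add(pid, seq)
            result.representatives.append(pid)
            result.assignment[pid] = pid
    return result


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_dropped: int
    loss_pct: float | None = None  # vs exhaustive check, when requested
    hits: dict[str, list[tuple[str, HitRecord]]] = field(default_factory=dict)

    @property
    def retained_pct(self) -> float:
        return 100.0 * self.n_retained / self.n_input if self.n_input else 0.0


def filter_seed_neighbors(
    candidates: Mapping[str, str],
    seed_clustroids: Mapping[str, str],
    p: GreedyParams,
    scoring: ScoringConfig = ScoringConfig(),
    exhaustive_check: bool = False,
) -> tuple[list[str], FilterReport]:
    """Keep the candidates with at least one verified hit to a clustroid.

    With ``exhaustive_check`` the dropped candidates are re-examined by
    brute-force alignment against every clustroid, and the fraction of
    true neighbors lost by the word-count scan order is reported.
    """
    if not seed_clustroids:
        raise ValueError("seed clustroids must be non-empty")
    index = KmerIndex(p.word_length)
    for cid in sorted(seed_clustroids):
        index.add(cid, seed_clustroids[cid])
    retained: list[str] = []
    report = FilterReport(n_input=len(candidates), n_retained=0, n_dropped=0)
    dropped: list[str] = []
    for pid in sorted(candidates):
        found = search(pid, candidates[pid], index, p, scoring)
        if found:
            retained.append(pid)
            report.hits[pid] = found
        else:
            dropped.append(pid)
    report.n_retained = len(retained)
    report.n_dropped = len(dropped)
    if exhaustive_check:
        t = p.effective_thresholds()
        lost = 0
        for pid in dropped:
            for cid in sorted(seed_clustroids):
                hit = pair_hit(pid, candidates[pid], cid, seed_clustroids[cid], scoring)
                if hit is not None and is_related(hit, t):
                    lost += 1
                    break
        true_total = report.n_retained + lost
        report.loss_pct = 100.0 * lost / true_total if true_total else 0.0
    return retained, report
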