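"""Pairwise protein similarity: built-in alignment and HSP aggregation.

Relatedness everywhere in the pipeline is decided from *aggregated* pairwise
hits: a pair of sequences may align in several local blocks (HSPs), and the
per-pair identity and coverage are computed over the retained blocks after
overlap pruning.  Hits come from one of two sources:

* the built-in aligner (:func:`align_pair`), a BLOSUM62 local alignment with
  affine gaps via :class:`Bio.Align.PairwiseAligner` — suitable for the
  desk-scale datasets this package targets; or
* an external 12-column tabular hit file (one row per HSP) read by
  :mod:`protoclust.io` and aggregated here.

The built-in aligner gates hits with a raw-score floor instead of an
E-value, since database-size E-value statistics are meaningless for small
in-memory sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core import HitRecord, ProteinRecord, Thresholds, edge_key, is_related


@dataclass(frozen=True)
class RawHSP:
    """One local alignment block, 1-based inclusive coordinates."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_identities: int
    n_columns: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")
        if self.n_identities > self.n_columns:
            raise ValueError("n_identities > n_columns")


@dataclass(frozen=True)
class ScoringConfig:
    """Built-in aligner settings.

    ``min_score`` is the raw-score floor standing in for the external
    aligner's E-value gate; alignments scoring below it yield no HSP.
    ``use_positives`` counts positive-scoring substitutions as matches when
    computing identity (off by default: "similarity" is percent identity).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_score: float = 40.0
    use_positives: bool = False
    overlap_prune_fraction: float = 0.5


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(cfg: ScoringConfig) -> Align.PairwiseAligner:
    key = (cfg.matrix_name, cfg.gap_open, cfg.gap_extend)
    al = _ALIGNER_CACHE.get(key)
    if al is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load(cfg.matrix_name)
        al.open_gap_score = cfg.gap_open
        al.extend_gap_score = cfg.gap_extend
        _ALIGNER_CACHE[key] = al
    return al


def align_pair(
    seq_a: str,
    seq_b: str,
    cfg: ScoringConfig = ScoringConfig(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[RawHSP]:
    """Best local alignment of two sequences as a (possibly empty) HSP list.

    Deterministic for fixed inputs and config (the aligner's traceback
    preference order is fixed).  Returns ``[]`` when the best local score is
    below ``cfg.min_score``.  Identities are exact residue matches unless
    ``cfg.use_positives`` is set.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _aligner(cfg)
    matrix = aligner.substitution_matrix
    alphabet = set(str(matrix.alphabet))
    bad = (set(seq_a) | set(seq_b)) - alphabet
    if bad:
        raise ValueError(f"residues outside scoring alphabet: {sorted(bad)}")

    if aligner.score(seq_a, seq_b) < cfg.min_score:
        return []
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q) == 0:
        return []
    n_id = 0
    n_pos = 0
    n_aligned = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for i in range(qe - qs):
            ra, rb = seq_a[qs + i], seq_b[ss + i]
            n_aligned += 1
            if ra == rb:
                n_id += 1
            if matrix[ra, rb] > 0:
                n_pos += 1
    # internal gap columns count toward alignment length, BLAST-style
    gap_cols = 0
    for k in range(1, len(blocks_q)):
        gap_cols += (blocks_q[k][0] - blocks_q[k - 1][1]) + (
            blocks_s[k][0] - blocks_s[k - 1][1]
        )
    n_columns = n_aligned + gap_cols
    matches = n_pos if cfg.use_positives else n_id
    return [
        RawHSP(
            query_id=query_id,
            subject_id=subject_id,
            q_start=int(blocks_q[0][0]) + 1,
            q_end=int(blocks_q[-1][1]),
            s_start=int(blocks_s[0][0]) + 1,
            s_end=int(blocks_s[-1][1]),
            n_identities=matches,
            n_columns=n_columns,
            score=float(aln.score),
        )
    ]


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = 0
    for a, b in sorted(intervals):
        if b <= end:
            continue
        total += b - max(a - 1, end)
        end = b
    return total


def _overlap_with_union(span: tuple[int, int], accepted: list[tuple[int, int]]) -> int:
    a, b = span
    covered = 0
    pos = a
    for x, y in sorted(accepted):
        if y < pos:
            continue
        if x > b:
            break
        covered += min(y, b) - max(x, pos) + 1
        pos = min(y, b) + 1
        if pos > b:
            break
    return covered


def aggregate_hsps(
    hsps: Sequence[RawHSP],
    len_q: int,
    len_s: int,
    overlap_prune_fraction: float = 0.5,
) -> HitRecord:
    """Collapse the HSPs of one ordered (query, subject) pair into a hit.

    HSPs are taken in decreasing score order (ties: more identities, then
    smaller query start); an HSP is discarded when more than
    ``overlap_prune_fraction`` of its query OR subject span is already
    covered by accepted HSPs.  Coverage is the union of accepted spans over
    each sequence length; identity is pooled over accepted HSPs.
    """
    if not hsps:
        raise ValueError("no hits")
    if len_q <= 0 or len_s <= 0:
        raise ValueError("sequence lengths must be positive")
    q, s = hsps[0].query_id, hsps[0].subject_id
    for h in hsps:
        if (h.query_id, h.subject_id) != (q, s):
            raise ValueError("HSPs must share one ordered (query, subject) pair")
    order = sorted(hsps, key=lambda h: (-h.score, -h.n_identities, h.q_start))
    acc_q: list[tuple[int, int]] = []
    acc_s: list[tuple[int, int]] = []
    sum_id = 0
    sum_cols = 0
    for h in order:
        q_span = (h.q_start, h.q_end)
        s_span = (h.s_start, h.s_end) if h.s_start <= h.s_end else (h.s_end, h.s_start)
        q_len = q_span[1] - q_span[0] + 1
        s_len = s_span[1] - s_span[0] + 1
        if acc_q and (
            _overlap_with_union(q_span, acc_q) > overlap_prune_fraction * q_len
            or _overlap_with_union(s_span, acc_s) > overlap_prune_fraction * s_len
        ):
            continue
        acc_q.append(q_span)
        acc_s.append(s_span)
        sum_id += h.n_identities
        sum_cols += h.n_columns
    cov_q = 100.0 * _interval_union_length([(a, b) for a, b in acc_q]) / len_q
    cov_s = 100.0 * _interval_union_length([(a, b) for a, b in acc_s]) / len_s
    identity = 100.0 * sum_id / sum_cols if sum_cols else 0.0
    return HitRecord(q, s, identity, min(cov_q, 100.0), min(cov_s, 100.0))


def pair_hit(
    id_a: str,
    seq_a: str,
    id_b: str,
    seq_b: str,
    cfg: ScoringConfig = ScoringConfig(),
) -> HitRecord | None:
    """Aggregated built-in hit for one pair, or None below the score floor."""
    hsps = align_pair(seq_a, seq_b, cfg, query_id=id_a, subject_id=id_b)
    if not hsps:
        return None
    return aggregate_hsps(hsps, len(seq_a), len(seq_b), cfg.overlap_prune_fraction)


def _shares_word(seq_a: str, seq_b: str, w: int) -> bool:
    if len(seq_a) < w or len(seq_b) < w:
        return True  # too short to prescreen; always verify
    words = {seq_a[i : i + w] for i in range(len(seq_a) - w + 1)}
    return any(seq_b[i : i + w] in words for i in range(len(seq_b) - w + 1))


def all_vs_all(
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
    t: Thresholds,
    cfg: ScoringConfig = ScoringConfig(),
    prescreen_word: int | None = 4,
) -> dict[tuple[str, str], HitRecord]:
    """Related unordered pairs among the given proteins, via built-in alignment.

    Returns a map from the canonical unordered pair key to the aggregated
    hit, containing exactly the pairs related under ``t``; self-pairs
    excluded.  The edge set is invariant under input order.

    ``prescreen_word`` skips alignment of pairs sharing no word of that
    length — a pure speed shortcut that cannot drop pairs at the identity
    levels the pipeline's thresholds use; pass ``None`` to disable.
    """
    if isinstance(proteins, Mapping):
        seqs = dict(proteins)
    else:
        seqs = {p.protein_id: p.sequence for p in proteins}
    if not seqs:
        raise ValueError("at least one protein required")
    ids = sorted(seqs)
    edges: dict[tuple[str, str], HitRecord] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if prescreen_word is not None and not _shares_word(
                seqs[a], seqs[b], prescreen_word
            ):
                continue
            hit = pair_hit(a, seqs[a], b, seqs[b], cfg)
            if hit is not None and is_related(hit, t):
                edges[edge_key(a, b)] = hit
    return edges
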