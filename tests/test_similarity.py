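import random

import pytest

from oracles import sw_affine
from protoclust.core import Thresholds, edge_key
from protoclust.similarity import (
    RawHSP,
    ScoringConfig,
    aggregate_hsps,
    align_pair,
    all_vs_all,
    pair_hit,
)
from protoclust.simulate import mutate

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n=100):
    return "".join(rng.choice(AA) for _ in range(n))


class TestAggregateHsps:
    def test_single_hsp_is_identity(self):
        h = RawHSP("q", "s", 1, 100, 1, 100, 80, 100, score=50)
        hit = aggregate_hsps([h], 100, 120)
        assert hit.identity_pct == pytest.approx(80.0)
        assert hit.coverage_query_pct == pytest.approx(100.0)
        assert hit.coverage_subject_pct == pytest.approx(100 * 100 / 120)

    def test_disjoint_hsps_are_additive(self):
        hsps = [
            RawHSP("q", "s", 1, 50, 1, 50, 40, 50, score=30),
            RawHSP("q", "s", 51, 100, 51, 100, 40, 50, score=30),
        ]
        hit = aggregate_hsps(hsps, 100, 100)
        assert hit.identity_pct == pytest.approx(80.0)
        assert hit.coverage_query_pct == pytest.approx(100.0)

    def test_overlapping_hsps_match_bruteforce_union(self):
        # oracle: explicit per-position union + greedy pruning by score
        hsps = [
            RawHSP("q", "s", 1, 60, 1, 60, 55, 60, score=100),
            RawHSP("q", "s", 41, 100, 41, 100, 50, 60, score=80),
        ]
        hit = aggregate_hsps(hsps, 100, 100)
        # second HSP overlaps 20/60 = 33% of its span: retained
        covered = set()
        for h in sorted(hsps, key=lambda h: -h.score):
            span = set(range(h.q_start, h.q_end + 1))
            if len(span & covered) <= 0.5 * len(span):
                covered |= span
        assert hit.coverage_query_pct == pytest.approx(100.0 * len(covered) / 100)
        assert hit.identity_pct == pytest.approx(100.0 * (55 + 50) / (60 + 60))

    def test_mostly_overlapping_hsp_is_pruned(self):
        hsps = [
            RawHSP("q", "s", 1, 60, 1, 60, 60, 60, score=100),
            RawHSP("q", "s", 10, 55, 10, 55, 30, 46, score=20),  # 100% overlap
        ]
        hit = aggregate_hsps(hsps, 100, 100)
        assert hit.identity_pct == pytest.approx(100.0)
        assert hit.coverage_query_pct == pytest.approx(60.0)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError, match="no hits"):
            aggregate_hsps([], 100, 100)

    def test_mixed_pairs_rejected(self):
        hsps = [
            RawHSP("q", "s", 1, 10, 1, 10, 10, 10),
            RawHSP("q", "z", 1, 10, 1, 10, 10, 10),
        ]
        with pytest.raises(ValueError, match="pair"):
            aggregate_hsps(hsps, 100, 100)


class TestAlignPair:
    def test_self_alignment_is_full_identity(self):
        rng = random.Random(0)
        s = _random_seq(rng)
        (h,) = align_pair(s, s)
        assert h.n_identities == len(s)
        assert (h.q_start, h.q_end) == (1, len(s))

    def test_two_substitutions_hand_countable(self):
        a = "ACDEFGHIKLMNPQRSTVWY" * 2
        b = list(a)
        b[5], b[25] = "W", "C"
        (h,) = align_pair(a, "".join(b))
        assert h.n_columns == 40
        assert h.n_identities == 38

    def test_below_score_floor_yields_no_hsp(self):
        rng = random.Random(1)
        assert align_pair(_random_seq(rng, 50), _random_seq(rng, 50)) == []

    def test_alphabet_violation(self):
        with pytest.raises(ValueError, match="alphabet"):
            align_pair("MK1", "MKL")

    def test_indel_pair_matches_dp_oracle(self):
        # a clean 5-residue deletion: the optimum is unique, so the built-in
        # aligner and the independent quadratic DP must agree exactly
        rng = random.Random(7)
        a = _random_seq(rng, 80)
        b = a[:40] + a[45:]
        (h,) = align_pair(a, b)
        score, pairs = sw_affine(a, b)
        assert h.score == pytest.approx(score)
        n_id = sum(1 for i, j in pairs if a[i] == b[j])
        assert h.n_identities == n_id
        q_span = (pairs[0][0] + 1, pairs[-1][0] + 1)
        assert (h.q_start, h.q_end) == q_span
        hit = aggregate_hsps([h], len(a), len(b))
        assert hit.coverage_query_pct == pytest.approx(
            100.0 * (q_span[1] - q_span[0] + 1) / len(a)
        )

    @pytest.mark.parametrize("target", [95.0, 80.0, 60.0])
    def test_substitution_mutants_identity_tracks_target(self, target):
        rng = random.Random(11)
        a = _random_seq(rng, 120)
        b = mutate(a, target, 3)
        (h,) = align_pair(a, b)
        hit = aggregate_hsps([h], len(a), len(b))
        # local alignment may trim low-identity ends, never report less
        assert hit.identity_pct >= target - 1.0


class TestAllVsAll:
    def test_identical_triple(self):
        seqs = {f"p{i}": "MKLVWYACDEFGHIKLMNPQRSTVWY" * 3 for i in range(3)}
        edges = all_vs_all(seqs, Thresholds(80, 85))
        assert len(edges) == 3
        assert all(h.identity_pct == pytest.approx(100.0) for h in edges.values())

    def test_unrelated_pair_no_edges(self):
        rng = random.Random(2)
        seqs = {"a": _random_seq(rng), "b": _random_seq(rng)}
        assert all_vs_all(seqs, Thresholds(80, 85)) == {}

    def test_family_matches_bruteforce_and_order_invariant(self):
        rng = random.Random(5)
        root = _random_seq(rng, 90)
        seqs = {f"m{i:02d}": mutate(root, rng.uniform(75, 99), rng.randrange(10**6))
                for i in range(12)}
        t = Thresholds(80, 85)
        edges = all_vs_all(seqs, t)
        # brute force over all pairs, no prescreen
        ids = sorted(seqs)
        expected = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                hit = pair_hit(a, seqs[a], b, seqs[b])
                if hit is not None and hit.identity_pct >= 80 and min(
                    hit.coverage_query_pct, hit.coverage_subject_pct
                ) >= 85:
                    expected[edge_key(a, b)] = hit
        assert set(edges) == set(expected)
        shuffled = dict(sorted(seqs.items(), key=lambda kv: kv[0], reverse=True))
        assert set(all_vs_all(shuffled, t)) == set(edges)

    def test_unknown_empty_input_is_error(self):
        with pytest.raises(ValueError):
            all_vs_all({}, Thresholds(80, 85))


def test_positives_mode_counts_positive_substitutions():
    a = "MKLVWYACDEFGHIKLMNPQRS"
    b = a.replace("L", "I")  # L->I scores positive in BLOSUM62
    hit_id = pair_hit("a", a, "b", b, ScoringConfig())
    hit_pos = pair_hit("a", a, "b", b, ScoringConfig(use_positives=True))
    assert hit_pos.identity_pct > hit_id.identity_pct
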