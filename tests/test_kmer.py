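import random

import pytest

from protoclust.core import Thresholds, is_related
from protoclust.kmer import (
    GreedyParams,
    KmerIndex,
    filter_seed_neighbors,
    greedy_cluster,
    search,
    sequence_words,
)
from protoclust.similarity import pair_hit
from protoclust.simulate import mutate

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n=100):
    return "".join(rng.choice(AA) for _ in range(n))


def _families(rng, n_fam=5, per_fam=10, spread=(96.0, 99.5)):
    seqs = {}
    fam_of = {}
    for f in range(n_fam):
        root = _random_seq(rng, 100 + 5 * f)
        for m in range(per_fam):
            pid = f"f{f}m{m}"
            seqs[pid] = mutate(root, rng.uniform(*spread), rng.randrange(10**6))
            fam_of[pid] = f
    return seqs, fam_of


def test_short_sequence_indexed_as_whole_word():
    assert sequence_words("MK", 5) == ["MK"]
    idx = KmerIndex(5)
    idx.add("short", "MK")
    assert idx.candidates("MK") == [("short", 1)]


def test_greedy_identical_sequences_one_representative():
    seqs = {f"p{i}": "MKLVWYACDEFGHIKLMNPQRSTVWY" * 4 for i in range(5)}
    res = greedy_cluster(seqs, GreedyParams(thresholds=Thresholds(98, 100)))
    assert len(res.representatives) == 1
    assert set(res.assignment) == set(seqs)
    assert len(set(res.assignment.values())) == 1


def test_greedy_no_shared_words_all_representatives():
    rng = random.Random(0)
    seqs = {"a": _random_seq(rng), "b": _random_seq(rng)}
    res = greedy_cluster(seqs, GreedyParams(thresholds=Thresholds(98, 100)))
    assert sorted(res.representatives) == ["a", "b"]


def test_greedy_families_verified_and_pure():
    """Every accepted assignment re-verifies; no cross-family assignment."""
    rng = random.Random(42)
    seqs, fam_of = _families(rng)
    params = GreedyParams(thresholds=Thresholds(93, 90))
    res = greedy_cluster(seqs, params)
    for pid, rep in res.assignment.items():
        assert fam_of[pid] == fam_of[rep]
        if pid != rep:
            hit = pair_hit(pid, seqs[pid], rep, seqs[rep])
            assert hit is not None and is_related(hit, params.thresholds)
    # rerun: prefix-stable / deterministic
    res2 = greedy_cluster(seqs, params)
    assert res2.assignment == res.assignment
    assert res2.representatives == res.representatives


def test_search_exact_and_empty():
    rng = random.Random(3)
    idx = KmerIndex(5)
    target = _random_seq(rng)
    idx.add("t", target)
    params = GreedyParams(thresholds=Thresholds(98, 100))
    hits = search("q", target, idx, params)
    assert hits and hits[0][0] == "t"
    assert hits[0][1].identity_pct == pytest.approx(100.0)
    assert search("q", _random_seq(rng), idx, params) == []


def test_search_recall_vs_exhaustive_oracle():
    """Word-count candidate scan finds nearly all true neighbors >=50% identity."""
    rng = random.Random(9)
    reps = {f"r{i}": _random_seq(rng, 110) for i in range(20)}
    idx = KmerIndex(5)
    for rid in sorted(reps):
        idx.add(rid, reps[rid])
    params = GreedyParams(thresholds=Thresholds(10, 70))
    n_true = n_found = 0
    for i in range(40):
        rid = f"r{i % 20}"
        q = mutate(reps[rid], rng.uniform(50, 95), rng.randrange(10**6))
        true_hits = set()
        for cand in reps:
            hit = pair_hit("q", q, cand, reps[cand])
            if hit is not None and is_related(hit, params.thresholds) \
                    and hit.identity_pct >= 50:
                true_hits.add(cand)
        found = {r for r, _ in search("q", q, idx, params)}
        n_true += len(true_hits)
        n_found += len(true_hits & found)
    assert n_true > 0
    assert n_found / n_true >= 0.95


def test_identity_floor_clamps_liberal_threshold():
    params = GreedyParams(thresholds=Thresholds(0, 70))
    assert params.effective_thresholds().min_identity_pct == 10.0


class TestFilterSeedNeighbors:
    def test_identical_candidate_retained_random_dropped(self):
        rng = random.Random(4)
        clustroids = {f"c{i}": _random_seq(rng, 100) for i in range(5)}
        candidates = {"same": clustroids["c0"], "junk": _random_seq(rng, 100)}
        retained, report = filter_seed_neighbors(
            candidates, clustroids, GreedyParams(thresholds=Thresholds(10, 70))
        )
        assert retained == ["same"]
        assert report.n_dropped == 1

    def test_lowering_identity_never_shrinks_retained_set(self):
        rng = random.Random(8)
        clustroids = {f"c{i}": _random_seq(rng, 100) for i in range(4)}
        candidates = {
            f"q{i}": mutate(clustroids[f"c{i % 4}"], rng.uniform(30, 90),
                            rng.randrange(10**6))
            for i in range(12)
        }
        previous: set[str] = set()
        for ident in (80, 50, 30, 10):
            retained, _ = filter_seed_neighbors(
                candidates, clustroids,
                GreedyParams(thresholds=Thresholds(ident, 70)),
            )
            assert previous <= set(retained)
            previous = set(retained)

    def test_empty_seed_set_is_error(self):
        with pytest.raises(ValueError):
            filter_seed_neighbors({"a": "MKL"}, {}, GreedyParams())

    def test_exhaustive_check_reports_loss(self):
        rng = random.Random(12)
        clustroids = {f"c{i}": _random_seq(rng, 100) for i in range(3)}
        candidates = {"hit": mutate(clustroids["c1"], 80, 5),
                      "miss": _random_seq(rng, 100)}
        _, report = filter_seed_neighbors(
            candidates, clustroids,
            GreedyParams(thresholds=Thresholds(10, 70)), exhaustive_check=True,
        )
        assert report.loss_pct == pytest.approx(0.0)
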