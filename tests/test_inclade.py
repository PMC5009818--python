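import random

import pytest

from oracles import weighted_medoid
from protoclust.core import CodingRegion, Dataset, Genome, ProteinRecord
from protoclust.inclade import (
    abundant_clades,
    build_context_vectors,
    cluster_clade,
    context_consistent,
    context_refine,
    flag_conservative,
    select_clustroid,
)


def _linear_dataset(protein_ids, strands=None, n_genomes=1):
    """One contig per genome carrying the given proteins in order."""
    genomes, regions, proteins = [], [], {}
    for g in range(n_genomes):
        gid = f"g{g}"
        contig = f"{gid}.c0"
        genomes.append(Genome(gid, "cl", contigs=(contig,)))
        for i, pid in enumerate(protein_ids):
            rid = f"{contig}:{i}"
            strand = (strands or ["+"] * len(protein_ids))[i]
            regions.append(CodingRegion(rid, gid, contig, i, strand, f"{pid}@{gid}"))
            proteins[f"{pid}@{gid}"] = ProteinRecord(
                f"{pid}@{gid}", "M" + "ACDEFGHIKL"[i % 10] * (g + i + 2), [rid]
            )
    return Dataset(genomes, regions, list(proteins.values()))


class TestContextVectors:
    def test_window_centered_and_end_padded(self):
        ds = _linear_dataset(["a", "b", "c", "d", "e"])
        clus = {f"{p}@g0": p.upper() for p in "abcde"}
        v = build_context_vectors(ds, clus)
        assert v["g0.c0:2"] == ("A", "B", "C", "D", "E")
        assert v["g0.c0:0"] == (None, None, "A", "B", "C")
        assert v["g0.c0:4"] == ("C", "D", "E", None, None)

    def test_minus_strand_window_reversed(self):
        ds = _linear_dataset(["a", "b", "c", "d", "e"], strands=["+", "+", "-", "+", "+"])
        clus = {f"{p}@g0": p.upper() for p in "abcde"}
        v = build_context_vectors(ds, clus)
        assert v["g0.c0:2"] == ("E", "D", "C", "B", "A")

    def test_unclustered_neighbor_is_absent_marker(self):
        ds = _linear_dataset(["a", "b", "c"])
        clus = {"a@g0": "A", "c@g0": "C"}  # b has no cluster
        v = build_context_vectors(ds, clus)
        assert v["a@g0" and "g0.c0:0"] == (None, None, "A", None, "C")
        assert "g0.c0:1" not in v


class TestContextConsistent:
    def test_three_of_five_rule(self):
        a = ("X", "Y", "C", "Z", "W")
        assert context_consistent(a, a)
        assert context_consistent(a, ("X", "Y", "C", "Q", "Q"))
        assert not context_consistent(a, ("X", "Q", "C", "Q", "Q"))

    def test_absent_positions_never_match(self):
        a = (None, None, "C", "Z", "W")
        b = (None, None, "C", "Z", "W")
        assert context_consistent(a, b)  # 3 present matching slots pass
        assert not context_consistent((None, None, "C", "Z", None), b)


class TestContextRefine:
    def test_shared_neighborhood_single_subcluster(self):
        vectors = {
            "r1": ("A", "B", "C", "D", "E"),
            "r2": ("A", "B", "C", "D", "E"),
            "r3": ("A", "B", "C", "Q", "E"),
        }
        regions = {"p1": ["r1"], "p2": ["r2"], "p3": ["r3"]}
        subs = context_refine({"p1", "p2", "p3"}, regions, vectors)
        assert subs == [{"p1", "p2", "p3"}]

    def test_disjoint_neighborhoods_split(self):
        vectors = {
            "r1": ("A", "B", "C", "D", "E"),
            "r2": ("V", "W", "C", "Y", "Z"),
        }
        regions = {"p1": ["r1"], "p2": ["r2"]}
        assert context_refine({"p1", "p2"}, regions, vectors) == [{"p1"}, {"p2"}]

    def test_protein_follows_plurality_of_its_regions(self):
        vectors = {
            "r1": ("A", "B", "C", "D", "E"),
            "r2": ("A", "B", "C", "D", "E"),
            "r3": ("V", "W", "C", "Y", "Z"),
            "s1": ("A", "B", "C", "D", "E"),
            "s2": ("V", "W", "C", "Y", "Z"),
        }
        regions = {"p": ["r1", "r2", "r3"], "q1": ["s1"], "q2": ["s2"]}
        subs = context_refine({"p", "q1", "q2"}, regions, vectors)
        assert {"p", "q1"} in subs and {"q2"} in subs

    def test_missing_vector_is_error(self):
        with pytest.raises(ValueError, match="context vector"):
            context_refine({"p"}, {"p": ["r1"]}, {})


class TestSelectClustroid:
    def test_singleton(self):
        assert select_clustroid(["only"], {}, lambda a, b: 0.0) == "only"

    def test_central_member_wins(self):
        d = {("a", "b"): 0.1, ("a", "c"): 0.1, ("b", "c"): 0.2}

        def dist(x, y):
            return d[tuple(sorted((x, y)))]

        assert select_clustroid(["a", "b", "c"], {}, dist) == "a"

    def test_score_tie_broken_by_own_weight_then_id(self):
        # two members always score identically (the other's weight cancels)
        dist = lambda a, b: 0.2
        assert select_clustroid(["a", "b"], {"a": 1, "b": 5}, dist) == "b"
        assert select_clustroid(["a", "b"], {"a": 3, "b": 3}, dist) == "a"

    def test_matches_bruteforce_on_random_instances(self):
        rng = random.Random(17)
        for _ in range(40):
            n = rng.randint(2, 8)
            members = [f"m{i}" for i in range(n)]
            d = {}
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    d[(a, b)] = rng.uniform(0, 1.4)  # some above the cap
            weights = {m: rng.randint(1, 9) for m in members}

            def dist(x, y):
                return d[tuple(sorted((x, y)))]

            assert select_clustroid(members, weights, dist) == \
                weighted_medoid(members, weights, dist)

    def test_empty_cluster_error(self):
        with pytest.raises(ValueError):
            select_clustroid([], {}, lambda a, b: 0.0)


class TestConservativeAndAbundance:
    def test_full_presence_is_conservative(self):
        pg = {f"p{i}": {f"g{i}"} for i in range(12)}
        reps = [f"g{i}" for i in range(12)]
        assert flag_conservative(pg.keys(), pg, reps)

    def test_single_genome_is_not(self):
        assert not flag_conservative(["p"], {"p": {"g0"}}, [f"g{i}" for i in range(12)])

    def test_eleven_of_twelve_passes_default_fraction(self):
        pg = {f"p{i}": {f"g{i}"} for i in range(11)}
        reps = [f"g{i}" for i in range(12)]
        assert flag_conservative(pg.keys(), pg, reps)  # 11/12 = 0.917 >= 0.9

    def test_abundant_clades_threshold(self):
        counts = {"a": 10, "b": 9, "c": 25}
        assert abundant_clades(counts) == ["a", "c"]
        assert abundant_clades({}) == []


class TestClusterCladeOnSimulation:
    def test_inclade_clusters_are_pure_and_complete(self, sim, pipeline_result):
        """Final in-clade clusters match planted families exactly: no cluster
        mixes families, no family splits across clusters."""
        fam = sim.truth.protein_family
        for clade, res in pipeline_result.inclade.items():
            cluster_fams = {}
            fams_clusters = {}
            for pid, cid in res.assignment.items():
                cluster_fams.setdefault(cid, set()).add(fam[pid])
                fams_clusters.setdefault(fam[pid], set()).add(cid)
            assert all(len(f) == 1 for f in cluster_fams.values())
            for f, cids in fams_clusters.items():
                if not f.startswith("uniq"):
                    assert len(cids) == 1, (f, cids)

    def test_paralog_pairs_merged_by_sequence_split_by_context(self, sim, pipeline_result):
        fam = sim.truth.protein_family
        for clade, res in pipeline_result.inclade.items():
            n_pairs = 0
            for fa, fb in sim.truth.paralog_pairs:
                ca = {c.cluster_id for c in res.clusters
                      if any(fam[p] == fa for p in c.members)}
                cb = {c.cluster_id for c in res.clusters
                      if any(fam[p] == fb for p in c.members)}
                assert ca and cb and ca.isdisjoint(cb)
                n_pairs += 1
            assert n_pairs == len(sim.truth.paralog_pairs)
            # context refinement actually did the splitting
            assert res.report["n_clusters"] > res.report["n_sequence_clusters"]

    def test_core_clusters_conservative_unique_not(self, sim, pipeline_result):
        fam = sim.truth.protein_family
        for clade, res in pipeline_result.inclade.items():
            for c in res.clusters:
                families = {fam[p] for p in c.members}
                (family,) = families
                if family in sim.truth.core_families:
                    assert c.is_conservative
                if family.startswith("uniq"):
                    assert not c.is_conservative
                assert c.clustroid_id in c.members

    def test_compression_exceeds_fivefold(self, pipeline_result):
        for res in pipeline_result.inclade.values():
            assert res.report["compression_ratio"] > 5.0
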