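import random

import pytest

from conftest import random_edge_instance
from oracles import naive_agglomerate
from protoclust.core import HitRecord, Thresholds, check_partition, edge_key
from protoclust.globalcluster import (
    SeedCluster,
    base_hierarchical,
    extend_seeds,
    modified_hierarchical,
    seed_clustering,
)

T50 = Thresholds(50, 70)


def _hit(a, b, ident, cov=100.0):
    return {edge_key(a, b): HitRecord(a, b, ident, cov, cov)}


class TestBaseHierarchical:
    def test_no_edges_all_singletons(self):
        ids = ["a", "b", "c"]
        assert base_hierarchical(ids, {}, T50) == [{"a"}, {"b"}, {"c"}]

    def test_identical_complete_graph_one_cluster(self):
        ids = [f"p{i}" for i in range(5)]
        edges = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                edges.update(_hit(a, b, 100))
        assert base_hierarchical(ids, edges, T50) == [set(ids)]

    def test_transitive_chain_with_cap(self):
        # a-b and b-c related, a-c unrelated: average linkage with the 1.0
        # cap decides whether c joins {a,b}
        edges = {**_hit("a", "b", 90), **_hit("b", "c", 90), **_hit("a", "c", 40)}
        parts = base_hierarchical(["a", "b", "c"], edges, T50)
        # ({a,b},c) linkage = (0.1 + 1.0)/2 = 0.55 > 0.5 cutoff: no merge
        assert parts == [{"a", "b"}, {"c"}]

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_matches_naive_oracle_on_random_instances(self, linkage):
        rng = random.Random(100)
        for _ in range(60):
            ids, edges = random_edge_instance(rng, rng.randint(2, 12))
            got = base_hierarchical(ids, edges, T50, linkage=linkage)
            expected = naive_agglomerate(ids, edges, T50, linkage=linkage)
            assert got == expected
            check_partition(got, set(ids))


class TestModifiedHierarchical:
    def test_equals_base_when_no_seeds(self):
        rng = random.Random(7)
        for _ in range(25):
            ids, edges = random_edge_instance(rng, rng.randint(2, 12))
            assert modified_hierarchical(ids, edges, T50, set()) == \
                base_hierarchical(ids, edges, T50)

    def test_absorbed_nonseed_does_not_move_seed_distances(self):
        """A chain of drifting homologs cannot drag a seed's profile.

        Seed s absorbs the non-seed pair {x1,x2}; y is close to the x's but
        unrelated to s.  Base linkage averages the x distances in, pulling
        {s,x1,x2}-y to (1.0+0.05+0.05)/3 and absorbing y; the modified rule
        keeps s's own profile (capped, no related edge), so y stays out.
        """
        ids = ["s", "x1", "x2", "y"]
        edges = {
            **_hit("x1", "x2", 99),
            **_hit("s", "x1", 96), **_hit("s", "x2", 96),
            **_hit("x1", "y", 95), **_hit("x2", "y", 95),
            **_hit("s", "y", 45),  # below threshold: unrelated
        }
        base = base_hierarchical(ids, edges, T50)
        mod = modified_hierarchical(ids, edges, T50, seed_ids={"s"})
        assert base == [{"s", "x1", "x2", "y"}]
        assert mod == [{"s", "x1", "x2"}, {"y"}]

    def test_two_seed_clusters_above_cutoff_never_merge(self):
        edges = {**_hit("s1", "a", 90), **_hit("s2", "b", 90), **_hit("a", "b", 45)}
        parts = modified_hierarchical(
            ["s1", "s2", "a", "b"], edges, T50, seed_ids={"s1", "s2"}
        )
        assert {"s1", "a"} in parts and {"s2", "b"} in parts

    def test_matches_naive_oracle_with_random_seed_sets(self):
        rng = random.Random(21)
        for _ in range(40):
            ids, edges = random_edge_instance(rng, rng.randint(3, 10))
            seed_ids = {i for i in ids if rng.random() < 0.3}
            got = modified_hierarchical(ids, edges, T50, seed_ids)
            expected = naive_agglomerate(ids, edges, T50, seed_ids=seed_ids)
            assert got == expected


class TestSeedClustering:
    def test_cross_clade_family_one_seed_cluster(self):
        edges = {**_hit("a", "b", 60), **_hit("b", "c", 62), **_hit("a", "c", 58)}
        seeds = seed_clustering(["a", "b", "c"], edges)
        assert len(seeds) == 1
        assert seeds[0].clustroid_members == {"a", "b", "c"}
        assert seeds[0].extension_members == set()

    def test_distinct_families_two_seed_clusters(self):
        seeds = seed_clustering(["a", "b"], _hit("a", "b", 40))
        assert len(seeds) == 2


class TestExtendSeeds:
    def _seeds(self):
        return [
            SeedCluster("seed:c1", {"c1"}),
            SeedCluster("seed:c2", {"c2", "c3"}),
        ]

    def test_identical_candidate_joins_its_cluster(self):
        hits = {"q": [HitRecord("q", "c1", 100, 100, 100)]}
        extended, leftovers = extend_seeds(["q"], self._seeds(), hits)
        assert extended[0].extension_members == {"q"}
        assert leftovers == {}

    def test_unrelated_candidate_is_leftover_with_neighbor_link(self):
        hits = {"q": [HitRecord("q", "c1", 38, 90, 90)]}
        extended, leftovers = extend_seeds(["q"], self._seeds(), hits)
        assert all(not sc.extension_members for sc in extended)
        link = leftovers["q"]
        assert link is not None
        assert link.clustroid_id == "c1"
        assert link.identity_pct == pytest.approx(38.0)

    def test_nearest_by_identity_wins(self):
        hits = {"q": [
            HitRecord("q", "c1", 64, 90, 90),
            HitRecord("q", "c2", 72, 80, 80),
        ]}
        extended, _ = extend_seeds(["q"], self._seeds(), hits)
        by_id = {sc.cluster_id: sc for sc in extended}
        assert by_id["seed:c2"].extension_members == {"q"}

    def test_compat_all_requires_every_clustroid(self):
        hits = {"q": [HitRecord("q", "c2", 72, 80, 80)]}  # no hit to c3
        extended, leftovers = extend_seeds(["q"], self._seeds(), hits, compat="all")
        assert "q" in leftovers

    def test_clustroid_membership_never_changes_and_order_free(self):
        hits = {
            "q1": [HitRecord("q1", "c1", 80, 90, 90)],
            "q2": [HitRecord("q2", "c3", 55, 75, 75)],
        }
        seeds = self._seeds()
        e1, _ = extend_seeds(["q1", "q2"], seeds, hits)
        e2, _ = extend_seeds(["q2", "q1"], seeds, hits)
        assert [(s.cluster_id, s.clustroid_members, s.extension_members) for s in e1] \
            == [(s.cluster_id, s.clustroid_members, s.extension_members) for s in e2]
        for before, after in zip(seeds, e1):
            assert after.clustroid_members == before.clustroid_members

    def test_leftover_count_monotone_in_identity_threshold(self):
        rng = random.Random(33)
        seeds = self._seeds()
        hits = {
            f"q{i}": [HitRecord(f"q{i}", "c1", rng.uniform(20, 90), 85, 85)]
            for i in range(30)
        }
        sizes = []
        for ident in (70, 50, 30):
            _, leftovers = extend_seeds(hits.keys(), seeds, hits, Thresholds(ident, 70))
            sizes.append(len(leftovers))
        assert sizes[0] >= sizes[1] >= sizes[2]
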