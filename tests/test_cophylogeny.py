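"""DTL reconciliation: oracle equivalence, enumeration, clustering,
cost space, permutation null."""

import numpy as np
import pytest

from oracles import (
    brute_force_dtl,
    congruent_pair,
    shape_to_tree,
    tree_shapes,
)
from rhizophage.io import TreeError, TreePair, parse_newick
from rhizophage.cophylogeny import (
    DTLCosts,
    cluster_mprs,
    cost_space,
    count_mprs,
    dtl_min_cost,
    enumerate_mprs,
    permutation_test,
    validate_reconciliation,
)
from rhizophage.simulate import CophyloSimParams, sim_cophylogeny

PAPER_COSTS = DTLCosts(0, 2, 1, 1)


class TestMinCost:
    def test_congruent_three_tips(self):
        pair = congruent_pair(3)
        assert dtl_min_cost(pair, PAPER_COSTS)[0] == 0

    def test_single_tip_trees(self):
        pair = TreePair(parse_newick("A;"), parse_newick("a;"), {"a": "A"})
        assert dtl_min_cost(pair, PAPER_COSTS)[0] == 0
        assert count_mprs(pair, PAPER_COSTS) == 1

    def test_discordant_four_tip_matches_oracle(self):
        host = parse_newick("((A,B),C);")
        phage = parse_newick("((a,c),b);")
        pair = TreePair(host, phage, {"a": "A", "b": "B", "c": "C"})
        (oracle,) = brute_force_dtl(pair, [(0, 2, 1, 1)])
        got = dtl_min_cost(pair, PAPER_COSTS)[0]
        assert got == pytest.approx(oracle[0])
        assert count_mprs(pair, PAPER_COSTS) == oracle[1]

    def test_nonbinary_rejected(self):
        host = parse_newick("(A,B,C);")
        phage = parse_newick("((a,b),c);")
        with pytest.raises(TreeError):
            TreePair(host, phage, {"a": "A", "b": "B", "c": "C"})

    def test_all_labelled_three_tip_pairs_match_oracle(self):
        """Exhaustive over labelled 3-tip topologies and bijective maps."""
        import itertools

        settings = [(0, 2, 1, 1), (0, 2, 1, 2)]
        topos = ["((X,Y),Z);", "((X,Z),Y);", "((Y,Z),X);"]
        for ht, pt in itertools.product(topos, repeat=2):
            host = parse_newick(ht.replace("X", "A").replace("Y", "B").replace("Z", "C"))
            phage = parse_newick(pt.replace("X", "a").replace("Y", "b").replace("Z", "c"))
            for perm in itertools.permutations("ABC"):
                tm = dict(zip("abc", perm))
                pair = TreePair(host, phage, tm)
                oracle = brute_force_dtl(pair, settings)
                for (mc, cnt), s in zip(oracle, settings):
                    assert dtl_min_cost(pair, DTLCosts(*s))[0] == pytest.approx(mc)
                    assert count_mprs(pair, DTLCosts(*s)) == cnt


class TestEnumeration:
    def test_congruent_single_all_cospeciation_certificate(self):
        pair = congruent_pair(5)
        mprs = enumerate_mprs(pair, PAPER_COSTS)
        assert mprs.count == 1 and len(mprs.sample) == 1
        rec = mprs.sample[0]
        assert rec.counts == {
            "cospeciation": 4, "duplication": 0, "transfer": 0, "loss": 0
        }
        validate_reconciliation(pair, rec, PAPER_COSTS)

    def test_enumeration_complete_and_valid_on_small_trees(self):
        rng = np.random.default_rng(17)
        for nh in (4, 5):
            for hs in tree_shapes(nh):
                host = shape_to_tree(hs, "H")
                htips = host.leaf_names()
                for ps in tree_shapes(4):
                    phage = shape_to_tree(ps, "p")
                    tm = {
                        p: htips[rng.integers(len(htips))]
                        for p in phage.leaf_names()
                    }
                    pair = TreePair(host, phage, tm)
                    mprs = enumerate_mprs(pair, PAPER_COSTS, cap=100000)
                    assert len(mprs.sample) == mprs.count
                    assert mprs.count == count_mprs(pair, PAPER_COSTS)
                    seen = set()
                    for rec in mprs.sample:
                        validate_reconciliation(pair, rec, PAPER_COSTS)
                        assert rec.total_cost == pytest.approx(mprs.min_cost)
                        key = rec.event_set()
                        assert key not in seen
                        seen.add(key)

    def test_cap_truncates_but_count_exact(self):
        sc = sim_cophylogeny(
            CophyloSimParams(n_host_tips=8, transfer=0.2, seed=0)
        )
        full = enumerate_mprs(sc.pair, PAPER_COSTS, cap=10000)
        if full.count < 3:
            pytest.skip("scenario has too few MPRs to exercise the cap")
        capped = enumerate_mprs(sc.pair, PAPER_COSTS, cap=2)
        assert len(capped.sample) == 2
        assert capped.count == full.count

    def test_deterministic_order(self):
        sc = sim_cophylogeny(
            CophyloSimParams(n_host_tips=8, transfer=0.2, seed=8)
        )
        a = enumerate_mprs(sc.pair, PAPER_COSTS, cap=50)
        b = enumerate_mprs(sc.pair, PAPER_COSTS, cap=50)
        assert [r.events for r in a.sample] == [r.events for r in b.sample]


class TestClustering:
    def _sample(self, seed=5, min_n=4):
        sc = sim_cophylogeny(
            CophyloSimParams(n_host_tips=10, transfer=0.25, seed=seed)
        )
        mprs = enumerate_mprs(sc.pair, PAPER_COSTS, cap=30)
        if len(mprs.sample) < min_n:
            pytest.skip("scenario yields too few MPRs")
        return mprs.sample

    def test_identical_sample_single_cluster(self):
        sample = self._sample()[:1] * 3
        out = cluster_mprs(sample, 1)
        assert out.clusters == [[0, 1, 2]]
        with pytest.raises(ValueError, match="distinct"):
            cluster_mprs(sample, 2)

    def test_two_groups_separate(self):
        sample = self._sample()
        out = cluster_mprs(sample, 2)
        assert len(out.clusters) == 2
        assert sorted(i for c in out.clusters for i in c) == list(
            range(len(sample))
        )
        for members, medoid in zip(out.clusters, out.representatives):
            assert medoid in members

    def test_medoid_minimises_within_cluster_distance(self):
        sample = self._sample()[:8]
        out = cluster_mprs(sample, 2)

        def d(i, j):
            return len(sample[i].event_set() ^ sample[j].event_set())

        for members, medoid in zip(out.clusters, out.representatives):
            best = min(members, key=lambda m: sum(d(m, x) for x in members))
            assert sum(d(medoid, x) for x in members) == sum(
                d(best, x) for x in members
            )

    def test_k_out_of_range(self):
        sample = self._sample()
        with pytest.raises(ValueError):
            cluster_mprs(sample, 0)
        with pytest.raises(ValueError):
            cluster_mprs(sample, len(sample) + 1)


class TestCostSpace:
    def test_congruent_single_all_cospeciation_region(self):
        pair = congruent_pair(6)
        cs = cost_space(pair, [0.5, 1.0, 1.5], [1.0, 2.0])
        assert cs.n_regions() == 1
        sig = cs.signatures[0][0]
        assert sig == frozenset({(5, 0, 0, 0)})
        assert np.allclose(cs.min_cost, 0.0)

    def test_min_cost_monotone_in_each_cost(self):
        sc = sim_cophylogeny(
            CophyloSimParams(n_host_tips=8, transfer=0.2, loss=0.1, seed=8)
        )
        cs = cost_space(sc.pair, [0.5, 1.0, 1.5, 2.0], [0.5, 1.0, 1.5, 2.0])
        assert (np.diff(cs.min_cost, axis=0) >= -1e-9).all()
        assert (np.diff(cs.min_cost, axis=1) >= -1e-9).all()

    def test_transfer_vs_losses_signature_flip(self):
        """A phage tip sitting on a distant host (one transfer vs a
        duplication plus deep losses) changes the optimal signature as
        the loss cost crosses the transfer cost."""
        host = parse_newick("(((A,B),C),D);")
        phage = parse_newick("((a1,a2),d);")
        pair = TreePair(
            host, phage, {"a1": "A", "a2": "A", "d": "D"}
        )
        with pytest.raises(ValueError):
            cost_space(pair, [1.0], [0.3])  # ranges need >= 2 points
        cs = cost_space(pair, [1.0, 1.5], [0.3, 2.0], duplication=2.0)
        sig_cheap_loss = cs.signatures[0][0]
        sig_dear_loss = cs.signatures[0][1]
        assert sig_cheap_loss != sig_dear_loss
        # expensive losses favour the transfer explanation
        assert any(s[2] > 0 for s in sig_dear_loss)


class TestPermutationTest:
    def test_congruent_trees_significant(self):
        pair = congruent_pair(8)
        obs, null, p = permutation_test(pair, PAPER_COSTS, n_perm=999, seed=0)
        assert obs == 0
        assert p <= 0.05

    def test_reproducible_and_in_range(self):
        sc = sim_cophylogeny(
            CophyloSimParams(n_host_tips=8, transfer=0.3, seed=10)
        )
        r1 = permutation_test(sc.pair, PAPER_COSTS, n_perm=199, seed=7)
        r2 = permutation_test(sc.pair, PAPER_COSTS, n_perm=199, seed=7)
        assert r1[2] == r2[2]
        assert 0 < r1[2] <= 1
        assert np.array_equal(r1[1], r2[1])

    def test_random_scenario_not_significant(self):
        """Tips scattered at random over hosts should look like the null."""
        rng = np.random.default_rng(3)
        host = congruent_pair(8).host
        phage = congruent_pair(8).phage
        htips = [f"H{i}" for i in range(1, 9)]
        tm = {f"p{i}": htips[rng.integers(8)] for i in range(1, 9)}
        pair = TreePair(host, phage, tm)
        _, _, p = permutation_test(pair, PAPER_COSTS, n_perm=499, seed=1)
        assert p > 0.05

    def test_topology_null_runs(self):
        pair = congruent_pair(6)
        obs, null, p = permutation_test(
            pair, PAPER_COSTS, n_perm=99, seed=2, null="topology"
        )
        assert obs == 0 and 0 < p <= 1

    def test_too_few_perms_rejected(self):
        pair = congruent_pair(4)
        with pytest.raises(ValueError):
            permutation_test(pair, PAPER_COSTS, n_perm=10, seed=0)
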