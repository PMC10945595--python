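"""Rank collapsing, LCA mapping, DL and DTL reconciliation against a
brute-force oracle, and support-driven rearrangement."""

import random

import pytest

from matrisome.io import read_newick
from matrisome.reconcile import (
    ReconciliationCosts,
    collapse_to_ranks,
    lca_map,
    rearrange_weak_edges,
    reconcile_dl,
    reconcile_dtl,
)
from matrisome.simulate import simulate_gene_tree

from conftest import random_tree_newick
from dtl_oracle import oracle_min_cost

COSTS = ReconciliationCosts(1.5, 1.0, 0.0, 1.0)


def _random_instance(rand: random.Random, max_species=5, max_gene_leaves=6):
    n_sp = rand.randint(2, max_species)
    species = [chr(ord("A") + i) for i in range(n_sp)]
    stree = read_newick(random_tree_newick(rand, species, lengths=False))
    n_gl = rand.randint(2, max_gene_leaves)
    counter = {}
    labels = []
    for _ in range(n_gl):
        sp = rand.choice(species)
        counter[sp] = counter.get(sp, 0) + 1
        labels.append(f"{sp}_{counter[sp]}")
    gtree = read_newick(random_tree_newick(rand, labels, lengths=False))
    return gtree, stree


class TestCollapse:
    def test_all_ranked_unchanged(self):
        t = read_newick("((A,B)g1,C)f1;")
        out = collapse_to_ranks(t, {"g1": "genus", "f1": "family"})
        sig = {frozenset(l.taxon.label for l in n.leaf_iter())
               for n in out.postorder_node_iter()}
        assert frozenset({"A", "B"}) in sig

    def test_unranked_node_contracted(self):
        t = read_newick("(((A,B)x,C)f1,D)k1;")
        out = collapse_to_ranks(t, {"f1": "family", "k1": "kingdom"})
        assert sorted(l.taxon.label for l in out.leaf_nodes()) == list("ABCD")
        sig = {frozenset(l.taxon.label for l in n.leaf_iter())
               for n in out.postorder_node_iter()}
        assert frozenset({"A", "B"}) not in sig
        assert frozenset({"A", "B", "C"}) in sig

    def test_leaf_set_preserved_on_random_trees(self):
        rand = random.Random(3)
        for _ in range(20):
            leaves = [f"s{i}" for i in range(rand.randint(3, 9))]
            t = read_newick(random_tree_newick(rand, leaves, lengths=False))
            out = collapse_to_ranks(t, {})  # nothing ranked: full contraction
            assert sorted(l.taxon.label for l in out.leaf_nodes()) == sorted(leaves)


class TestLcaMap:
    def test_congruent_tree_maps_isomorphically(self):
        sp = read_newick("((A,B),C);")
        g = read_newick("((A_1,B_1),C_1);")
        m = lca_map(g, sp)
        root_image = m[g.seed_node]
        assert {l.taxon.label for l in root_image.leaf_iter()} == {"A", "B", "C"}

    def test_paralog_pairs_map_to_common_ancestor(self):
        sp = read_newick("(A,B);")
        g = read_newick("((A_1,B_1),(A_2,B_2));")
        m = lca_map(g, sp)
        internals = [n for n in g.preorder_internal_node_iter()]
        for node in internals:
            assert m[node] is sp.seed_node

    def test_unresolvable_leaf_named_in_error(self):
        sp = read_newick("(A,B);")
        g = read_newick("(A_1,Zed_1);")
        with pytest.raises(ValueError, match="Zed_1"):
            lca_map(g, sp)


class TestReconcileDL:
    def test_congruent_trees_cost_zero(self):
        sp = read_newick("((A,B),C);")
        g = read_newick("((A_1,B_1),C_1);")
        r = reconcile_dl(g, sp, COSTS)
        assert r.duplications == r.losses == 0
        assert r.total_cost == 0.0
        assert all(ev in ("codivergence", "leaf") for ev in r.events.values())

    def test_root_duplication(self):
        sp = read_newick("(A,B);")
        g = read_newick("((A_1,B_1),(A_2,B_2));")
        r = reconcile_dl(g, sp, COSTS)
        assert r.duplications == 1 and r.losses == 0
        assert r.total_cost == 1.5

    def test_matches_bruteforce_on_random_instances(self):
        rand = random.Random(91)
        for _ in range(40):
            g, s = _random_instance(rand)
            r = reconcile_dl(g, s, COSTS)
            expected = oracle_min_cost(g, s, COSTS, allow_transfer=False)
            assert r.total_cost == pytest.approx(expected)


class TestReconcileDTL:
    def test_congruent_trees_all_codivergence(self):
        sp = read_newick("((A,B),C);")
        g = read_newick("((A_1,B_1),C_1);")
        r = reconcile_dtl(g, sp, COSTS)
        assert r.total_cost == 0.0
        assert r.transfers == r.duplications == r.losses == 0

    def test_transfer_beats_duplication_on_classic_case(self):
        # gene ((a,c),b) on species ((A,B),C): one transfer explains the
        # tree more cheaply than any transfer-free scenario
        sp = read_newick("((A,B),C);")
        g = read_newick("((A_1,C_1),B_1);")
        r = reconcile_dtl(g, sp, COSTS)
        assert r.transfers == 1
        dl = reconcile_dl(g, sp, COSTS)
        assert r.total_cost < dl.total_cost

    def test_matches_bruteforce_on_random_instances(self):
        rand = random.Random(17)
        for _ in range(40):
            g, s = _random_instance(rand)
            r = reconcile_dtl(g, s, COSTS)
            expected = oracle_min_cost(g, s, COSTS, allow_transfer=True)
            assert r.total_cost == pytest.approx(expected)

    def test_dtl_never_costlier_than_dl(self):
        rand = random.Random(55)
        for _ in range(30):
            g, s = _random_instance(rand)
            assert (reconcile_dtl(g, s, COSTS).total_cost
                    <= reconcile_dl(g, s, COSTS).total_cost + 1e-9)

    def test_expensive_transfers_reduce_to_dl(self):
        rand = random.Random(23)
        costly = ReconciliationCosts(1.5, 1e6, 0.0, 1.0)
        for _ in range(50):
            g, s = _random_instance(rand)
            dtl = reconcile_dtl(g, s, costly)
            dl = reconcile_dl(g, s, costly)
            assert dtl.duplications == dl.duplications
            assert dtl.losses == dl.losses
            assert dtl.transfers == 0

    def test_total_cost_identity(self):
        rand = random.Random(7)
        for _ in range(20):
            g, s = _random_instance(rand)
            r = reconcile_dtl(g, s, COSTS)
            recomputed = (r.duplications * COSTS.duplication
                          + r.transfers * COSTS.transfer
                          + r.codivergences * COSTS.codivergence
                          + r.losses * COSTS.loss)
            assert r.total_cost == pytest.approx(recomputed)

    def test_planted_event_counts_recovered(self, species_tree_4):
        hits = 0
        n = 100
        for seed in range(n):
            gtree, truth = simulate_gene_tree(
                species_tree_4, 0.03, 0.02, 0.01, seed=seed)
            r = reconcile_dtl(gtree, species_tree_4, COSTS)
            if (r.duplications == truth.params["duplications"]
                    and r.transfers == truth.params["transfers"]):
                hits += 1
        assert hits / n >= 0.9


class TestRearrange:
    def test_strong_supports_leave_tree_unchanged(self):
        sp = read_newick("((A,B),(C,D));")
        g = read_newick("(((A_1,B_1)99,C_1)99,D_1);")
        out = rearrange_weak_edges(g, sp, COSTS, 98.0)
        sig = {frozenset(l.taxon.label for l in n.leaf_iter())
               for n in out.postorder_node_iter()}
        assert frozenset({"A_1", "B_1"}) in sig
        assert frozenset({"A_1", "B_1", "C_1"}) in sig

    def test_weak_edge_rearrangement_removes_spurious_duplication(self):
        # ((A,C),(B,D)) costs > 0 on species ((A,B),(C,D)); collapsing the
        # weak edges lets the optimizer recover the congruent topology
        sp = read_newick("((A,B),(C,D));")
        g = read_newick("((A_1,C_1)50,(B_1,D_1)50);")
        before = reconcile_dtl(g, sp, COSTS).total_cost
        out = rearrange_weak_edges(g, sp, COSTS, 98.0)
        after = reconcile_dtl(out, sp, COSTS).total_cost
        assert after < before
        assert after == 0.0

    def test_cost_never_increases(self):
        rand = random.Random(5)
        for _ in range(15):
            g, s = _random_instance(rand, max_species=4, max_gene_leaves=5)
            # attach random supports to internal edges
            for node in g.preorder_internal_node_iter():
                if node is not g.seed_node:
                    node.label = str(rand.choice([40, 60, 97, 99, 100]))
            before = reconcile_dtl(g, s, COSTS).total_cost
            out = rearrange_weak_edges(g, s, COSTS, 98.0)
            after = reconcile_dtl(out, s, COSTS).total_cost
            assert after <= before + 1e-9
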