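import math
import random

import dendropy
import numpy as np
import pytest
from dendropy.model.parsimony import fitch_down_pass

import paleomacro as pm
from paleomacro.parsimony import (_all_topologies, _adj_to_dendropy,
                                  _bipartitions, _CharData, _score_adj)

from conftest import random_matrix


def _mat(taxa_states: dict[str, list[int | None]],
         ordered: list[bool] | None = None) -> pm.CharacterMatrix:
    taxa = list(taxa_states)
    cells = [[frozenset() if s is None else frozenset({s})
              for s in states] for states in taxa_states.values()]
    return pm.CharacterMatrix(taxa, cells, ordered or [])


class TestFitchLength:
    def test_invariant_character_costs_nothing(self):
        t = pm.read_tree("((A,B),(C,D));")
        m = _mat({"A": [0], "B": [0], "C": [0], "D": [0]})
        assert pm.fitch_length(t, m) == 0

    def test_single_origin_costs_one_step(self):
        t = pm.read_tree("((A,B),(C,D));")
        m = _mat({"A": [0], "B": [0], "C": [1], "D": [1]})
        assert pm.fitch_length(t, m) == 1

    def test_missing_cells_never_add_steps(self):
        t = pm.read_tree("((A,B),(C,D));")
        m = _mat({"A": [0], "B": [None], "C": [None], "D": [0]})
        assert pm.fitch_length(t, m) == 0

    def test_polymorphic_tip_can_match_either_state(self):
        t = pm.read_tree("((A,B),(C,D));")
        m = pm.CharacterMatrix(
            ["A", "B", "C", "D"],
            [[frozenset({0, 1})], [frozenset({0})],
             [frozenset({1})], [frozenset({1})]])
        assert pm.fitch_length(t, m) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_dendropy_fitch(self, seed):
        """Independent oracle: dendropy's Fitch downpass on the same
        random tree and matrix."""
        m = random_matrix(seed, n_taxa=8, n_chars=25, missing=0.3)
        nexus = pm.write_character_matrix(m)
        dmat = dendropy.StandardCharacterMatrix.get(data=nexus,
                                                    schema="nexus")
        tree = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=8,
            taxon_namespace=dmat.taxon_namespace,
            rng=random.Random(seed))
        oracle = fitch_down_pass(
            tree.postorder_node_iter(),
            taxon_state_sets_map=dmat.taxon_state_sets_map(
                gaps_as_missing=True))
        assert pm.fitch_length(tree, m) == oracle

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_rerooting(self, seed):
        m = random_matrix(seed, n_taxa=8, n_chars=20, missing=0.2)
        trees = pm.heuristic_search(
            m, pm.SearchConfig(n_replicates=1, seed=seed))
        t = trees[0]
        base = pm.fitch_length(t, m)
        for leaf_i in (1, 4):
            clone = t.clone(depth=1)
            leaf = clone.leaf_nodes()[leaf_i]
            clone.reroot_at_edge(leaf.edge)
            assert pm.fitch_length(clone, m) == base

    def test_unknown_tip_raises(self):
        t = pm.read_tree("((A,B),(C,X));")
        m = _mat({"A": [0], "B": [0], "C": [1], "D": [1]})
        with pytest.raises(KeyError):
            pm.fitch_length(t, m)

    def test_ordered_character_counts_intermediate_steps(self):
        # 0 -> 2 on an additive character costs two steps, one unordered
        t = pm.read_tree("((A,B),(C,D));")
        states = {"A": [0], "B": [0], "C": [2], "D": [2]}
        unordered = _mat(states)
        ordered = _mat(states, ordered=[True])
        assert pm.fitch_length(t, unordered) == 1
        assert pm.fitch_length(t, ordered) == 2


class TestCharStepBounds:
    def test_min_max_from_frequencies(self):
        m = _mat({f"T{i}": [s] for i, s in enumerate([0, 0, 1, 1, 1])})
        assert pm.char_min_steps(m, 0) == 1
        assert pm.char_max_steps(m, 0) == 2

    def test_invariant_character_is_zero_zero(self):
        m = _mat({f"T{i}": [0] for i in range(5)})
        assert pm.char_min_steps(m, 0) == 0
        assert pm.char_max_steps(m, 0) == 0

    def test_all_missing_character_is_zero_zero(self):
        m = _mat({f"T{i}": [None] for i in range(4)})
        assert pm.char_min_steps(m, 0) == 0
        assert pm.char_max_steps(m, 0) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_max_equals_star_tree_length(self, seed):
        """Star-tree oracle: the conceivable maximum is the length on the
        completely unresolved tree."""
        m = random_matrix(seed, n_taxa=10, n_chars=6, missing=0.2)
        star = pm.read_tree("(" + ",".join(m.taxa) + ");")
        star_len = pm.fitch_length(star, m)
        total_max = sum(pm.char_max_steps(m, j)
                        for j in range(m.n_characters))
        assert total_max == star_len


class TestEnsembleIndices:
    def test_perfectly_congruent_matrix(self):
        m = _mat({"A": [0, 0], "B": [0, 0], "C": [1, 0], "D": [1, 1],
                  "E": [1, 1]})
        trees, best = pm.exhaustive_search(m)
        stats = pm.ensemble_indices(trees[0], m)
        assert stats.ci == 1.0
        assert stats.ri == 1.0

    def test_hand_worked_convergent_character(self):
        # char 1 groups (A,B,C) (min 1, star max 3); char 2 is convergent
        # in C and F on the tree ((A,B,C),(D,E,F)) (min 1, star max 2):
        # length 3, Σmin 2, Σmax 5
        m = _mat({"A": [1, 0], "B": [1, 0], "C": [1, 1],
                  "D": [0, 0], "E": [0, 0], "F": [0, 1]})
        t = pm.read_tree("((A,B,C),(D,E,F));")
        stats = pm.ensemble_indices(t, m)
        assert stats.length == 3
        assert stats.ci == pytest.approx(2 / 3)
        assert stats.ri == pytest.approx((5 - 3) / (5 - 2))
        assert stats.rc == pytest.approx(stats.ci * stats.ri)

    def test_rc_is_product_of_ci_and_ri(self, small_sim):
        _, _, _, matrix, _ = small_sim
        trees = pm.heuristic_search(
            matrix, pm.SearchConfig(n_replicates=1, seed=0,
                                    max_trees_held=5))
        stats = pm.ensemble_indices(trees[0], matrix)
        assert stats.rc == pytest.approx(stats.ci * stats.ri, abs=1e-12)

    def test_no_variation_reports_absent_ri(self):
        m = _mat({"A": [0], "B": [0], "C": [0], "D": [0]})
        t = pm.read_tree("((A,B),(C,D));")
        stats = pm.ensemble_indices(t, m)
        assert stats.ri is None and stats.rc is None


class TestHeuristicSearch:
    def test_perfect_signal_recovers_true_tree(self):
        # nested synapomorphies: ((((A,B),C),D),E)
        m = _mat({"A": [1, 1, 1], "B": [1, 1, 1], "C": [0, 1, 1],
                  "D": [0, 0, 1], "E": [0, 0, 0]})
        trees = pm.heuristic_search(m, pm.SearchConfig(n_replicates=2,
                                                       seed=0))
        assert len(trees) == 1
        assert pm.fitch_length(trees[0], m) == 3
        # unrooted splits, canonical side excludes taxon A:
        # {A,B}|{C,D,E} and {A,B,C}|{D,E}
        assert pm.tree_key(trees[0]) == frozenset({
            frozenset({"C", "D", "E"}), frozenset({"D", "E"})})

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_optimum(self, seed):
        """Brute-force oracle over all 945 seven-taxon topologies."""
        m = random_matrix(200 + seed, n_taxa=7, n_chars=10, missing=0.25)
        _, best = pm.exhaustive_search(m)
        found = pm.heuristic_search(
            m, pm.SearchConfig(n_replicates=3, seed=seed))
        assert pm.fitch_length(found[0], m) == best

    def test_fixed_seed_is_reproducible(self):
        m = random_matrix(77, n_taxa=8, n_chars=12, missing=0.2)
        cfg = pm.SearchConfig(n_replicates=2, seed=123)
        a = {pm.tree_key(t) for t in pm.heuristic_search(m, cfg)}
        b = {pm.tree_key(t) for t in pm.heuristic_search(m, cfg)}
        assert a == b

    def test_outgroup_orients_root(self):
        m = _mat({"A": [1, 1], "B": [1, 1], "C": [0, 1], "D": [0, 0]})
        trees = pm.heuristic_search(
            m, pm.SearchConfig(n_replicates=1, seed=0, outgroup="D"))
        root_children = trees[0].seed_node.child_nodes()
        labels = [c.taxon.label for c in root_children if c.is_leaf()]
        assert "D" in labels


class TestConsensusAndPruning:
    def test_consensus_of_one_tree_is_itself(self):
        t = pm.read_tree("((A,B),(C,D),E);")
        assert pm.tree_key(pm.strict_consensus([t])) == pm.tree_key(t)

    def test_conflicting_clade_collapses(self):
        t1 = pm.read_tree("(((A,B),C),D,E);")
        t2 = pm.read_tree("(((A,C),B),D,E);")
        cons = pm.strict_consensus([t1, t2])
        # only {A,B,C}|{D,E} survives; the conflicting (A,B) clade is gone
        assert pm.tree_key(cons) == frozenset({frozenset({"D", "E"})})

    def test_consensus_of_all_topologies_is_star(self):
        taxa = [f"T{i}" for i in range(7)]
        ns = dendropy.TaxonNamespace()
        trees = [_adj_to_dendropy(adj, taxa, ns, None)
                 for adj in _all_topologies(7)]
        assert len(trees) == 945
        assert pm.tree_key(pm.strict_consensus(trees)) == frozenset()

    def test_prune_cherry_member(self):
        t = pm.read_tree("((A,B),(C,D));")
        (pruned,) = pm.prune_taxon([t], "A")
        labels = sorted(lf.taxon.label for lf in pruned.leaf_node_iter())
        assert labels == ["B", "C", "D"]

    def test_prune_merges_trees_differing_only_in_that_taxon(self):
        t1 = pm.read_tree("(((A,B),C),(D,E));")
        t2 = pm.read_tree("((A,(B,C)),(D,E));")  # B moves
        merged = pm.prune_taxon([t1, t2], "B")
        assert len(merged) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_prune_then_consensus_at_least_as_resolved(self, seed):
        m = random_matrix(300 + seed, n_taxa=7, n_chars=8, missing=0.3)
        trees, _ = pm.exhaustive_search(m)
        victim = m.taxa[0]
        prune_first = pm.strict_consensus(pm.prune_taxon(trees, victim))
        consensus_first = pm.prune_taxon([pm.strict_consensus(trees)],
                                         victim)[0]
        assert pm.tree_key(prune_first) >= pm.tree_key(consensus_first)


class TestDecayIndex:
    def test_forced_clade_decays_at_character_count(self):
        k = 3
        taxa = ["A", "B", "C", "D", "E"]
        cells = [[frozenset({1 if t in ("A", "B") else 0})] * k
                 for t in taxa]
        m = pm.CharacterMatrix(taxa, cells)
        cfg = pm.SearchConfig(n_replicates=3, seed=0)
        assert pm.decay_index(m, {"A", "B"}, cfg) == k

    def test_matches_enumeration_oracle(self):
        """Decay for every consensus clade equals the enumeration value:
        (shortest tree lacking the clade) − (global optimum)."""
        m = random_matrix(42, n_taxa=6, n_chars=12, n_states=2)
        trees, best = pm.exhaustive_search(m)
        cons = pm.strict_consensus(trees)
        data = _CharData(m)
        full = (1 << 6) - 1
        cfg = pm.SearchConfig(n_replicates=5, seed=1)
        for clade in pm.tree_key(cons):
            mask = 0
            for name in clade:
                mask |= 1 << m.taxa.index(name)
            canon = min(mask, full ^ mask)
            best_without = min(
                _score_adj(adj, data) for adj in _all_topologies(6)
                if canon not in _bipartitions(adj, 6))
            assert pm.decay_index(m, clade, cfg) == best_without - best

    def test_trivial_bipartition_is_unbreakable(self):
        m = random_matrix(1, n_taxa=6, n_chars=8)
        cfg = pm.SearchConfig(n_replicates=1, seed=0)
        assert pm.decay_index(m, {m.taxa[0]}, cfg) == math.inf
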