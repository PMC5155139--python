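import numpy as np
import pytest

from paleobite.parsimony import (CharacterMatrix, Tree, ensemble_ci_ri,
                                 map_synapomorphies, step_bounds, tree_length)

from conftest import all_topologies, brute_force_length, random_matrix


def simple_matrix(columns, ordered=None, taxa=None):
    """columns: list of per-character state strings, '?' for missing."""
    n_taxa = len(columns[0])
    taxa = taxa or [chr(65 + i) for i in range(n_taxa)]
    cells = [[None if col[i] == "?" else frozenset({int(col[i])})
              for col in columns] for i in range(n_taxa)]
    return CharacterMatrix(taxa, cells, ordered or [False] * len(columns))


class TestTreeLength:
    def test_single_origin(self):
        m = simple_matrix(["0011"])
        assert tree_length(Tree.from_newick("((A,B),(C,D));"), m) == 1

    def test_conflicting_topology_two_steps(self):
        m = simple_matrix(["0011"])
        t = Tree.from_newick("((A,C),(B,D));")
        assert tree_length(t, m) == 2
        assert tree_length(t, m) == brute_force_length(t, m)

    def test_ordered_range_width(self):
        m = simple_matrix(["02"], ordered=[True], taxa=["A", "B"])
        t = Tree.from_newick("(A,B);")
        assert tree_length(t, m) == 2

    def test_missing_cells_never_add_cost(self):
        m1 = simple_matrix(["0011"])
        m2 = simple_matrix(["0?11"])
        t = Tree.from_newick("((A,B),(C,D));")
        assert tree_length(t, m2) <= tree_length(t, m1)

    def test_polymorphism_cheapest_member(self):
        cells = [[frozenset({0, 1})], [frozenset({0})],
                 [frozenset({1})], [frozenset({1})]]
        m = CharacterMatrix(["A", "B", "C", "D"], cells)
        t = Tree.from_newick("((A,B),(C,D));")
        assert tree_length(t, m) == 1

    def test_per_character_breakdown_sums(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 6, 5)
        t = all_topologies(m.taxa)[0]
        total, per_char = tree_length(t, m, per_character=True)
        assert total == per_char.sum()

    def test_soft_polytomy_scores_like_best_case(self):
        """A star tree never scores below any resolution of it."""
        m = simple_matrix(["0011", "0101"])
        star = Tree.from_newick("(A,B,C,D);")
        resolved = [Tree.from_newick(s) for s in
                    ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]]
        assert tree_length(star, m) >= min(tree_length(t, m)
                                           for t in resolved)

    def test_unknown_leaf_rejected(self):
        m = simple_matrix(["0011"])
        with pytest.raises(ValueError, match="absent"):
            tree_length(Tree.from_newick("((A,B),(C,X));"), m)

    def test_matches_brute_force_on_random_instances(self, rng):
        """DP length equals exhaustive minimization over internal state
        assignments on random <=7-taxon instances (30 spot checks; the
        full 200-instance sweep runs with the acceptance checks)."""
        for _ in range(30):
            n_taxa = int(rng.integers(4, 8))
            n_char = int(rng.integers(1, 7))
            m = random_matrix(rng, n_taxa, n_char)
            topos = all_topologies(m.taxa)
            t = topos[int(rng.integers(len(topos)))]
            assert tree_length(t, m) == brute_force_length(t, m)

    def test_matches_dendropy_fitch_on_unordered_matrix(self, rng):
        """Independent cross-check: unordered lengths agree with
        dendropy's Fitch down-pass on single-state matrices."""
        dendropy = pytest.importorskip("dendropy")
        from dendropy.model.parsimony import parsimony_score
        m = random_matrix(rng, 7, 8, poly_p=0.0, ordered_p=0.0)
        taxa = dendropy.TaxonNamespace()
        rows = {t: "".join("?" if c is None else str(next(iter(c)))
                           for c in row)
                for t, row in zip(m.taxa, m.cells)}
        dmat = dendropy.StandardCharacterMatrix.from_dict(
            rows, taxon_namespace=taxa)
        for t in all_topologies(m.taxa)[::101]:
            dt = dendropy.Tree.get(data=t.to_newick(), schema="newick",
                                   taxon_namespace=taxa)
            dt.encode_bipartitions()
            assert tree_length(t, m) == parsimony_score(dt, dmat)

    def test_constant_character_adds_nothing(self, rng):
        m = random_matrix(rng, 6, 4)
        cells2 = [row + [frozenset({1})] for row in m.cells]
        m2 = CharacterMatrix(m.taxa, cells2, m.ordered_flags + [False])
        t = all_topologies(m.taxa)[7]
        assert tree_length(t, m) == tree_length(t, m2)


class TestStepBounds:
    def test_binary_three_three(self):
        m = simple_matrix(["000111"])
        b = step_bounds(m)
        assert b.m[0] == 1 and b.g[0] == 3

    def test_constant_character(self):
        m = simple_matrix(["1111"])
        b = step_bounds(m)
        assert b.m[0] == 0 and b.g[0] == 0

    def test_ordered_0022(self):
        m = simple_matrix(["0022"], ordered=[True])
        b = step_bounds(m)
        assert b.m[0] == 2 and b.g[0] == 4

    def test_bounds_bracket_every_topology(self, rng):
        """m <= s <= g over all topologies on random 6-taxon characters,
        and both bounds are attained-or-valid per the star-tree bound."""
        for _ in range(5):
            m = random_matrix(rng, 6, 3, missing_p=0.1, poly_p=0.0)
            b = step_bounds(m)
            lengths = np.array([
                [tree_length(t, m, per_character=True)[1][j]
                 for t in all_topologies(m.taxa)]
                for j in range(m.n_char)])
            for j in range(m.n_char):
                assert lengths[j].min() == b.m[j]
                assert lengths[j].max() <= b.g[j]


class TestCiRi:
    def test_perfectly_congruent_matrix(self):
        m = simple_matrix(["0011", "0001", "0111"])
        best = min(all_topologies(m.taxa),
                   key=lambda t: tree_length(t, m))
        ci, ri = ensemble_ci_ri(best, m)
        assert ci == pytest.approx(1.0)
        assert ri == pytest.approx(1.0)

    def test_matches_hand_computation(self, rng):
        m = random_matrix(rng, 6, 5, missing_p=0.1)
        t = all_topologies(m.taxa)[3]
        ci, ri = ensemble_ci_ri(t, m)
        b = step_bounds(m)
        _, s = tree_length(t, m, per_character=True)
        assert ci == pytest.approx(b.m.sum() / s.sum())
        inf = b.g > b.m
        expect_ri = (b.g[inf] - s[inf]).sum() / (b.g[inf] - b.m[inf]).sum()
        assert ri == pytest.approx(expect_ri)

    def test_ci_ri_in_unit_interval(self, rng):
        for _ in range(5):
            m = random_matrix(rng, 6, 6, missing_p=0.1)
            t = all_topologies(m.taxa)[0]
            ci, ri = ensemble_ci_ri(t, m)
            assert 0 < ci <= 1.0
            assert ri <= 1.0


class TestSynapomorphies:
    def test_single_clean_character_one_change(self):
        m = simple_matrix(["0011"])
        t = Tree.from_newick("((A,B),(C,D));", rooted=True)
        changes = map_synapomorphies(t, m)
        assert len(changes) == 1
        assert changes[0]["branch"] == "{C,D}"

    def test_total_changes_equal_tree_length(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 5)
            t = all_topologies(m.taxa)[int(rng.integers(100))]
            t = Tree.from_newick(t.to_newick(), rooted=True)
            for opt in ("acctran", "deltran"):
                changes = map_synapomorphies(t, m, optimization=opt)
                assert sum(c["steps"] for c in changes) == tree_length(t, m)

    def test_homoplastic_character_counts_match_brute_force(self):
        """Parallel origin of state 1: two changes whichever MP
        reconstruction is chosen."""
        m = simple_matrix(["010010"], taxa=list("ABCDEF"))
        t = Tree.from_newick("(((A,B),(C,D)),(E,F));", rooted=True)
        assert brute_force_length(t, m) == 2
        changes = map_synapomorphies(t, m)
        assert sum(c["steps"] for c in changes) == 2
        assert {c["branch"] for c in changes} == {"B", "E"}

    def test_unrooted_input_rejected(self):
        m = simple_matrix(["0011"])
        t = Tree.from_newick("((A,B),(C,D));", rooted=False)
        with pytest.raises(ValueError, match="rooted"):
            map_synapomorphies(t, m)
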