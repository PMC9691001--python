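"""Dollo parsimony: step counting, search, bootstrap, indices, NEXUS IO."""

import itertools

import numpy as np
import pytest

from aluphylo.dollo import (
    CharacterMatrix,
    UndefinedIndicesError,
    bootstrap_support,
    dollo_lengths,
    dollo_steps,
    encode_character_matrix,
    enumerate_topologies,
    majority_rule_consensus,
    read_matrix_csv,
    read_nexus,
    score_tree,
    search_most_parsimonious,
    star_tree,
    tree_indices,
    write_nexus,
)
from aluphylo.tree import parse_newick
from conftest import bruteforce_dollo

QUAD = parse_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


def matrix_from_columns(taxa, columns):
    states = np.array(
        [[col.get(t, 0) for col in columns] for t in taxa], dtype=np.int8
    )
    return CharacterMatrix(list(taxa), [f"c{i}" for i in range(len(columns))], states)


class TestDolloSteps:
    def test_clean_clade_single_gain(self):
        assert dollo_steps(QUAD, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_homoplastic_character_gain_plus_two_losses(self):
        assert dollo_steps(QUAD, {"A": 1, "C": 1, "B": 0, "D": 0}) == 3

    def test_missing_state_resolved_to_minimize(self):
        assert dollo_steps(QUAD, {"A": 1, "B": -1, "C": 0, "D": 0}) == 1

    def test_constant_absent_column_zero_steps(self):
        assert dollo_steps(QUAD, {"A": 0, "B": 0, "C": 0, "D": 0}) == 0

    def test_matches_bruteforce_on_random_trees(self):
        """Sampled version of the exhaustive oracle equivalence check."""
        taxa = ["A", "B", "C", "D", "E"]
        trees = enumerate_topologies(taxa, ["A"])[:6]
        for tree in trees:
            for bits in itertools.product([0, 1], repeat=5):
                column = dict(zip(taxa, bits))
                assert dollo_steps(tree, column) == bruteforce_dollo(tree, column)

    def test_missing_states_match_bruteforce(self):
        taxa = ["A", "B", "C", "D"]
        rng = np.random.default_rng(3)
        trees = enumerate_topologies(taxa, ["A"])
        for tree in trees:
            for _ in range(20):
                column = {t: int(rng.integers(-1, 2)) for t in taxa}
                if all(v == -1 for v in column.values()):
                    continue
                assert dollo_steps(tree, column) == bruteforce_dollo(tree, column)

    def test_vectorized_lengths_match_scalar(self):
        taxa = ["A", "B", "C", "D"]
        rng = np.random.default_rng(5)
        cols = [
            {t: int(rng.integers(0, 2)) for t in taxa} for _ in range(30)
        ]
        M = matrix_from_columns(taxa, cols)
        vec = dollo_lengths(QUAD, M)
        for j, col in enumerate(cols):
            assert vec[j] == dollo_steps(QUAD, col)


class TestEncoding:
    def test_genotype_codes_and_outgroup_padding(self):
        table = {
            ("L1", "x1"): (1, 1),
            ("L1", "x2"): (1, 0),
            ("L2", "x1"): (0, 0),
            ("L2", "x2"): None,
        }
        M = encode_character_matrix(table, outgroup_taxa=["og"])
        assert M.taxa == ["x1", "x2", "og"]
        col1 = M.column("L1")
        col2 = M.column("L2")
        assert (col1["x1"], col1["x2"], col1["og"]) == (1, 1, 0)
        assert (col2["x1"], col2["x2"], col2["og"]) == (0, -1, 0)

    def test_unknown_genotype_code_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype"):
            encode_character_matrix({("L1", "x1"): (2, 0)})

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError, match="no observed state"):
            encode_character_matrix({("L1", "x1"): None})


class TestSearch:
    def build_compatible(self, with_extra_taxon_e=True):
        taxa = ["A", "B", "C", "D", "E", "OUT"]
        true = parse_newick("(OUT:1,((((A:1,B:1):1,C:1):1,D:1):1,E:1):1):0;")
        cols = [
            {"A": 1, "B": 1},
            {"A": 1, "B": 1, "C": 1},
            {"A": 1, "B": 1, "C": 1, "D": 1},
            {"A": 1},
            {"E": 1},
        ]
        return taxa, true, matrix_from_columns(taxa, cols)

    def test_exhaustive_enumeration_counts(self):
        # unrooted topology counts: (2n-5)!! for n tips
        assert len(enumerate_topologies(["A", "B", "C", "D"], ["A"])) == 3
        assert len(enumerate_topologies(list("ABCDE"), ["A"])) == 15
        assert len(enumerate_topologies(list("ABCDEF"), ["A"])) == 105

    def test_compatible_matrix_recovers_true_topology(self):
        taxa, true, M = self.build_compatible()
        best = search_most_parsimonious(M, ["OUT"], mode="exhaustive")
        assert best.tree_length == 5  # one step per variable character
        assert len(best.alternatives) == 1
        assert best.topology.canonical() == true.canonical()

    def test_heuristic_matches_exhaustive_on_random_matrices(self):
        taxa = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(8)
        agree = 0
        trials = 30
        for t in range(trials):
            cols = [
                {x: int(rng.integers(0, 2)) for x in taxa[1:]} for _ in range(12)
            ]
            M = matrix_from_columns(taxa, cols)
            exh = search_most_parsimonious(M, ["A"], mode="exhaustive")
            heu = search_most_parsimonious(M, ["A"], mode="heuristic", seed=t)
            agree += exh.tree_length == heu.tree_length
        assert agree >= trials - 1

    def test_single_variable_character_any_grouping_optimal(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        M = matrix_from_columns(taxa, [{"A": 1, "B": 1}])
        best = search_most_parsimonious(M, ["OUT"], mode="exhaustive")
        assert best.tree_length == 1
        for alt in best.alternatives:
            assert score_tree(alt, M) == 1

    def test_exhaustive_size_limit(self):
        taxa = [f"t{i}" for i in range(12)]
        M = matrix_from_columns(taxa, [{"t1": 1, "t2": 1}])
        with pytest.raises(ValueError, match="heuristic"):
            search_most_parsimonious(M, ["t0"], mode="exhaustive")

    def test_length_invariant_under_child_order(self):
        taxa, true, M = self.build_compatible()
        base = score_tree(true, M)
        shuffled = true.copy()
        for node in shuffled.postorder():
            node.children = node.children[::-1]
        assert score_tree(shuffled, M) == base


class TestBootstrap:
    def test_unanimous_signal_full_support(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        cols = [{"A": 1, "B": 1}] * 8
        M = matrix_from_columns(taxa, cols)
        support, _ = bootstrap_support(M, ["OUT"], replicates=50, seed=2)
        assert support[frozenset({"A", "B"})] == 100.0

    def test_supports_bounded_and_deterministic(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        rng = np.random.default_rng(11)
        cols = [{x: int(rng.integers(0, 2)) for x in taxa[:4]} for _ in range(10)]
        M = matrix_from_columns(taxa, cols)
        s1, f1 = bootstrap_support(M, ["OUT"], replicates=40, seed=7)
        s2, f2 = bootstrap_support(M, ["OUT"], replicates=40, seed=7)
        assert s1 == s2 and f1 == f2
        for v in s1.values():
            assert 0.0 <= v <= 100.0

    def test_majority_signal_beats_conflicting_signal(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        cols = [{"A": 1, "B": 1}, {"A": 1, "B": 1}, {"B": 1, "C": 1}]
        M = matrix_from_columns(taxa, cols)
        _, freq = bootstrap_support(M, ["OUT"], replicates=200, seed=3)
        table = dict(freq)
        ab = table.get(frozenset({"A", "B"}), 0.0)
        bc = table.get(frozenset({"B", "C"}), 0.0)
        assert ab > bc

    def test_consensus_contains_majority_clade(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        cols = [{"A": 1, "B": 1}] * 5 + [{"C": 1, "D": 1}] * 5
        M = matrix_from_columns(taxa, cols)
        _, freq = bootstrap_support(M, ["OUT"], replicates=50, seed=4)
        cons = majority_rule_consensus(freq, taxa)
        assert frozenset({"A", "B"}) in set(cons.clades())


class TestIndices:
    def test_compatible_matrix_perfect_indices(self):
        taxa = ["A", "B", "C", "D", "OUT"]
        cols = [{"A": 1, "B": 1}, {"A": 1, "B": 1, "C": 1}, {"D": 1}]
        M = matrix_from_columns(taxa, cols)
        best = search_most_parsimonious(M, ["OUT"], mode="exhaustive")
        stats = tree_indices(best.topology, M)
        assert stats["ci"] == 1.0
        assert stats["hi"] == 0.0
        assert stats["ri"] == 1.0

    def test_single_homoplastic_character(self):
        # A=1,C=1 on ((A,B),(C,D)): s=3; star tree g=3; m=1
        taxa = ["A", "B", "C", "D"]
        M = matrix_from_columns(taxa, [{"A": 1, "C": 1}])
        assert dollo_lengths(QUAD, M)[0] == 3
        assert dollo_lengths(star_tree(taxa), M)[0] == 3
        stats = tree_indices(QUAD, M)
        assert stats["ci"] == pytest.approx(1 / 3)
        assert stats["ri"] == pytest.approx(0.0)

    def test_ci_plus_hi_is_one(self):
        taxa = ["A", "B", "C", "D"]
        rng = np.random.default_rng(13)
        for _ in range(10):
            cols = [
                {t: int(rng.integers(0, 2)) for t in taxa} for _ in range(8)
            ]
            M = matrix_from_columns(taxa, cols)
            if not M.variable_mask().any():
                continue
            stats = tree_indices(QUAD, M)
            assert stats["ci"] + stats["hi"] == pytest.approx(1.0)

    def test_all_constant_matrix_undefined(self):
        taxa = ["A", "B", "C", "D"]
        M = matrix_from_columns(taxa, [{t: 1 for t in taxa}, {}])
        with pytest.raises(UndefinedIndicesError):
            tree_indices(QUAD, M)


class TestIO:
    def test_nexus_roundtrip_via_dendropy(self, tmp_path):
        taxa = ["A", "B", "C", "OUT"]
        cols = [{"A": 1, "B": 1}, {"A": 1, "C": -1}]
        states = np.array(
            [[c.get(t, 0) for c in cols] for t in taxa], dtype=np.int8
        )
        states[2, 1] = -1
        M = CharacterMatrix(taxa, ["l1", "l2"], states)
        path = tmp_path / "m.nex"
        write_nexus(M, path)
        text = path.read_text()
        assert "ctype Dollo.up: all" in text
        back = read_nexus(path)
        assert back.taxa == taxa
        assert np.array_equal(back.states, M.states)

    def test_csv_import(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("taxon,l1,l2\nA,1,0\nB,1,1\nC,0,0\n")
        M = read_matrix_csv(path)
        assert M.taxa == ["A", "B", "C"]
        assert M.states[1, 1] == 1
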