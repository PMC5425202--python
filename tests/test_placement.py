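"""Exhaustive placement, ratchet search, suboptimality, position reports."""

import numpy as np
import pytest

from fossilplace.matrix_io import CharacterMatrix, append_characters
from fossilplace.placement import (
    RatchetConfig,
    _restrict_taxa,
    enumerate_placements,
    extra_steps_under_restriction,
    ratchet_search,
    summarize_mp_positions,
)
from fossilplace.scaffold import Scaffold, encode_scaffold, satisfies_scaffold
from fossilplace.simulate import (
    SimulationConfig,
    degrade_matrix,
    random_binary_tree,
    simulate_characters,
)
from fossilplace.trees import parse_newick, same_topology


def scaffold_from(topology, fossil="fossil"):
    return Scaffold(
        topology=topology,
        backbone_taxa=topology.leaf_labels(),
        floating_taxa=frozenset({fossil}),
        source="test",
    )


def simulated_instance(n_backbone, n_chars, seed, branch_length=0.2, fossil_missing=0.0):
    """A (scaffold, fossil, matrix) triple with the fossil's true position known."""
    labels = [f"g{i:02d}" for i in range(n_backbone)] + ["fossil"]
    true_tree = random_binary_tree(labels, seed=seed, branch_length=branch_length)
    config = SimulationConfig(
        tree=true_tree, n_characters=n_chars, n_states=3, seed=seed + 1
    )
    matrix, _ = simulate_characters(config)
    if fossil_missing:
        matrix = degrade_matrix(
            matrix, frozenset(["fossil"]), fossil_missing, 0.0, seed=seed + 2
        )
    backbone = true_tree.prune_leaf("fossil")
    return scaffold_from(backbone), "fossil", matrix, true_tree


class TestEnumerate:
    def test_three_leaf_scaffold_has_three_candidates(self):
        sc = scaffold_from(parse_newick("(A,B,C);"))
        labels = ["A", "B", "C", "fossil"]
        rows = {t: [frozenset([i % 2])] for i, t in enumerate(labels)}
        res = enumerate_placements(sc, "fossil", CharacterMatrix(labels, rows))
        assert len(res.edge_scores) == 3

    def test_edge_count_is_2n_minus_3(self):
        sc, fossil, matrix, _ = simulated_instance(10, 40, seed=3)
        res = enumerate_placements(sc, fossil, matrix)
        assert len(res.edge_scores) == 2 * 10 - 3

    def test_noise_free_recovery_of_pruned_leaf(self):
        sc, fossil, matrix, true_tree = simulated_instance(
            10, 60, seed=11, branch_length=0.05
        )
        res = enumerate_placements(sc, fossil, matrix)
        assert any(same_topology(t, true_tree) for t in res.mp_trees)

    def test_every_mp_tree_complies_with_scaffold(self):
        sc, fossil, matrix, _ = simulated_instance(12, 30, seed=7, fossil_missing=0.5)
        res = enumerate_placements(sc, fossil, matrix)
        assert res.mp_edges
        for tree in res.mp_trees:
            assert satisfies_scaffold(tree, sc)

    def test_soft_and_hard_modes_agree(self):
        for seed in range(5):
            sc, fossil, matrix, _ = simulated_instance(
                8, 25, seed=seed, fossil_missing=0.4
            )
            soft = enumerate_placements(sc, fossil, matrix, mode="soft")
            hard = enumerate_placements(sc, fossil, matrix, mode="hard")
            assert soft.mp_edges == hard.mp_edges
            assert soft.min_morph_length == hard.min_morph_length

    def test_polytomous_scaffold_counts_resolutions(self):
        """A scaffold polytomy is free to resolve; MP trees can outnumber MP edges."""
        topo = parse_newick("(A,B,C,D);")
        sc = scaffold_from(topo)
        labels = ["A", "B", "C", "D", "fossil"]
        # constant characters: every placement and resolution ties
        rows = {t: [frozenset([0])] * 3 for t in labels}
        res = enumerate_placements(sc, "fossil", CharacterMatrix(labels, rows))
        assert len(res.mp_trees) >= len(res.mp_edges)
        assert len(res.mp_trees) == 15  # all binary 5-leaf topologies tie

    def test_errors(self):
        sc, fossil, matrix, _ = simulated_instance(6, 10, seed=1)
        with pytest.raises(ValueError, match="not in matrix"):
            enumerate_placements(sc, "nope", matrix)
        small = _restrict_taxa(matrix, [t for t in matrix.taxa if t != "g00"])
        with pytest.raises(ValueError, match="backbone"):
            enumerate_placements(sc, fossil, small)


class TestRatchet:
    def combined(self, sc, fossil, matrix, weight=99):
        block = encode_scaffold(sc, weight=weight)
        keep = sorted(sc.backbone_taxa | {fossil})
        return append_characters(_restrict_taxa(matrix, keep), block.columns)

    def test_matches_exhaustive_oracle(self):
        """Default-config ratchet attains the exhaustive optimum and MP set."""
        for seed in range(5):
            sc, fossil, matrix, _ = simulated_instance(
                12, 30, seed=100 + seed, fossil_missing=0.3
            )
            exact = enumerate_placements(sc, fossil, matrix)
            combined = self.combined(sc, fossil, matrix)
            found = ratchet_search(
                combined, RatchetConfig(n_sets=4, iterations_per_set=50, seed=seed),
                frozenset([fossil]),
            )
            assert found.min_length == exact.min_length
            assert found.mp_edges == exact.mp_edges
            assert sorted(map(repr, map(lambda t: sorted(map(sorted, t.bipartitions())), found.mp_trees))) == sorted(
                map(repr, map(lambda t: sorted(map(sorted, t.bipartitions())), exact.mp_trees))
            )

    def test_zero_iterations_still_returns_a_result(self):
        sc, fossil, matrix, _ = simulated_instance(8, 20, seed=9)
        combined = self.combined(sc, fossil, matrix)
        res = ratchet_search(
            combined,
            RatchetConfig(n_sets=1, iterations_per_set=0, seed=0),
            frozenset([fossil]),
        )
        assert res.mp_edges
        assert res.min_length <= max(s.total for s in res.edge_scores.values())

    def test_returned_trees_comply(self):
        sc, fossil, matrix, _ = simulated_instance(10, 25, seed=21, fossil_missing=0.4)
        combined = self.combined(sc, fossil, matrix)
        res = ratchet_search(combined, RatchetConfig(n_sets=3, iterations_per_set=30, seed=2), frozenset([fossil]))
        for tree in res.mp_trees:
            assert satisfies_scaffold(tree, sc)

    def test_deterministic_under_seed(self):
        sc, fossil, matrix, _ = simulated_instance(10, 25, seed=33)
        combined = self.combined(sc, fossil, matrix)
        cfg = RatchetConfig(n_sets=2, iterations_per_set=20, seed=5)
        a = ratchet_search(combined, cfg, frozenset([fossil]))
        b = ratchet_search(combined, cfg, frozenset([fossil]))
        assert a.mp_edges == b.mp_edges and a.min_length == b.min_length

    def test_empty_and_multi_fossil_rejected(self):
        sc, fossil, matrix, _ = simulated_instance(8, 20, seed=41)
        combined = self.combined(sc, fossil, matrix)
        with pytest.raises(ValueError):
            ratchet_search(combined, RatchetConfig(), frozenset())
        with pytest.raises(NotImplementedError):
            ratchet_search(combined, RatchetConfig(), frozenset(["fossil", "g00"]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RatchetConfig(perturbation_fraction=0.0)
        with pytest.raises(ValueError):
            RatchetConfig(n_sets=0)


class TestSuboptimality:
    def test_allowed_superset_of_mp_edges_costs_nothing(self):
        sc, fossil, matrix, _ = simulated_instance(10, 30, seed=55)
        res = enumerate_placements(sc, fossil, matrix)
        assert extra_steps_under_restriction(res, res.mp_edges) == 0
        assert extra_steps_under_restriction(res, set(res.edge_scores)) == 0

    def test_matches_edge_score_table(self):
        sc, fossil, matrix, _ = simulated_instance(10, 30, seed=56, fossil_missing=0.3)
        res = enumerate_placements(sc, fossil, matrix)
        worst = max(res.morph_scores, key=lambda e: res.morph_scores[e])
        expected = res.morph_scores[worst] - min(res.morph_scores.values())
        assert extra_steps_under_restriction(res, {worst}) == expected

    def test_unknown_edge_rejected(self):
        sc, fossil, matrix, _ = simulated_instance(8, 20, seed=57)
        res = enumerate_placements(sc, fossil, matrix)
        with pytest.raises(KeyError):
            extra_steps_under_restriction(res, {frozenset({"g00", "zzz"})})


class TestPositionReport:
    def setup_result(self):
        topo = parse_newick("((A,B),((C,D),(E,G)));")
        sc = Scaffold(
            topology=topo,
            backbone_taxa=topo.leaf_labels(),
            floating_taxa=frozenset({"fossil"}),
            source="test",
            clades={"K": frozenset({"C", "D"}), "big": frozenset({"C", "D", "E", "G"})},
        )
        return sc

    def _result_with_mp_edge(self, sc, edge):
        labels = sorted(sc.backbone_taxa | {"fossil"})
        # one character that pulls the fossil onto the requested edge
        side = set(edge)
        rows = {
            t: [frozenset([1]) if t in side or t == "fossil" else frozenset([0])]
            for t in labels
        }
        return enumerate_placements(sc, "fossil", CharacterMatrix(labels, rows))

    def test_stem_edge_reports_sister(self):
        sc = self.setup_result()
        res = self._result_with_mp_edge(sc, frozenset({"C", "D"}))
        report = summarize_mp_positions(res, sc)
        assert any("sister to K" == v for v in report.values())

    def test_internal_edge_reports_within(self):
        sc = self.setup_result()
        res = self._result_with_mp_edge(sc, frozenset({"C"}))
        report = summarize_mp_positions(res, sc)
        assert any(v == "within K" for v in report.values())

    def test_non_clade_rejected(self):
        sc = self.setup_result()
        res = self._result_with_mp_edge(sc, frozenset({"C", "D"}))
        with pytest.raises(ValueError):
            summarize_mp_positions(res, sc, {"bad": frozenset({"A", "C"})})
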