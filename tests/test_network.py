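"""Cosine projection: hand-checked values, brute-force oracle, invariants."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import as_network, make_diary_frame
from leisurenet import (
    build_incidence, cosine_similarity_matrix, project_to_network,
    prune_inactive_nodes,
)
from leisurenet.diary_io import HIGH, IncidenceMatrix
from oracles import cosine_oracle


def incidence_from_binary(binary: np.ndarray, activities=None) -> IncidenceMatrix:
    binary = np.asarray(binary, dtype=float)
    n, m = binary.shape
    activities = activities or [f"act{j}" for j in range(m)]
    return IncidenceMatrix(persons=[f"p{i}" for i in range(n)],
                           activities=list(activities), binary=binary,
                           weights=binary * 30.0, group_label=HIGH,
                           day_type="weekday")


class TestCosineSimilarity:
    def test_identical_columns_have_similarity_one(self):
        inc = incidence_from_binary([[1, 1], [1, 1], [0, 0]])
        _, sim = cosine_similarity_matrix(inc)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_disjoint_columns_have_similarity_zero(self):
        inc = incidence_from_binary([[1, 0], [0, 1]])
        _, sim = cosine_similarity_matrix(inc)
        assert sim[0, 1] == 0.0

    def test_hand_computed_half_overlap(self):
        # participants {1,2} vs {2,3}: dot 1, norms sqrt(2) each -> 0.5
        inc = incidence_from_binary([[1, 0], [1, 1], [0, 1]])
        _, sim = cosine_similarity_matrix(inc)
        assert sim[0, 1] == pytest.approx(0.5)

    def test_diagonal_zero_and_range(self):
        rng = np.random.default_rng(2)
        inc = incidence_from_binary(rng.integers(0, 2, (8, 5)) | [[1, 1, 1, 1, 1]])
        _, sim = cosine_similarity_matrix(inc)
        assert np.all(np.diag(sim) == 0)
        assert np.all((sim >= 0) & (sim <= 1))

    @pytest.mark.parametrize("weighting", ["binary", "minutes"])
    def test_matches_double_loop_oracle(self, weighting):
        """On small random incidences the matrix equals a naive pairwise
        dot/norm computation to 1e-12."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            n, m = rng.integers(2, 7), rng.integers(2, 7)
            cells = rng.integers(0, 2, (n, m)).astype(float)
            cells[:, cells.sum(axis=0) == 0] = 1.0  # no empty columns
            inc = incidence_from_binary(cells)
            labels, sim = cosine_similarity_matrix(inc, weighting=weighting)
            vecs = inc.binary if weighting == "binary" else inc.weights
            expected = cosine_oracle({a: vecs[:, j].tolist()
                                      for j, a in enumerate(labels)})
            for (a, b), value in expected.items():
                i, j = labels.index(a), labels.index(b)
                assert sim[i, j] == pytest.approx(value, abs=1e-12)

    def test_symmetric_regardless_of_column_order(self):
        rng = np.random.default_rng(3)
        cells = rng.integers(0, 2, (10, 6)).astype(float)
        cells[0] = 1
        inc = incidence_from_binary(cells)
        perm = rng.permutation(6)
        inc_perm = incidence_from_binary(cells[:, perm],
                                         activities=[f"act{j}" for j in perm])
        labels, sim = cosine_similarity_matrix(inc)
        labels_p, sim_p = cosine_similarity_matrix(inc_perm)
        assert np.allclose(sim, sim.T, atol=1e-12)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                ip, jp = labels_p.index(a), labels_p.index(b)
                assert sim[i, j] == pytest.approx(sim_p[ip, jp], abs=1e-12)

    def test_person_mode_projection(self):
        inc = incidence_from_binary([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        labels, sim = cosine_similarity_matrix(inc, mode="person")
        assert labels == ["p0", "p1", "p2"]
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == 0.0

    def test_single_activity_warns_and_returns_zero(self):
        inc = incidence_from_binary([[1], [1]])
        with pytest.warns(UserWarning, match="single-node"):
            _, sim = cosine_similarity_matrix(inc)
        assert sim.shape == (1, 1) and sim[0, 0] == 0.0


class TestProjection:
    def test_tau_zero_connects_all_positive_pairs(self):
        inc = incidence_from_binary(np.ones((4, 5)))
        net = project_to_network(inc, tau=0.0)
        assert net.n_edges == 10  # complete graph on 5 nodes

    def test_tau_zero_never_creates_zero_similarity_edges(self):
        inc = incidence_from_binary([[1, 0], [1, 0], [0, 1], [0, 1]])
        net = project_to_network(inc, tau=0.0)
        assert net.n_edges == 0 and net.n_nodes == 2

    def test_tau_one_requires_identical_participant_sets(self):
        inc = incidence_from_binary([[1, 1, 1], [1, 1, 0], [0, 0, 1]])
        net = project_to_network(inc, tau=1.0)
        assert set(map(frozenset, net.graph.edges)) == {frozenset(("act0", "act1"))}

    def test_three_activity_toy_with_mixed_similarities(self):
        """Pairwise similarities {2/3, 0, 0} at tau 0.45: one edge
        survives and the disjoint activity is isolated."""
        inc = incidence_from_binary([
            [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0],
        ])
        labels, sim = cosine_similarity_matrix(inc)
        net = project_to_network(inc, tau=0.45, min_participants=1)
        assert net.n_edges == 1
        assert "act2" in [str(v) for v in net.graph if net.graph.degree(v) == 0]

    def test_min_participants_drops_single_participant_activities(self):
        inc = incidence_from_binary([[1, 1, 0], [1, 0, 0], [1, 0, 0]])
        net = project_to_network(inc, tau=0.0, min_participants=2)
        assert net.removed_low_participation == ["act1", "act2"]
        assert net.nodes == ["act0"]

    def test_edge_weight_carries_similarity_and_respects_tau(self, default_diaries):
        inc = build_incidence(default_diaries, HIGH, "weekday")
        net = project_to_network(inc, tau=0.3)
        labels, sim = cosine_similarity_matrix(inc)
        index = {a: i for i, a in enumerate(labels)}
        for a, b, w in net.graph.edges(data="weight"):
            assert w >= net.threshold_used - 1e-12
            assert w == pytest.approx(sim[index[str(a)], index[str(b)]], abs=1e-12)

    def test_invalid_tau_rejected(self):
        inc = incidence_from_binary([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="tau"):
            project_to_network(inc, tau=1.5)

    def test_tau_monotonicity(self, default_diaries):
        """Raising tau never adds edges, raises density/inclusiveness, or
        removes isolates — on a fixed incidence matrix."""
        from leisurenet import summarize

        inc = build_incidence(default_diaries, HIGH, "weekday")
        last = None
        for tau in np.linspace(0.0, 0.9, 10):
            s = summarize(project_to_network(inc, tau=float(tau)))
            if last is not None:
                assert s.n_edges <= last.n_edges
                assert s.density <= last.density + 1e-12
                assert s.inclusiveness <= last.inclusiveness + 1e-12
                assert s.isolated_count >= last.isolated_count
            last = s


class TestPruneInactiveNodes:
    def test_defaults_are_a_no_op(self):
        net = as_network(nx.path_graph(5))
        pruned, removed = prune_inactive_nodes(net)
        assert removed == [] and pruned.n_nodes == 5

    def test_star_hub_survives_degree_cut(self):
        net = as_network(nx.star_graph(6))  # hub 0 has degree 6, leaves 1
        pruned, removed = prune_inactive_nodes(net, min_degree=2)
        assert pruned.nodes == [0]
        assert sorted(removed) == [1, 2, 3, 4, 5, 6]

    def test_toy_fixture_matches_hand_enumeration(self):
        # degrees: a:1 b:3 c:2 d:2 e:0 -> cut at 2 removes {a, e}
        g = nx.Graph([("a", "b"), ("b", "c"), ("b", "d"), ("c", "d")])
        g.add_node("e")
        pruned, removed = prune_inactive_nodes(as_network(g), min_degree=2)
        assert sorted(removed) == ["a", "e"]
        assert pruned.nodes == ["b", "c", "d"]
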