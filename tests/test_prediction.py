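"""Module detection and function scoring around a target protein."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcprop.data_io import AnnotationMap
from funcprop.prediction import (NoCandidatesError, choose_k, module_fitness,
                                 neighbour_fitness, predict, score_functions,
                                 select_candidates)
from conftest import pn_from_graph, random_weighted_graph, weighted_graph


class TestModuleFitness:
    def test_isolated_clique_is_one(self):
        pn = pn_from_graph(weighted_graph(
            [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]))
        assert module_fitness({"a", "b", "c"}, pn) == 1.0

    def test_three_to_one_split(self):
        # w_in = 3 (internal), w_out = 1 (boundary) -> 0.75
        pn = pn_from_graph(weighted_graph(
            [("a", "b", 1.5), ("a", "c", 1.5), ("c", "x", 1.0)]))
        assert module_fitness({"a", "b", "c"}, pn) == pytest.approx(0.75)

    def test_weightless_module_is_zero(self):
        pn = pn_from_graph(weighted_graph([("a", "b", 1.0)]))
        assert module_fitness({"x", "y"}, pn) == 0.0

    def test_scale_invariance_beta_one(self):
        rng = np.random.default_rng(3)
        g = random_weighted_graph(rng, 12, 0.4)
        pn = pn_from_graph(g)
        g2 = g.copy()
        for a, b in g2.edges:
            g2[a][b]["weight"] *= 7.5
        pn2 = pn_from_graph(g2)
        nodes = sorted(g.nodes)
        for size in (2, 4, 6):
            members = set(nodes[:size])
            f1 = module_fitness(members, pn)
            assert 0.0 <= f1 <= 1.0
            assert f1 == pytest.approx(module_fitness(members, pn2))


class TestNeighbourFitness:
    def test_inward_only_neighbour_positive(self):
        # u ties into a cohesive base and has no outward edges
        pn = pn_from_graph(weighted_graph([
            ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
            ("u", "a", 1.0), ("u", "b", 1.0),
        ]))
        assert neighbour_fitness("u", {"a", "b", "c", "u"}, pn) > 0.0

    def test_isolated_u_zero(self):
        pn = pn_from_graph(weighted_graph([("a", "b", 1.0)]))
        assert neighbour_fitness("z", {"a", "b"}, pn) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_difference(self, seed):
        """Definitional oracle: direct difference of two fitness calls."""
        rng = np.random.default_rng(200 + seed)
        g = random_weighted_graph(rng, int(rng.integers(5, 20)), 0.4)
        pn = pn_from_graph(g)
        nodes = sorted(g.nodes)
        for _ in range(30):
            k = int(rng.integers(1, min(6, len(nodes))))
            base = set(rng.choice(nodes, size=k, replace=False).tolist())
            u = nodes[int(rng.integers(len(nodes)))]
            direct = (module_fitness(base | {u}, pn)
                      - module_fitness(base - {u}, pn))
            assert neighbour_fitness(u, base, pn) == pytest.approx(
                direct, abs=1e-12)


class TestSelectCandidates:
    def test_cohesive_neighbourhood_fully_retained(self):
        # all of v's neighbours mutually connected, no outside edges
        edges = [("v", x, 1.0) for x in "abc"]
        edges += [(x, y, 1.0) for x, y in itertools.combinations("abc", 2)]
        pn = pn_from_graph(weighted_graph(edges))
        mod = select_candidates("v", pn)
        assert mod.members == frozenset("abc")
        assert mod.fitness > 0.0

    def test_outward_heavy_neighbour_removed(self):
        edges = [("v", x, 1.0) for x in ("a", "b", "u")]
        edges += [("a", "b", 1.0)]
        # u hangs off v only and drags heavy weight out of the module
        edges += [("u", f"x{i}", 5.0) for i in range(4)]
        pn = pn_from_graph(weighted_graph(edges))
        mod = select_candidates("v", pn)
        assert "u" not in mod.members
        assert {"a", "b"} <= mod.members

    def test_single_neighbour_component_retained(self):
        pn = pn_from_graph(weighted_graph([("v", "a", 0.8)]))
        mod = select_candidates("v", pn)
        assert mod.members == frozenset({"a"})

    def test_no_neighbours_raises(self):
        pn = pn_from_graph(weighted_graph([("a", "b", 1.0)]))
        with pytest.raises(NoCandidatesError):
            select_candidates("z", pn)

    def test_invariant_to_edge_storage_order(self):
        rng = np.random.default_rng(4)
        g = random_weighted_graph(rng, 15, 0.4)
        pn1 = pn_from_graph(g)
        g2 = weighted_graph([(b, a, d["weight"])
                             for a, b, d in reversed(list(g.edges(data=True)))])
        pn2 = pn_from_graph(g2)
        for v in sorted(g.nodes):
            if g.degree(v) == 0:
                continue
            assert (select_candidates(v, pn1).members
                    == select_candidates(v, pn2).members)

    def test_sign_scale_invariance(self):
        rng = np.random.default_rng(12)
        g = random_weighted_graph(rng, 12, 0.5)
        g2 = g.copy()
        for a, b in g2.edges:
            g2[a][b]["weight"] *= 3.0
        pn1, pn2 = pn_from_graph(g), pn_from_graph(g2)
        for v in sorted(g.nodes):
            if g.degree(v):
                assert (select_candidates(v, pn1).members
                        == select_candidates(v, pn2).members)


class TestScoreFunctions:
    def test_single_candidate(self):
        pn = pn_from_graph(weighted_graph([("v", "u", 0.7)]))
        go = AnnotationMap({"u": {"f1"}})
        assert score_functions("v", {"u"}, pn, go) == [("f1", 0.7)]

    def test_weighted_vote(self):
        pn = pn_from_graph(weighted_graph([("v", "u1", 0.3), ("v", "u2", 0.5)]))
        go = AnnotationMap({"u1": {"f1"}, "u2": {"f1", "f2"}})
        assert score_functions("v", {"u1", "u2"}, pn, go) == [
            ("f1", pytest.approx(0.8)), ("f2", 0.5)]

    def test_unannotated_functions_absent(self):
        pn = pn_from_graph(weighted_graph([("v", "u", 0.7)]))
        go = AnnotationMap({"w": {"f9"}})
        assert score_functions("v", {"u"}, pn, go) == []


class TestChooseK:
    def test_nearest_neighbour_count(self):
        pn = pn_from_graph(weighted_graph([("v", "a", 0.9), ("v", "b", 0.2)]))
        go = AnnotationMap({"a": {"f1", "f2", "f3"}, "b": {"f4"}})
        assert choose_k("v", pn, go) == 3

    def test_tie_broken_by_larger_annotation_count(self):
        pn = pn_from_graph(weighted_graph([("v", "a", 0.9), ("v", "b", 0.9)]))
        go = AnnotationMap({"a": {"f1", "f2"}, "b": {"f3", "f4", "f5", "f6"}})
        assert choose_k("v", pn, go) == 4

    def test_nearest_annotated_wins_over_nearest(self):
        pn = pn_from_graph(weighted_graph([("v", "near", 0.95),
                                           ("v", "ann", 0.5)]))
        go = AnnotationMap({"ann": {"f1", "f2"}})
        assert choose_k("v", pn, go) == 2

    def test_no_annotated_neighbour_raises(self):
        pn = pn_from_graph(weighted_graph([("v", "a", 0.9)]))
        with pytest.raises(NoCandidatesError):
            choose_k("v", pn, AnnotationMap({}))


class TestPredict:
    def _planted_pn(self):
        # one tight module {m1,m2,m3,v} sharing {f1,f2}; one distractor
        edges = [("v", "m1", 0.9), ("v", "m2", 0.8), ("v", "m3", 0.7),
                 ("m1", "m2", 0.9), ("m1", "m3", 0.8), ("m2", "m3", 0.9),
                 ("v", "d", 0.1), ("d", "x1", 0.9), ("d", "x2", 0.9)]
        go = AnnotationMap({"m1": {"f1", "f2"}, "m2": {"f1", "f2"},
                            "m3": {"f1", "f2", "f9"}, "d": {"f3"}})
        return pn_from_graph(weighted_graph(edges)), go

    def test_planted_module_functions_recovered(self):
        pn, go = self._planted_pn()
        rec = predict("v", pn, go)
        assert {"f1", "f2"} <= rec.predicted
        assert "f3" not in rec.predicted
        assert "d" not in rec.candidates

    def test_k_larger_than_positive_scores(self):
        # the K-defining neighbour (most similar, 3 annotations) is pruned
        # from the module for dragging weight outward, so only one
        # positive-score function remains and |predicted| < K
        edges = [("v", "d", 0.9), ("v", "u", 0.7), ("v", "w", 0.6),
                 ("u", "w", 0.9)]
        edges += [("d", f"x{i}", 5.0) for i in range(4)]
        pn = pn_from_graph(weighted_graph(edges))
        go = AnnotationMap({"d": {"g1", "g2", "g3"}, "u": {"f1"},
                            "w": {"f1"}})
        rec = predict("v", pn, go)
        assert rec.k == 3
        assert "d" not in rec.candidates
        assert rec.predicted == {"f1"}
        assert len(rec.predicted) == min(rec.k, len(rec.candidate_functions))

    def test_determinism(self):
        pn, go = self._planted_pn()
        r1 = predict("v", pn, go)
        r2 = predict("v", pn, go)
        assert r1 == r2


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=15)
def test_module_selection_deterministic_under_reconstruction(seed):
    rng = np.random.default_rng(seed)
    g = random_weighted_graph(rng, 10, 0.5)
    pn1 = pn_from_graph(g)
    pn2 = pn_from_graph(g.copy())
    for v in g.nodes:
        if g.degree(v):
            assert (select_candidates(v, pn1).members
                    == select_candidates(v, pn2).members)
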