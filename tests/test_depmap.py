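import itertools

import pytest

from fluxredirect import (
    Design,
    dependency_graph,
    derive_enzyme_groups,
    evaluate_design,
    map_dependencies,
)
from fluxredirect.depmap import DependencySet, PoolTarget
from fluxredirect.library import CoefficientLibrary, LibraryEntry
from fluxredirect.toys import TOY_EXPORT

TOL = 1e-6


@pytest.fixture(scope="module")
def t4_groups(t4):
    return {g.group_id: g for g in derive_enzyme_groups(t4)}


@pytest.fixture(scope="module")
def t4_pool():
    return [
        PoolTarget("enzb", 1, 1.0, "flat"),
        PoolTarget("enzd", -1, -1.0, "flat"),
        PoolTarget("upta", 1, 1.0, "flat"),
    ]


class TestMapDependencies:
    def test_drain_toy_needs_the_pair(self, t4, t4_groups, t4_pool):
        sets = map_dependencies(
            t4, t4_pool, 2, TOY_EXPORT, t4_groups, max_production=10.0
        )
        assert [sorted(s.members) for s in sets] == [
            [("enzb", 1), ("enzd", -1)]
        ]
        assert sets[0].production == pytest.approx(10.0, abs=TOL)
        assert sets[0].labels == ("flat",)

    def test_no_singleton_qualifies_on_drain_toy(self, t4, t4_groups, t4_pool):
        sets = map_dependencies(
            t4, t4_pool, 1, TOY_EXPORT, t4_groups, max_production=10.0
        )
        assert sets == []

    def test_sufficient_singleton_suppresses_non_improving_pairs(self, t1):
        groups = {g.group_id: g for g in derive_enzyme_groups(t1)}
        pool = [PoolTarget("enzp", 1, 1.0), PoolTarget("enzb", 1, 1.0)]
        sets = map_dependencies(t1, pool, 2, TOY_EXPORT, groups, max_production=10.0)
        # each singleton already reaches full production; the pair cannot
        # strictly improve and is not reported
        assert {frozenset(s.members) for s in sets} == {
            frozenset({("enzp", 1)}), frozenset({("enzb", 1)}),
        }

    def test_every_reported_set_beats_all_proper_subsets(self, t4, t4_groups, t4_pool):
        sets = map_dependencies(
            t4, t4_pool, 3, TOY_EXPORT, t4_groups, max_production=10.0
        )
        lib = CoefficientLibrary(
            [LibraryEntry(t.group_id, f"p{i}", t.beta) for i, t in enumerate(t4_pool)],
            t4_groups,
        )
        key = {(t.group_id, t.sign): (t.group_id, f"p{i}") for i, t in enumerate(t4_pool)}
        for s in sets:
            members = sorted(s.members)
            for r in range(len(members)):
                for sub in itertools.combinations(members, r):
                    design = Design(frozenset(key[m] for m in sub))
                    _, sub_prod = evaluate_design(
                        t4, design, 0.02, lib, TOY_EXPORT
                    )
                    assert s.production > sub_prod + TOL / 10

    def test_pool_order_invariance(self, t4, t4_groups, t4_pool):
        forward = map_dependencies(
            t4, t4_pool, 2, TOY_EXPORT, t4_groups, max_production=10.0
        )
        backward = map_dependencies(
            t4, list(reversed(t4_pool)), 2, TOY_EXPORT, t4_groups, max_production=10.0
        )
        assert forward == backward

    def test_subset_enumeration_count(self, t4, t4_groups, t4_pool, monkeypatch):
        calls = {"n": 0}
        import fluxredirect.depmap as dm

        original = dm.evaluate_design

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(dm, "evaluate_design", counting)
        map_dependencies(t4, t4_pool, 2, TOY_EXPORT, t4_groups, max_production=10.0)
        # baseline + C(3,1) + C(3,2); no same-group sign conflicts in this pool
        assert calls["n"] == 1 + 3 + 3

    def test_invalid_subset_bound_rejected(self, t4, t4_groups, t4_pool):
        with pytest.raises(ValueError):
            map_dependencies(t4, t4_pool, 0, TOY_EXPORT, t4_groups)


class TestDependencyGraph:
    def test_single_and_pair_roles(self):
        sets = [
            DependencySet(frozenset({("a", 1)}), 10.0),
            DependencySet(frozenset({("a", 1), ("b", -1)}), 12.0),
        ]
        graph = dependency_graph(sets, max_production=12.0)
        assert graph.nodes["a[+]"]["role"] == "alone"
        assert graph.nodes["b[-]"]["role"] == "pair_only"
        assert graph.has_edge("a[+]", "b[-]")

    def test_high_production_edges_flagged_at_90pct(self):
        sets = [
            DependencySet(frozenset({("a", 1), ("b", 1)}), 9.5),
            DependencySet(frozenset({("a", 1), ("c", -1)}), 5.0),
        ]
        graph = dependency_graph(sets, max_production=10.0)
        assert graph.edges["a[+]", "b[+]"]["high_production"] is True
        assert graph.edges["a[+]", "c[-]"]["high_production"] is False

    def test_triples_do_not_enter_the_graph(self):
        sets = [DependencySet(frozenset({("a", 1), ("b", 1), ("c", 1)}), 8.0)]
        graph = dependency_graph(sets, max_production=10.0)
        assert len(graph) == 0

    def test_empty_input_gives_empty_graph(self):
        graph = dependency_graph([], max_production=1.0)
        assert len(graph) == 0 and graph.number_of_edges() == 0
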