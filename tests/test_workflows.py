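"""Batch comparison workflows: cardinalities, filtering, graph construction."""

import numpy as np
import pytest

from cmlink.scoring import best_sequence
from cmlink.toymodels import (
    CLAN_THRESHOLD,
    ToyModelSpec,
    build_toy_cm,
    clan_fixture,
    random_toy_spec,
)
from cmlink.workflows import (
    FilterSpec,
    LinkTable,
    TableMode,
    build_link_graph,
    clan_components,
    compare_all_vs_all,
    compare_one_vs_many,
    filter_results,
)


@pytest.fixture(scope="module")
def five_toys():
    rng = np.random.default_rng(555)
    return [
        build_toy_cm(
            random_toy_spec(rng, min_len=2, max_len=4, allow_bif=False, name=f"m{i}")
        )
        for i in range(5)
    ]


@pytest.fixture(scope="module")
def all_vs_all_table(five_toys):
    return compare_all_vs_all(five_toys)


class TestOneVsMany:
    def test_cardinality_one_query(self, five_toys):
        t = compare_one_vs_many(five_toys[:1], five_toys[1:4])
        assert len(t.entries) == 3
        assert t.mode is TableMode.ONE_VS_MANY

    def test_query_against_own_copy_links_at_best_score(self, five_toys):
        q = five_toys[0]
        t = compare_one_vs_many([q], five_toys[:3])
        self_entry = next(
            e for e in t.entries if e.model_a == q.name and e.model_b == q.name
        )
        assert self_entry.link_score == pytest.approx(
            best_sequence(q).score, abs=1e-6
        )

    def test_two_queries_times_five(self, five_toys):
        rng = np.random.default_rng(556)
        queries = [
            build_toy_cm(random_toy_spec(rng, max_len=3, name=f"q{i}"))
            for i in range(2)
        ]
        t = compare_one_vs_many(queries, five_toys)
        assert len(t.entries) == 10
        # role-swapped recomputation agrees pair by pair
        t2 = compare_one_vs_many(five_toys, queries)
        fwd = {(e.model_a, e.model_b): e.link_score for e in t.entries}
        for e in t2.entries:
            assert e.link_score == pytest.approx(
                fwd[(e.model_b, e.model_a)], abs=1e-6
            )

    def test_bad_model_recorded_not_fatal(self, five_toys):
        import copy

        broken = copy.deepcopy(five_toys[1])
        broken.states[0].transitions[99] = -1.0
        t = compare_one_vs_many(five_toys[:1], [five_toys[2], broken, five_toys[3]])
        assert len(t.entries) == 2
        assert len(t.errors) >= 1

    def test_empty_inputs_rejected(self, five_toys):
        with pytest.raises(ValueError):
            compare_one_vs_many([], five_toys)


class TestAllVsAll:
    def test_cardinality_choose_two(self, all_vs_all_table):
        assert len(all_vs_all_table.entries) == 10
        pairs = {(e.model_a, e.model_b) for e in all_vs_all_table.entries}
        assert len(pairs) == 10  # every unordered pair exactly once

    def test_two_identical_models_single_entry(self):
        a = build_toy_cm(ToyModelSpec("ACG", "...", seed=1, name="a"))
        b = build_toy_cm(ToyModelSpec("ACG", "...", seed=1, name="b"))
        t = compare_all_vs_all([a, b])
        assert len(t.entries) == 1
        assert t.entries[0].link_score == pytest.approx(
            best_sequence(a).score, abs=1e-6
        )

    def test_invariant_under_input_permutation(self, five_toys, all_vs_all_table):
        t2 = compare_all_vs_all(list(reversed(five_toys)))
        ref = {
            frozenset((e.model_a, e.model_b)): e.link_score
            for e in all_vs_all_table.entries
        }
        for e in t2.entries:
            key = frozenset((e.model_a, e.model_b))
            assert e.link_score == pytest.approx(ref[key], abs=1e-6)

    def test_fewer_than_two_models_rejected(self, five_toys):
        with pytest.raises(ValueError):
            compare_all_vs_all(five_toys[:1])


class TestFiltering:
    def test_empty_filter_keeps_everything(self, all_vs_all_table):
        t = filter_results(all_vs_all_table, FilterSpec())
        assert len(t.entries) == len(all_vs_all_table.entries)

    def test_threshold_above_max_empties_table(self, all_vs_all_table):
        top = max(e.link_score for e in all_vs_all_table.entries)
        t = filter_results(all_vs_all_table, FilterSpec(min_link_score=top + 1))
        assert t.entries == []

    def test_top_n_matches_independent_sort(self, all_vs_all_table):
        t = filter_results(all_vs_all_table, FilterSpec(top_n=5))
        expected = sorted(
            (e.link_score for e in all_vs_all_table.entries), reverse=True
        )[:5]
        assert [e.link_score for e in t.entries] == expected

    def test_name_pattern_case_insensitive(self, all_vs_all_table):
        t = filter_results(all_vs_all_table, FilterSpec(name_pattern="M0"))
        assert t.entries
        assert all("m0" in (e.model_a + e.model_b) for e in t.entries)

    def test_idempotent(self, all_vs_all_table):
        spec = FilterSpec(min_link_score=0.0, top_n=4)
        once = filter_results(all_vs_all_table, spec)
        twice = filter_results(once, spec)
        assert [
            (e.model_a, e.model_b, e.link_score) for e in once.entries
        ] == [(e.model_a, e.model_b, e.link_score) for e in twice.entries]

    def test_top_n_must_be_positive(self):
        with pytest.raises(ValueError):
            FilterSpec(top_n=0)


class TestGraph:
    def test_no_surviving_entries_keeps_isolated_nodes(self, all_vs_all_table):
        top = max(e.link_score for e in all_vs_all_table.entries)
        g = build_link_graph(all_vs_all_table, FilterSpec(min_link_score=top + 1))
        assert g.nodes == all_vs_all_table.models
        assert g.edges == []

    def test_edge_weights_trace_to_table_entries(self, all_vs_all_table):
        g = build_link_graph(all_vs_all_table, FilterSpec())
        ref = {
            frozenset((e.model_a, e.model_b)): e.link_score
            for e in all_vs_all_table.entries
        }
        assert len(g.edges) == len(ref)
        for a, b, w in g.edges:
            assert w == ref[frozenset((a, b))]

    def test_clan_fixture_satellite_has_degree_one(self, clan_table):
        g = build_link_graph(
            clan_table, FilterSpec(min_link_score=CLAN_THRESHOLD)
        ).to_networkx()
        assert g.degree["sat"] == 1
        assert set(g["sat"]) == {"t1"}

    def test_clan_components_recover_partition(self, clan_table):
        # above the satellite's link: clan clique separates from the satellite
        g = build_link_graph(clan_table, FilterSpec(min_link_score=9.0))
        comps = clan_components(g)
        assert {"t1", "t2", "t3", "t4"} in comps
        assert {"sat"} in comps
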