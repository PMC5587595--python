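"""MIS, all possible inputs, substituting sets, swaps and classification."""

import pytest

from netctrl import synthgen
from netctrl.all_inputs import (
    ALWAYS_INPUT,
    NEVER_INPUT,
    SOMETIMES_INPUT,
    PerfectMatchingError,
    all_possible_inputs,
    classify_nodes,
    control_profile,
    find_mis,
    substituting_sets,
    substitutability_profile,
    swap_mis,
)
from netctrl.graph_core import DirectedNetwork, to_bipartite
from netctrl.matching import Matching
from netctrl.oracle import union_of_unmatched, verify_mis


def forced_demo_matching(g):
    """The documented maximum matching of the 10-node demo: MIS {4, 10}."""
    m = Matching.empty(g.N)
    for s, t in [
        ("1", "2"), ("2", "3"), ("3", "1"), ("4", "5"),
        ("5", "6"), ("6", "7"), ("7", "8"), ("8", "9"),
    ]:
        u, v = g.label_index[s], g.label_index[t]
        m.mate_of_out[u] = v
        m.mate_of_in[v] = u
    return m


class TestFindMis:
    def test_star_mis_is_one_of_the_two_valid_sets(self, star3):
        _, mis, perfect = find_mis(star3)
        assert not perfect
        assert mis in ({"1", "3"}, {"1", "2"})
        assert verify_mis(star3, mis)

    def test_path_has_unique_mis(self, path3):
        _, mis, perfect = find_mis(path3)
        assert mis == {"1"} and not perfect

    def test_two_cycle_perfect_matching_canonical_choice(self):
        g = synthgen.fixture("cycle2")
        _, mis, perfect = find_mis(g)
        assert perfect and mis == {"1"}

    def test_mis_size_law(self):
        for i in range(300):
            g = synthgen.random_small_digraph(10, (0.05, 0.9), seed=110_000 + i)
            m, mis, perfect = find_mis(g)
            assert len(mis) == max(g.N - m.size, 1)
            assert perfect == (m.size == g.N)


class TestAllPossibleInputs:
    def test_demo_network_possible_inputs(self, demo10):
        assert all_possible_inputs(demo10) == {"4", "6", "8", "9", "10"}

    def test_diamond_excludes_sink(self, diamond):
        assert all_possible_inputs(diamond) == {"1", "2", "3"}

    def test_star(self, star3):
        assert all_possible_inputs(star3) == {"1", "2", "3"}

    def test_perfect_matching_returns_every_node(self):
        assert all_possible_inputs(synthgen.fixture("cycle2")) == {"1", "2"}

    def test_equals_enumeration_union_on_random_graphs(self):
        for i in range(300):
            g = synthgen.random_small_digraph(8, (0.05, 0.9), seed=120_000 + i)
            assert all_possible_inputs(g) == union_of_unmatched(g)


class TestSubstitutingSets:
    def test_demo_network_k_sets(self, demo10):
        m = forced_demo_matching(demo10)
        subs = substituting_sets(demo10, m)
        assert subs == {"4": {"6", "8"}, "10": {"9"}}

    def test_star_k_sets(self, star3):
        i = star3.label_index
        m = Matching.empty(3)
        m.mate_of_out[i["1"]] = i["2"]
        m.mate_of_in[i["2"]] = i["1"]
        subs = substituting_sets(star3, m)
        assert subs == {"1": set(), "3": {"2"}}

    def test_path_input_has_no_substitutes(self, path3):
        prof = control_profile(path3)
        assert prof.substitutes == {"1": frozenset()}

    def test_input_node_not_in_its_own_k_set(self):
        for i in range(200):
            g = synthgen.random_small_digraph(10, (0.05, 0.9), seed=130_000 + i)
            prof = control_profile(g)
            if prof.perfect_matching:
                continue
            for m_lab, k in prof.substitutes.items():
                assert m_lab not in k

    def test_perfect_matching_raises(self):
        g = synthgen.fixture("cycle2")
        m, _, perfect = find_mis(g)
        assert perfect
        with pytest.raises(PerfectMatchingError, match="perfect"):
            substituting_sets(g, m)

    def test_mis_union_ksets_equals_possible_inputs(self):
        for i in range(200):
            g = synthgen.random_small_digraph(9, (0.05, 0.9), seed=140_000 + i)
            prof = control_profile(g)
            if prof.perfect_matching:
                continue
            union = set(prof.mis)
            for k in prof.substitutes.values():
                union |= k
            assert union == set(prof.possible_inputs)


class TestSwapMis:
    def test_demo_swaps_match_documented_sets(self, demo10):
        m = forced_demo_matching(demo10)
        _, mis1 = swap_mis(demo10, m, "4", "8")
        assert mis1 == {"8", "10"}
        _, mis2 = swap_mis(demo10, m, "4", "6")
        assert mis2 == {"6", "10"}

    def test_star_swap(self, star3):
        i = star3.label_index
        m = Matching.empty(3)
        m.mate_of_out[i["1"]] = i["2"]
        m.mate_of_in[i["2"]] = i["1"]
        m2, mis = swap_mis(star3, m, "3", "2")
        assert mis == {"1", "2"}
        assert m2.mate_of_out[i["1"]] == i["3"]
        assert verify_mis(star3, mis)

    def test_swap_is_involutive_on_the_same_path(self, demo10):
        m = forced_demo_matching(demo10)
        m2, mis2 = swap_mis(demo10, m, "4", "8")
        m3, mis3 = swap_mis(demo10, m2, "8", "4")
        assert mis3 == {"4", "10"}
        assert m3.size == m.size

    def test_swap_with_non_substitute_raises(self, demo10):
        m = forced_demo_matching(demo10)
        with pytest.raises(ValueError, match="not a substitute"):
            swap_mis(demo10, m, "4", "9")

    def test_every_swap_yields_valid_mis_and_maximum_matching(self):
        from netctrl.matching import is_maximum

        for i in range(150):
            g = synthgen.random_small_digraph(8, (0.05, 0.9), seed=150_000 + i)
            b = to_bipartite(g)
            prof = control_profile(g)
            if prof.perfect_matching:
                continue
            from netctrl.matching import hopcroft_karp

            m, _ = hopcroft_karp(b)
            for m_lab, k in substituting_sets(g, m, b=b).items():
                for n_lab in k:
                    m2, mis2 = swap_mis(g, m, m_lab, n_lab, b=b)
                    assert m2.size == m.size
                    m2.validate(b)
                    assert is_maximum(b, m2)
                    assert mis2 == (set(prof_mis(m, g)) - {m_lab}) | {n_lab}
                    assert verify_mis(g, mis2)


def prof_mis(m, g):
    return {g.labels[v] for v in m.unmatched_in()}


class TestClassifyNodes:
    def test_path(self, path3):
        assert classify_nodes(path3) == {
            "1": ALWAYS_INPUT,
            "2": NEVER_INPUT,
            "3": NEVER_INPUT,
        }

    def test_diamond(self, diamond):
        assert classify_nodes(diamond) == {
            "1": ALWAYS_INPUT,
            "2": SOMETIMES_INPUT,
            "3": SOMETIMES_INPUT,
            "4": NEVER_INPUT,
        }

    def test_star(self, star3):
        assert classify_nodes(star3) == {
            "1": ALWAYS_INPUT,
            "2": SOMETIMES_INPUT,
            "3": SOMETIMES_INPUT,
        }

    def test_perfect_matching_all_sometimes(self):
        assert set(classify_nodes(synthgen.fixture("cycle2")).values()) == {
            SOMETIMES_INPUT
        }

    def test_always_means_in_every_enumerated_mis(self):
        """always_input <=> unmatched in EVERY maximum matching (oracle)."""
        from netctrl.graph_core import to_bipartite
        from netctrl.oracle import enumerate_maximum_matchings

        for i in range(200):
            g = synthgen.random_small_digraph(7, (0.05, 0.9), seed=160_000 + i)
            b = to_bipartite(g)
            classes = classify_nodes(g)
            all_mis = [
                {g.labels[v] for v in m.unmatched_in()}
                for m in enumerate_maximum_matchings(b)
            ]
            if not all_mis[0] and len(all_mis) == 1 and g.N > 1:
                continue  # perfect matching: convention covered elsewhere
            in_every = set.intersection(*map(set, all_mis)) if all_mis[0] else set()
            for lab, cls in classes.items():
                if g.N == 1:
                    assert cls == ALWAYS_INPUT
                    continue
                assert (cls == ALWAYS_INPUT) == (lab in in_every)


class TestSubstitutabilityProfile:
    def test_demo_profile_ranked(self, demo10):
        m = forced_demo_matching(demo10)
        subs = substituting_sets(demo10, m)
        from netctrl.all_inputs import ControlProfile

        prof = ControlProfile(
            n=demo10.N,
            l=demo10.L,
            matching_size=m.size,
            perfect_matching=False,
            mis=frozenset({"4", "10"}),
            possible_inputs=frozenset({"4", "6", "8", "9", "10"}),
            substitutes={k: frozenset(v) for k, v in subs.items()},
        )
        assert substitutability_profile(prof) == [
            ("4", 2, 0.2),
            ("10", 1, 0.1),
        ]

    def test_path_profile(self, path3):
        prof = control_profile(path3)
        assert substitutability_profile(prof) == [("1", 0, 0.0)]

    def test_ties_share_s_and_break_by_label(self, star3):
        g = DirectedNetwork.from_labeled_edges(
            [("1", "2"), ("3", "2"), ("1", "4"), ("3", "4")]
        )
        prof = control_profile(g)
        rows = substitutability_profile(prof)
        sizes = [s for _, s, _ in rows]
        assert sizes == sorted(sizes, reverse=True)
        labels_with_equal_s = [
            [lab for lab, s, _ in rows if s == val] for val in set(sizes)
        ]
        for group in labels_with_equal_s:
            assert group == sorted(group)
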