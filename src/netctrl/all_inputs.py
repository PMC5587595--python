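"""All possible input nodes, substituting sets and MIS swaps.

A Minimum Input Set (MIS) of a directed network is the set of in-nodes left
unmatched by any one maximum matching.  Because maximum matchings are not
unique, many MISs may exist; the nodes appearing in at least one MIS are the
*possible input nodes*.  The central fact exploited here: given ONE maximum
matching M with unmatched in-nodes D,

1. every member of D is a possible input node, and
2. a matched node n is a possible input node iff n^in is reachable from some
   m^in (m in D) through an even alternating path.

Sufficiency is constructive: flipping the matched/unmatched status of every
edge on that path yields another maximum matching whose unmatched set is
D - {m} + {n}; so the reachable nodes from m^in are exactly the nodes that
can *substitute* m one-for-one in the MIS (the set K_m).  Necessity follows
from the symmetric difference of M with any matching that leaves n
unmatched.  Hence one matching plus one alternating BFS gives the union of
all MISs without enumerating them.

If the matching is perfect there are no unmatched in-nodes; a single input
node then suffices and it can be ANY node, so every node is a possible
input.  The canonical MIS reported in that case is the smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from netctrl.graph_core import BipartiteGraph, DirectedNetwork, to_bipartite
from netctrl.matching import (
    UNMATCHED,
    Matching,
    alternating_reachability,
    hopcroft_karp,
)

ALWAYS_INPUT = "always_input"
SOMETIMES_INPUT = "sometimes_input"
NEVER_INPUT = "never_input"


class PerfectMatchingError(ValueError):
    """Raised when substituting sets are requested for a perfect matching.

    With a perfect matching any single node is a valid MIS on its own, so
    per-input substituting sets are not defined; callers should use the
    perfect-matching convention (possible inputs = all nodes) instead.
    """


@dataclass
class ControlProfile:
    """Full controllability profile of one directed network.

    Substituting sets are reported relative to the single computed matching;
    other maximum matchings may assign the same substitute to a different
    input node, and only ``possible_inputs`` (the union) is
    matching-invariant.
    """

    n: int
    l: int
    matching_size: int
    perfect_matching: bool
    mis: frozenset[str]
    possible_inputs: frozenset[str]
    substitutes: dict[str, frozenset[str]] | None

    @property
    def n_pd(self) -> float:
        """Density of possible input nodes, |union of all MISs| / N."""
        return len(self.possible_inputs) / self.n

    def ranked_profile(self) -> list[tuple[str, int, float]]:
        """(input label, s_i, p_i = s_i/N), sorted by s_i descending.

        Ties are broken by ascending label.  Empty for perfect matchings.
        """
        if self.substitutes is None:
            return []
        rows = [(m, len(k), len(k) / self.n) for m, k in self.substitutes.items()]
        rows.sort(key=lambda r: (-r[1], r[0]))
        return rows


def find_mis(
    g: DirectedNetwork, greedy_init: bool = False
) -> tuple[Matching, frozenset[str], bool]:
    """One maximum matching and the MIS it induces.

    Returns (matching, mis_labels, perfect).  The MIS is the unmatched
    in-node set; for a perfect matching the convention is the single
    smallest label (any node works).
    """
    b = to_bipartite(g)
    m, _reach = hopcroft_karp(b, greedy_init=greedy_init)
    unmatched = m.unmatched_in()
    if not unmatched:
        return m, frozenset({min(g.labels)}), True
    return m, frozenset(g.labels[v] for v in unmatched), False


def all_possible_inputs(g: DirectedNetwork) -> frozenset[str]:
    """Union of all MISs, from a single maximum matching.

    The in-nodes reachable by alternating paths from the unmatched in-nodes
    (roots included) are exactly the nodes some maximum matching leaves
    unmatched; under a perfect matching every node qualifies.
    """
    b = to_bipartite(g)
    m, reach = hopcroft_karp(b)
    if m.size == g.N:
        return frozenset(g.labels)
    return frozenset(g.labels[v] for v in reach.reached_in)


def substituting_sets(
    g: DirectedNetwork, m: Matching, b: BipartiteGraph | None = None
) -> dict[str, frozenset[str]]:
    """K_m for every input node m: the nodes that can replace m in the MIS.

    Computed by one alternating BFS per root, so a node reachable from two
    roots appears in both K-sets.  The input node itself is excluded (it
    trivially substitutes itself).
    """
    if b is None:
        b = to_bipartite(g)
    roots = m.unmatched_in()
    if not roots:
        raise PerfectMatchingError(
            "perfect matching: any single node is an MIS; substituting sets "
            "are undefined (see the perfect-matching convention)"
        )
    out: dict[str, frozenset[str]] = {}
    for r in roots:
        reach = alternating_reachability(b, m, roots=[r])
        out[g.labels[r]] = frozenset(
            g.labels[v] for v in reach.reached_in if v != r
        )
    return out


def swap_mis(
    g: DirectedNetwork,
    m: Matching,
    m_label: str,
    n_label: str,
    b: BipartiteGraph | None = None,
) -> tuple[Matching, frozenset[str]]:
    """Replace input node m by a substitute n, flipping one alternating path.

    Requires n in K_m.  The even alternating path from m^in to n^in has its
    matched and unmatched edges exchanged, producing a new maximum matching
    of the same size whose unmatched in-nodes are (MIS - {m}) + {n}.
    """
    if b is None:
        b = to_bipartite(g)
    mi = g.label_index[m_label]
    ni = g.label_index[n_label]
    if m.mate_of_in[mi] != UNMATCHED:
        raise ValueError(f"{m_label!r} is not an input node of this matching")
    reach = alternating_reachability(b, m, roots=[mi])
    if ni == mi or ni not in reach.reached_in:
        raise ValueError(
            f"{n_label!r} is not a substitute of input node {m_label!r}"
        )
    path = reach.path_to(ni, m)  # [m^in, o_1, v_1, ..., o_k, n^in]
    new = m.copy()
    # flip: each out-node on the path re-pairs with the in-node BEFORE it
    new.mate_of_in[ni] = UNMATCHED
    for i in range(1, len(path), 2):
        o = path[i]
        v_prev = path[i - 1]
        new.mate_of_in[v_prev] = o
        new.mate_of_out[o] = v_prev
    unmatched = new.unmatched_in()
    return new, frozenset(g.labels[v] for v in unmatched)


def classify_nodes(g: DirectedNetwork) -> dict[str, str]:
    """Partition nodes into always / sometimes / never input.

    always_input: in every MIS (an input node with an empty substituting
    set); never_input: in no MIS; sometimes_input: the rest.  Under a
    perfect matching every node is sometimes_input (any single node is a
    valid MIS, and no node is in all of them once N > 1).
    """
    profile = control_profile(g)
    if profile.perfect_matching:
        if g.N == 1:
            return {g.labels[0]: ALWAYS_INPUT}
        return {lab: SOMETIMES_INPUT for lab in g.labels}
    out: dict[str, str] = {}
    subs = profile.substitutes or {}
    for lab in g.labels:
        if lab not in profile.possible_inputs:
            out[lab] = NEVER_INPUT
        elif lab in profile.mis and not subs[lab]:
            out[lab] = ALWAYS_INPUT
        else:
            out[lab] = SOMETIMES_INPUT
    return out


def substitutability_profile(
    profile: ControlProfile,
) -> list[tuple[str, int, float]]:
    """Ranked substitutability of each input node: (label, s_i, p_i=s_i/N)."""
    return profile.ranked_profile()


def control_profile(
    g: DirectedNetwork, with_substitutes: bool = True
) -> ControlProfile:
    """Compute the full profile: MIS, all possible inputs, substituting sets.

    ``with_substitutes=False`` skips the per-root BFS sweep (which costs
    O(|MIS| * L) in the worst case) and reports ``substitutes=None``; the
    MIS and possible-input set are unaffected.
    """
    b = to_bipartite(g)
    m, reach = hopcroft_karp(b)
    size = m.size
    if size == g.N:
        return ControlProfile(
            n=g.N,
            l=g.L,
            matching_size=size,
            perfect_matching=True,
            mis=frozenset({min(g.labels)}),
            possible_inputs=frozenset(g.labels),
            substitutes=None,
        )
    mis = frozenset(g.labels[v] for v in m.unmatched_in())
    possible = frozenset(g.labels[v] for v in reach.reached_in)
    subs = substituting_sets(g, m, b=b) if with_substitutes else None
    return ControlProfile(
        n=g.N,
        l=g.L,
        matching_size=size,
        perfect_matching=False,
        mis=mis,
        possible_inputs=possible,
        substitutes=subs,
    )
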