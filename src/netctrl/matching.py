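"""From-scratch Hopcroft-Karp maximum matching with a reachability hook.

The matcher operates on the bipartite split of a directed network and is
oriented the way the controllability argument needs it: alternating searches
are rooted at the *unmatched in-nodes* (the driver side).  From an in-node
the search crosses non-matching edges to out-nodes; from an out-node it can
only continue through its matching edge back to an in-node.  An augmenting
path therefore ends at an unmatched out-node, and when no such path exists
(Berge's condition) the matching is maximum.

The final, failed phase of the search is not wasted: the set of in-nodes it
reaches is exactly the set of nodes that some maximum matching leaves
unmatched, i.e. all possible input nodes.  ``hopcroft_karp`` returns that
final-phase reachability alongside the matching.

No randomisation is used anywhere here; given an adjacency order the whole
computation is deterministic.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from netctrl.graph_core import BipartiteGraph

logger = logging.getLogger(__name__)

UNMATCHED = -1

# dist sentinel values: -1 = unvisited, -2 = consumed by the augmenting DFS
_UNSEEN = -1
_USED = -2


@dataclass
class Matching:
    """An injective pairing of out-nodes to in-nodes along bipartite edges.

    ``mate_of_out[u]`` is the in-node matched with u^out (or UNMATCHED);
    ``mate_of_in`` is the inverse map.
    """

    mate_of_out: list[int]
    mate_of_in: list[int]

    @classmethod
    def empty(cls, n: int) -> "Matching":
        return cls([UNMATCHED] * n, [UNMATCHED] * n)

    @property
    def n(self) -> int:
        return len(self.mate_of_out)

    @property
    def size(self) -> int:
        return sum(1 for v in self.mate_of_out if v != UNMATCHED)

    def unmatched_in(self) -> list[int]:
        return [v for v, o in enumerate(self.mate_of_in) if o == UNMATCHED]

    def unmatched_out(self) -> list[int]:
        return [u for u, v in enumerate(self.mate_of_out) if v == UNMATCHED]

    def matched_pairs(self) -> frozenset[tuple[int, int]]:
        """Canonical edge-set view {(out, in), ...} for comparison."""
        return frozenset(
            (u, v) for u, v in enumerate(self.mate_of_out) if v != UNMATCHED
        )

    def copy(self) -> "Matching":
        return Matching(list(self.mate_of_out), list(self.mate_of_in))

    def validate(self, b: BipartiteGraph) -> None:
        """Assert the two mate maps are mutually inverse matching edges of b."""
        for u, v in enumerate(self.mate_of_out):
            if v != UNMATCHED:
                if self.mate_of_in[v] != u:
                    raise AssertionError("mate maps are not mutually inverse")
                if v not in b.adj_out[u]:
                    raise AssertionError(f"matched pair ({u},{v}) is not an edge")
        for v, u in enumerate(self.mate_of_in):
            if u != UNMATCHED and self.mate_of_out[u] != v:
                raise AssertionError("mate maps are not mutually inverse")


@dataclass
class ReachableSet:
    """Alternating-path reachability from unmatched in-nodes (the roots).

    ``reached_in`` holds every in-node on an even alternating path from some
    root (the roots themselves included); a non-root member was entered
    through its matching edge, so ``pred_out[mate_of_in[v]]`` walks one such
    path back to a root.
    """

    roots: tuple[int, ...]
    reached_in: frozenset[int]
    reached_out: frozenset[int]
    pred_out: dict[int, int]  # out-node -> in-node it was first reached from

    def path_to(self, v_in: int, m: Matching) -> list[int]:
        """One even alternating path root, o_1, v_1, ..., o_k, v_in.

        Nodes alternate in/out starting and ending on the in side; odd
        positions are out-nodes.  For a root the path is just [root].
        """
        if v_in not in self.reached_in:
            raise ValueError(f"in-node {v_in} is not reachable")
        rev: list[int] = [v_in]
        cur = v_in
        while m.mate_of_in[cur] != UNMATCHED and cur not in self.roots:
            o = m.mate_of_in[cur]
            rev.append(o)
            cur = self.pred_out[o]
            rev.append(cur)
        return rev[::-1]


@dataclass
class Phase:
    """Result of one layered alternating BFS against a matching.

    If ``free_out`` is non-empty, shortest augmenting paths exist and end at
    those out-nodes, all in layer ``aug_level``.  Otherwise the BFS ran to
    exhaustion and ``reachable()`` yields the complete alternating-path
    reachability of the matching.
    """

    roots: tuple[int, ...]
    dist_in: list[int]
    dist_out: list[int]
    pred_out: list[int]
    free_out: list[int]
    aug_level: int  # layer of the free out-nodes, -1 if none found

    @property
    def augmenting_found(self) -> bool:
        return bool(self.free_out)

    def reachable(self) -> ReachableSet:
        if self.augmenting_found:
            raise ValueError(
                "phase found augmenting paths; reachability is only complete "
                "once the matching is maximum"
            )
        reached_in = frozenset(
            v for v, d in enumerate(self.dist_in) if d >= 0
        )
        reached_out = frozenset(
            u for u, d in enumerate(self.dist_out) if d >= 0
        )
        pred = {u: self.pred_out[u] for u in reached_out}
        return ReachableSet(self.roots, reached_in, reached_out, pred)


def find_augmenting_phase(b: BipartiteGraph, m: Matching) -> Phase:
    """Layered BFS over alternating paths from all unmatched in-nodes.

    Expansion stops at the first layer containing an unmatched out-node
    (shortest augmenting paths found); if no layer does, the search exhausts
    the full reachable set.
    """
    n = b.n
    dist_in = [_UNSEEN] * n
    dist_out = [_UNSEEN] * n
    pred_out = [_UNSEEN] * n
    roots = tuple(m.unmatched_in())
    for v in roots:
        dist_in[v] = 0
    layer = list(roots)
    depth = 0
    free_out: list[int] = []
    aug_level = -1
    adj_in = b.adj_in
    mate_of_out = m.mate_of_out
    while layer and not free_out:
        nxt: list[int] = []
        for v in layer:
            dv = depth + 1
            for o in adj_in[v]:
                if dist_out[o] == _UNSEEN:
                    dist_out[o] = dv
                    pred_out[o] = v
                    w = mate_of_out[o]
                    if w == UNMATCHED:
                        free_out.append(o)
                        aug_level = dv
                    elif dist_in[w] == _UNSEEN:
                        dist_in[w] = dv + 1
                        nxt.append(w)
        layer = nxt
        depth += 2
    return Phase(roots, dist_in, dist_out, pred_out, free_out, aug_level)


def _try_augment(b: BipartiteGraph, m: Matching, phase: Phase, root: int) -> bool:
    """Iterative DFS for one shortest augmenting path from ``root``.

    Follows the BFS layering (out-nodes only at dist_in+1); consumes each
    out-node at most once per phase, which keeps a whole phase linear in the
    edge count.  On success the path is flipped into the matching.
    """
    dist_in = phase.dist_in
    dist_out = phase.dist_out
    adj_in = b.adj_in
    mate_of_out = m.mate_of_out
    stack: list[tuple[int, Iterable[int]]] = [(root, iter(adj_in[root]))]
    chosen: list[int] = []  # out-node entering each non-root frame
    while stack:
        v, it = stack[-1]
        d = dist_in[v] + 1
        advanced = False
        for o in it:
            if dist_out[o] != d:
                continue
            dist_out[o] = _USED
            w = mate_of_out[o]
            if w == UNMATCHED:
                # flip the path: root gains a mate, every matched edge on the
                # path shifts one step toward the free out-node
                chosen.append(o)
                for (vv, _ign), oo in zip(stack, chosen):
                    m.mate_of_in[vv] = oo
                    m.mate_of_out[oo] = vv
                return True
            if dist_in[w] == d + 1:
                chosen.append(o)
                stack.append((w, iter(adj_in[w])))
                advanced = True
                break
        if not advanced:
            stack.pop()
            if chosen:
                chosen.pop()
    return False


def hopcroft_karp(
    b: BipartiteGraph, greedy_init: bool = False
) -> tuple[Matching, ReachableSet]:
    """Maximum matching plus the final-phase alternating reachability.

    Phases of layered BFS + vertex-disjoint shortest augmenting paths until
    no augmenting path exists; O(N^1/2 L).  The returned ReachableSet is
    computed against the *maximum* matching, rooted at its unmatched
    in-nodes — the raw material for the all-possible-inputs harvest.

    ``greedy_init`` seeds the matching greedily before the first phase; it
    changes intermediate matchings only, never any reported set.
    """
    n = b.n
    m = Matching.empty(n)
    if greedy_init:
        for u in range(n):
            for v in b.adj_out[u]:
                if m.mate_of_in[v] == UNMATCHED:
                    m.mate_of_out[u] = v
                    m.mate_of_in[v] = u
                    break
    phases = 0
    while True:
        phase = find_augmenting_phase(b, m)
        phases += 1
        if not phase.augmenting_found:
            reach = phase.reachable()
            logger.debug(
                "hopcroft_karp: n=%d phases=%d matching_size=%d",
                n,
                phases,
                m.size,
            )
            return m, reach
        for root in phase.roots:
            if m.mate_of_in[root] == UNMATCHED:
                _try_augment(b, m, phase, root)


def alternating_reachability(
    b: BipartiteGraph, m: Matching, roots: Sequence[int] | None = None
) -> ReachableSet:
    """Plain (non-layered) alternating BFS from unmatched in-nodes.

    Independent of the phase machinery; against a maximum matching it must
    agree exactly with the final phase of ``hopcroft_karp``.  ``roots``
    restricts the search (used per-root for substituting sets)."""
    n = b.n
    if roots is None:
        roots = m.unmatched_in()
    seen_in = [False] * n
    seen_out = [False] * n
    pred_out: dict[int, int] = {}
    q = deque(roots)
    for v in roots:
        seen_in[v] = True
    mate_of_out = m.mate_of_out
    adj_in = b.adj_in
    while q:
        v = q.popleft()
        for o in adj_in[v]:
            if not seen_out[o]:
                seen_out[o] = True
                pred_out[o] = v
                w = mate_of_out[o]
                if w != UNMATCHED and not seen_in[w]:
                    seen_in[w] = True
                    q.append(w)
    return ReachableSet(
        tuple(roots),
        frozenset(v for v in range(n) if seen_in[v]),
        frozenset(u for u in range(n) if seen_out[u]),
        pred_out,
    )


def is_maximum(b: BipartiteGraph, m: Matching) -> bool:
    """Berge's condition: maximum iff no augmenting path exists."""
    return not find_augmenting_phase(b, m).augmenting_found


def augment(m: Matching, paths: Sequence[Sequence[int]]) -> Matching:
    """Flip a set of vertex-disjoint augmenting paths into a new matching.

    Each path is a node sequence [v0_in, o1_out, v1_in, ..., ok_out] of odd
    edge count, alternating sides, with both endpoints unmatched; flipping
    it raises the matching size by one.  Violations raise AssertionError
    (they indicate a caller bug, not bad data).
    """
    out = m.copy()
    used: set[tuple[str, int]] = set()
    for path in paths:
        if len(path) < 2 or len(path) % 2 != 0:
            raise AssertionError("augmenting path must have odd edge count")
        v0, ok = path[0], path[-1]
        if m.mate_of_in[v0] != UNMATCHED or m.mate_of_out[ok] != UNMATCHED:
            raise AssertionError("augmenting path endpoints must be unmatched")
        for i, node in enumerate(path):
            key = ("in" if i % 2 == 0 else "out", node)
            if key in used:
                raise AssertionError("augmenting paths are not vertex-disjoint")
            used.add(key)
        # check alternation against the ORIGINAL matching
        for i in range(1, len(path) - 1, 2):
            o, v = path[i], path[i + 1]
            if m.mate_of_out[o] != v:
                raise AssertionError(
                    f"edge ({o}^out,{v}^in) on the path is not matched"
                )
        for i in range(0, len(path) - 1, 2):
            v, o = path[i], path[i + 1]
            out.mate_of_in[v] = o
            out.mate_of_out[o] = v
    return out
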