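"""Independent correctness oracles for the possible-input computation.

Two routes that do NOT share machinery with the alternating-path harvest:

* exhaustive enumeration of every maximum matching (exponential, budgeted,
  for small graphs), whose union of unmatched in-node sets is the ground
  truth for "all possible input nodes";
* the earlier node-removal algorithm: a matched node n is a possible input
  iff deleting n^in leaves the maximum matching size unchanged, detected by
  a single augmenting-path search from n's freed partner (O(L) per node,
  O(NL) overall).

Plus ``verify_mis``, a direct validity check for a candidate input set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from netctrl.graph_core import BipartiteGraph, DirectedNetwork, to_bipartite
from netctrl.matching import UNMATCHED, Matching, hopcroft_karp


class BudgetExceededError(RuntimeError):
    """The enumeration oracle refused an input larger than its budget."""


@dataclass(frozen=True)
class EnumerationBudget:
    """Hard limits that make the exponential oracle refuse rather than hang."""

    max_nodes: int = 16
    max_matchings: int = 10**6


def enumerate_maximum_matchings(
    b: BipartiteGraph, budget: EnumerationBudget = EnumerationBudget()
) -> Iterator[Matching]:
    """Yield every maximum matching of ``b`` exactly once.

    Depth-first branching over out-nodes in index order (match u^out to each
    still-free in-neighbour, or leave it unmatched), pruned by the maximum
    matching size computed once up front.  Each leaf is a distinct out->in
    assignment, so no deduplication is needed.
    """
    if b.n > budget.max_nodes:
        raise BudgetExceededError(
            f"graph has {b.n} nodes; enumeration budget allows {budget.max_nodes}"
        )
    target, _ = hopcroft_karp(b)
    target_size = target.size
    n = b.n
    mate_of_out = [UNMATCHED] * n
    mate_of_in = [UNMATCHED] * n
    yielded = 0

    def rec(u: int, matched: int) -> Iterator[Matching]:
        nonlocal yielded
        if matched + (n - u) < target_size:  # cannot reach the maximum
            return
        if u == n:
            if matched == target_size:
                yielded += 1
                if yielded > budget.max_matchings:
                    raise BudgetExceededError(
                        f"more than {budget.max_matchings} maximum matchings"
                    )
                yield Matching(list(mate_of_out), list(mate_of_in))
            return
        for v in b.adj_out[u]:
            if mate_of_in[v] == UNMATCHED:
                mate_of_out[u] = v
                mate_of_in[v] = u
                yield from rec(u + 1, matched + 1)
                mate_of_out[u] = UNMATCHED
                mate_of_in[v] = UNMATCHED
        yield from rec(u + 1, matched)

    yield from rec(0, 0)


def union_of_unmatched(
    g: DirectedNetwork, budget: EnumerationBudget = EnumerationBudget()
) -> frozenset[str]:
    """Ground-truth possible-input set: union of unmatched in-nodes over ALL
    maximum matchings (perfect-matching convention: every node)."""
    b = to_bipartite(g)
    out: set[int] = set()
    perfect = False
    for m in enumerate_maximum_matchings(b, budget):
        unmatched = m.unmatched_in()
        if not unmatched:
            perfect = True
            break
        out.update(unmatched)
    if perfect:
        return frozenset(g.labels)
    return frozenset(g.labels[v] for v in out)


def removal_test_possible_inputs(g: DirectedNetwork) -> frozenset[str]:
    """The earlier O(NL) algorithm: per-node removal test.

    Compute one maximum matching M.  Unmatched in-nodes are possible inputs
    outright.  For each matched in-node v: drop v^in and the matched edge
    (o, v); the reduced graph's maximum matching keeps the original size iff
    an augmenting path from the freed out-node o exists, in which case some
    maximum matching leaves v unmatched.  (Perfect-matching convention:
    every node is a possible input.)
    """
    b = to_bipartite(g)
    m, _ = hopcroft_karp(b)
    n = b.n
    if m.size == n:
        return frozenset(g.labels)
    possible = set(m.unmatched_in())
    adj_out = b.adj_out
    mate_of_out = m.mate_of_out
    mate_of_in = m.mate_of_in
    # stamped visitation arrays: one allocation for the whole sweep
    stamp_in = [0] * n
    stamp_out = [0] * n
    stamp = 0
    stack: list[int] = []
    for v0 in range(n):
        o0 = mate_of_in[v0]
        if o0 == UNMATCHED:
            continue
        stamp += 1
        stamp_in[v0] = stamp  # the deleted in-node is off limits
        stamp_out[o0] = stamp
        stack.append(o0)
        found = False
        while stack:
            o = stack.pop()
            for w in adj_out[o]:
                if stamp_in[w] == stamp:
                    continue
                stamp_in[w] = stamp
                o2 = mate_of_in[w]
                if o2 == UNMATCHED:
                    found = True
                    stack.clear()
                    break
                if stamp_out[o2] != stamp:
                    stamp_out[o2] = stamp
                    stack.append(o2)
            if found:
                break
        if found:
            possible.add(v0)
    return frozenset(g.labels[v] for v in possible)


def max_matching_size_without_in_node(g: DirectedNetwork, label: str) -> int:
    """Maximum matching size after deleting one in-node (removal primitive)."""
    b = to_bipartite(g)
    vi = g.label_index[label]
    b.adj_in[vi] = []
    b.adj_out = [[w for w in nbrs if w != vi] for nbrs in b.adj_out]
    m, _ = hopcroft_karp(b)
    return m.size


def verify_mis(g: DirectedNetwork, candidate: frozenset[str] | set[str]) -> bool:
    """Is ``candidate`` a valid Minimum Input Set of ``g``?

    True iff |candidate| = max(N - M*, 1) and the bipartite graph restricted
    to the remaining in-nodes admits a matching saturating all of them
    (i.e. some maximum matching leaves exactly the candidate unmatched; for
    a perfect matching any single node qualifies).
    """
    for lab in candidate:
        if lab not in g.label_index:
            raise ValueError(f"unknown node label {lab!r}")
    b = to_bipartite(g)
    m_star, _ = hopcroft_karp(b)
    required = max(g.N - m_star.size, 1)
    if len(candidate) != required:
        return False
    drop = {g.label_index[lab] for lab in candidate}
    restricted = BipartiteGraph(
        b.n,
        [[w for w in nbrs if w not in drop] for nbrs in b.adj_out],
        [[] if v in drop else list(b.adj_in[v]) for v in range(b.n)],
    )
    m, _ = hopcroft_karp(restricted)
    return m.size == g.N - len(candidate)
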