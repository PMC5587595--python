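"""Directed-network container, edge-list I/O and the bipartite split.

A directed network G(V, E) is stored with string node labels and 0-based
internal indices assigned in order of first appearance, which makes every
downstream computation deterministic for a given input file.

For matching purposes each node n is split into an out-copy n^out (tail of
its out-edges) and an in-copy n^in (head of its in-edges); the directed edge
(u, v) becomes the undirected bipartite edge u^out -- v^in.  A matching of
that bipartite graph never pairs two edges sharing a head or sharing a tail,
which is exactly the "each driven node has a dedicated superior" picture of
structural controllability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from netctrl.all_inputs import ControlProfile

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class DirectedNetwork:
    """A node-labelled digraph with deterministic label <-> index mapping.

    Attributes
    ----------
    labels
        Node labels in order of first appearance; index i <-> labels[i].
    edges
        Simple (deduplicated) list of (source_index, target_index) pairs.
    """

    labels: list[str]
    edges: list[tuple[int, int]]
    label_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.label_index) != len(self.labels):
            raise ValueError("duplicate node labels")
        n = len(self.labels)
        seen: set[tuple[int, int]] = set()
        for u, v in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u}, {v}) out of range for N={n}")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u}, {v})")
            seen.add((u, v))

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def L(self) -> int:
        return len(self.edges)

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.labels[u], self.labels[v]) for u, v in self.edges]

    @classmethod
    def from_labeled_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        self_loop_policy: str = "keep",
        extra_nodes: Iterable[str] = (),
    ) -> "DirectedNetwork":
        """Build a network from (source_label, target_label) pairs.

        Duplicate edges are dropped (first occurrence wins); self-loops are
        kept or dropped per ``self_loop_policy``.  Labels are indexed in
        first-appearance order, sources before targets within a pair.
        """
        if self_loop_policy not in ("keep", "drop"):
            raise ValueError(f"unknown self_loop_policy {self_loop_policy!r}")
        labels: list[str] = []
        index: dict[str, int] = {}

        def idx(lab: str) -> int:
            i = index.get(lab)
            if i is None:
                i = len(labels)
                index[lab] = i
                labels.append(lab)
            return i

        edges: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        n_dup = n_loop = 0
        for s, t in pairs:
            u, v = idx(str(s)), idx(str(t))
            if u == v and self_loop_policy == "drop":
                n_loop += 1
                continue
            if (u, v) in seen:
                n_dup += 1
                continue
            seen.add((u, v))
            edges.append((u, v))
        for lab in extra_nodes:
            idx(str(lab))
        if n_dup:
            logger.info("dropped %d duplicate edge(s)", n_dup)
        if n_loop:
            logger.info("dropped %d self-loop(s) (policy=drop)", n_loop)
        if not labels:
            raise EdgeListError("empty graph: no nodes found")
        return cls(labels, edges)

    def relabel(self, mapping: dict[str, str]) -> "DirectedNetwork":
        """Return a copy with labels renamed through a bijective mapping."""
        new = [mapping[lab] for lab in self.labels]
        return DirectedNetwork(new, list(self.edges))

    def permute(self, order: Sequence[int]) -> "DirectedNetwork":
        """Return the same labelled graph with node order ``order`` and the
        edge list re-sorted accordingly (used for invariance testing)."""
        labels = [self.labels[i] for i in order]
        pos = {old: new for new, old in enumerate(order)}
        edges = sorted((pos[u], pos[v]) for u, v in self.edges)
        return DirectedNetwork(labels, edges)


@dataclass
class BipartiteGraph:
    """Bipartite split B(V^out, V^in, E) of a directed network.

    ``adj_out[u]`` lists the in-copies reachable from u^out (i.e. the heads
    of u's out-edges); ``adj_in[v]`` is the inverse adjacency (tails of v's
    in-edges).  Both sides have exactly n entries, one per original node.
    """

    n: int
    adj_out: list[list[int]]
    adj_in: list[list[int]]

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adj_out)


def read_edge_list(path, self_loop_policy: str = "keep") -> DirectedNetwork:
    """Parse a plain-text edge list: one ``SOURCE TARGET`` pair per line.

    Lines whose first non-blank character is ``#`` and blank lines are
    skipped.  Tokens beyond the second are ignored with a warning.  A line
    with exactly one token is a parse error naming the line number.
    """
    pairs: list[tuple[str, str]] = []
    warned_extra = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListError(
                    f"{path}: line {lineno}: expected 'SOURCE TARGET', got {stripped!r}"
                )
            if len(tokens) > 2 and not warned_extra:
                logger.warning(
                    "%s: line %d: ignoring extra tokens beyond the first two",
                    path,
                    lineno,
                )
                warned_extra = True
            pairs.append((tokens[0], tokens[1]))
    if not pairs:
        raise EdgeListError(f"{path}: empty graph (no edges or nodes)")
    return DirectedNetwork.from_labeled_edges(pairs, self_loop_policy=self_loop_policy)


def write_edge_list(g: DirectedNetwork, path) -> None:
    """Write ``g`` as a plain-text edge list (round-trips with read_edge_list)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in g.edge_labels():
            fh.write(f"{s}\t{t}\n")


def to_bipartite(g: DirectedNetwork) -> BipartiteGraph:
    """Split every node into an out-copy and an in-copy.

    The directed edge (u, v) becomes the single bipartite edge u^out--v^in;
    adjacency lists preserve input edge order (the matcher is deterministic
    given this order).
    """
    n = g.N
    adj_out: list[list[int]] = [[] for _ in range(n)]
    adj_in: list[list[int]] = [[] for _ in range(n)]
    for u, v in g.edges:
        adj_out[u].append(v)
        adj_in[v].append(u)
    return BipartiteGraph(n, adj_out, adj_in)


def report_dict(profile: "ControlProfile", meta: dict | None = None) -> dict:
    """Assemble the JSON-serialisable report for a computed control profile."""
    subs = profile.substitutes
    doc = {
        "n": profile.n,
        "l": profile.l,
        "matching_size": profile.matching_size,
        "perfect_matching": profile.perfect_matching,
        "mis": sorted(profile.mis),
        "possible_inputs": sorted(profile.possible_inputs),
        "n_pd": profile.n_pd,
        "substitutes": (
            None if subs is None else {m: sorted(k) for m, k in subs.items()}
        ),
        "profile": (
            None
            if subs is None
            else [
                [label, s, p]
                for label, s, p in profile.ranked_profile()
            ]
        ),
    }
    if meta is not None:
        doc["meta"] = meta
    return doc


def write_report(profile: "ControlProfile", path, meta: dict | None = None) -> None:
    """Write the control-profile report as sorted, indented JSON."""
    doc = report_dict(profile, meta=meta)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
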