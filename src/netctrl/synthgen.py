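"""Seeded synthetic-network generators and named fixture graphs.

The scale-free family is a two-sided (dual) preferential-attachment growth
process.  Each newly born node draws independent Poisson(<k>/4) counts of
out-edges and in-edges: its out-edges attach to existing targets with
probability proportional to their in-degree, its in-edges come from existing
sources chosen proportionally to their out-degree.  Pure linear attachment
gives both degree tails the Barabasi-Albert exponent 3; other exponents r
are obtained by adding the uniform attachment offset a = (r - 3) * <k>/4.
The Poisson spread matters: it leaves a small mass of in-degree-0 /
out-degree-0 nodes at every density, so matchings approach but do not reach
perfection as <k> grows — the regime in which the density of possible input
nodes collapses with increasing average degree.  Self-loops and duplicate
arcs are excluded by construction, so generated graphs are always simple.

Every generator is a pure function of its configuration, seed included:
the same config yields a byte-identical edge list.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from netctrl.graph_core import DirectedNetwork


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic network draw.

    family: ``scale_free`` | ``erdos_renyi`` | ``fixture``;
    n: node count; k_avg: target average degree <k> = 2L/N;
    r_in, r_out: power-law tail exponents (scale-free only);
    seed: RNG seed; fixture_name: which named graph (fixture family only).
    """

    family: str
    n: int = 0
    k_avg: float = 0.0
    r_in: float = 3.0
    r_out: float = 3.0
    seed: int = 0
    fixture_name: str | None = None


# Named small graphs used throughout the tests and documentation.  The
# "substitution_demo" network is a synthetic, hand-constructed 10-node
# example whose single maximum-matching analysis exhibits two driver nodes
# with non-trivial substituting sets: MIS {4, 10}, all possible inputs
# {4, 6, 8, 9, 10}, K_4 = {6, 8}, K_10 = {9}.
_FIXTURES: dict[str, list[tuple[str, str]]] = {
    "path3": [("1", "2"), ("2", "3")],
    "star3": [("1", "2"), ("1", "3")],
    "diamond": [("1", "2"), ("1", "3"), ("2", "4"), ("3", "4")],
    "cycle2": [("1", "2"), ("2", "1")],
    "selfloop1": [("1", "1")],
    "substitution_demo": [
        ("1", "2"),
        ("2", "3"),
        ("3", "1"),
        ("4", "5"),
        ("5", "4"),
        ("5", "6"),
        ("6", "7"),
        ("7", "6"),
        ("7", "8"),
        ("8", "9"),
        ("8", "10"),
    ],
}


def fixture(name: str) -> DirectedNetwork:
    """Return a named small graph (see ``fixture_names``)."""
    try:
        edges = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return DirectedNetwork.from_labeled_edges(edges)


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's Poisson sampler (lam is small here, a few at most)."""
    limit = math.exp(-lam)
    p, k = 1.0, 0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def gen_scale_free(config: SynthConfig) -> DirectedNetwork:
    """Directed scale-free network by dual preferential attachment.

    Growth starts from a small directed seed ring; each new node draws
    Poisson(<k>/4) out-edges (targets by in-degree) and Poisson(<k>/4)
    in-edges (sources by out-degree), so the realised average degree
    2L/N concentrates tightly around ``config.k_avg`` and both degree
    tails have exponent r_in / r_out (default 3).  Output is always a
    simple digraph; node labels are "1".."n" in creation order.
    """
    n, k_avg = config.n, config.k_avg
    if n < 2:
        raise ValueError("scale-free generator requires n >= 2")
    if not (0 < k_avg < n):
        raise ValueError(f"infeasible k_avg={k_avg} for n={n}")
    if config.r_in <= 2 or config.r_out <= 2:
        raise ValueError("tail exponents must exceed 2")
    lam = k_avg / 4.0
    # uniform attachment offset shifts the BA exponent: r = 3 + a / lam
    a_in = (config.r_in - 3.0) * lam
    a_out = (config.r_out - 3.0) * lam
    rng = random.Random(config.seed)
    heads: list[int] = []  # target of each edge (in-degree urn)
    tails: list[int] = []  # source of each edge (out-degree urn)
    edges: list[tuple[int, int]] = []

    def add(u: int, v: int) -> None:
        edges.append((u, v))
        tails.append(u)
        heads.append(v)

    m0 = min(n, max(2, int(lam) + 2))
    for i in range(m0):
        add(i, (i + 1) % m0)

    def pick(urn: list[int], offset: float, n_alive: int) -> int:
        total = len(urn) + offset * n_alive
        if offset > 0 and rng.random() >= len(urn) / total:
            return rng.randrange(n_alive)
        return urn[rng.randrange(len(urn))]

    for t in range(m0, n):
        n_out = min(_poisson(rng, lam), t)
        n_in = min(_poisson(rng, lam), t)
        chosen: set[int] = set()
        guard = 0
        while len(chosen) < n_out and guard < 100 * (n_out + 1):
            guard += 1
            v = pick(heads, a_in, t)
            if v != t and v not in chosen:
                chosen.add(v)
                add(t, v)
        chosen = set()
        guard = 0
        while len(chosen) < n_in and guard < 100 * (n_in + 1):
            guard += 1
            u = pick(tails, a_out, t)
            if u != t and u not in chosen:
                chosen.add(u)
                add(u, t)
    labels = [str(i + 1) for i in range(n)]
    return DirectedNetwork(labels, edges)


def gen_erdos_renyi(n: int, k_avg: float, seed: int) -> DirectedNetwork:
    """Directed Erdos-Renyi G(n, p) with p = k_avg / (n - 1).

    Every ordered pair (u, v), u != v, is an edge independently with
    probability p; <k> = 2L/N has expectation k_avg.
    """
    if n < 2:
        raise ValueError("erdos_renyi requires n >= 2")
    if not (0 < k_avg <= n - 1):
        raise ValueError(f"k_avg must lie in (0, n-1]; got {k_avg}")
    p = k_avg / (n - 1)
    rng = np.random.default_rng(seed)
    if n <= 2048:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        us, vs = np.nonzero(mask)
        edges = [(int(u), int(v)) for u, v in zip(us, vs)]
    else:
        n_pairs = n * (n - 1)
        m = int(rng.binomial(n_pairs, p))
        chosen: set[int] = set()
        while len(chosen) < m:
            draw = rng.integers(0, n_pairs, size=m - len(chosen))
            chosen.update(int(x) for x in draw)
        edges = []
        for code in sorted(chosen):
            u, r = divmod(code, n - 1)
            v = r if r < u else r + 1
            edges.append((u, v))
    labels = [str(i + 1) for i in range(n)]
    return DirectedNetwork(labels, edges)


def random_small_digraph(
    n_max: int,
    density_range: tuple[float, float] = (0.05, 0.9),
    seed: int = 0,
) -> DirectedNetwork:
    """One small ER digraph with uniform n in [1, n_max] and uniform density.

    Driver for the enumeration-oracle sweeps; a single isolated node is a
    legal draw (its MIS is itself).  Deterministic per seed.
    """
    rng = random.Random(seed)
    n = rng.randint(1, n_max)
    p = rng.uniform(*density_range)
    edges = [
        (str(u + 1), str(v + 1))
        for u in range(n)
        for v in range(n)
        if u != v and rng.random() < p
    ]
    return DirectedNetwork.from_labeled_edges(
        edges, extra_nodes=[str(i + 1) for i in range(n)]
    )


def sweep_small_digraphs(
    count: int,
    n_max: int,
    density_range: tuple[float, float] = (0.05, 0.9),
    seed: int = 0,
):
    """Reproducible sequence of ``count`` small digraphs (oracle sweeps)."""
    for i in range(count):
        yield random_small_digraph(n_max, density_range, seed=seed * 1_000_003 + i)


def tail_exponent(values, tail_fraction: float = 0.05) -> float:
    """Hill estimator of a power-law tail exponent from degree samples.

    Uses the top ``tail_fraction`` of the sorted sample (at least 10
    points); returns alpha with P(X >= x) ~ x^-(alpha-1), i.e. the density
    exponent comparable to r_in/r_out.
    """
    xs = np.sort(np.asarray(values, dtype=float))
    xs = xs[xs > 0]
    k = max(10, int(len(xs) * tail_fraction))
    tail = xs[-k:]
    x_min = tail[0]
    if x_min <= 0 or len(tail) < 2:
        raise ValueError("not enough tail mass to estimate an exponent")
    logs = np.log(tail / x_min)
    mean_log = float(np.mean(logs))
    if mean_log == 0:
        raise ValueError("degenerate tail (all values equal)")
    return 1.0 + 1.0 / mean_log
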