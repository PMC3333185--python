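"""Independent brute-force oracles and seeded synthetic-input generators.

Nothing here shares code paths with the algebraic machinery it checks:

* ``brute_force_norm`` finds a minimal 2-cycle factorization by
  breadth-first search over group products, independently of the
  ``|E| - n_c`` formula;
* ``bfs_optimal_weight`` finds the true minimum sorting weight by
  Dijkstra over the graph of all small chromosomes connected by single
  CCLP operations (weight 1 or 2), independently of the sorter and of
  the residual-norm bound;
* ``random_gene_order`` and ``scramble`` produce reproducible seeded
  inputs (uniform signed permutations, and identity chromosomes
  shuffled by k random operations with a known weight budget).
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

from .cclp_ops import CCLPError, CCLPOperation, apply, enumerate_operations
from .chromosome import (
    Chromosome,
    GeneOrder,
    canonical_gene_order,
    from_gene_order,
    identity_chromosome,
)
from .perm_algebra import Permutation, norm

__all__ = [
    "StateGraph",
    "build_state_graph",
    "bfs_optimal_weight",
    "brute_force_norm",
    "random_gene_order",
    "scramble",
    "fixture_rows",
]


class OracleGuardError(RuntimeError):
    """An exponential oracle was asked to run beyond its guard."""


def brute_force_norm(a: Permutation, guard: int = 6) -> int:
    """Length of a shortest 2-cycle factorization of ``a``, by BFS.

    Searches products of 2-cycles breadth-first from the identity until
    ``a`` is reached; exact but exponential, hence guarded to small
    ground sets.
    """
    elems = sorted(a.ground_set.elements)
    if len(elems) > guard:
        raise OracleGuardError(
            f"brute_force_norm guard: |E|={len(elems)} > {guard} "
            f"(group has up to {_factorial(len(elems))} states)"
        )
    target = tuple(a(e) for e in elems)
    start = tuple(elems)
    if target == start:
        return 0
    index = {e: i for i, e in enumerate(elems)}
    pairs = list(combinations(range(len(elems)), 2))
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, d = frontier.popleft()
        for i, j in pairs:
            nxt = list(state)
            # multiply by the 2-cycle (elems[i], elems[j]) on the left
            for k, v in enumerate(state):
                if index[v] == i:
                    nxt[k] = elems[j]
                elif index[v] == j:
                    nxt[k] = elems[i]
            t = tuple(nxt)
            if t == target:
                return d + 1
            if t not in seen:
                seen.add(t)
                frontier.append((t, d + 1))
    raise AssertionError("2-cycles generate the symmetric group")  # pragma: no cover


def _factorial(k: int) -> int:
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


@dataclass(frozen=True)
class StateGraph:
    """All chromosomes on n genes, connected by single CCLP operations.

    Nodes are canonical circular gene orders (read from gene +1); each
    edge is one operation with weight 1 (reversal) or 2 (non-reversal).
    """

    n: int
    edges: dict  # node -> {neighbor: weight}

    @property
    def nodes(self) -> list[tuple[int, ...]]:
        return list(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for node, nbrs in self.edges.items():
            for nbr, wt in nbrs.items():
                g.add_edge(node, nbr, weight=wt)
        return g


def _canonical(chrom: Chromosome) -> tuple[int, ...]:
    return canonical_gene_order(chrom).genes


@lru_cache(maxsize=None)
def build_state_graph(n: int, guard: int = 4, override: bool = False) -> StateGraph:
    """Exhaustive operation graph over every chromosome on n genes."""
    if n > guard and not override:
        raise OracleGuardError(
            f"state-graph guard: n={n} > {guard} "
            f"(about {_factorial(n - 1) * 2 ** (n - 1)} states, each expanded "
            "by exhaustive operation enumeration)"
        )
    start = identity_chromosome(n)
    edges: dict[tuple[int, ...], dict[tuple[int, ...], int]] = {}
    frontier = deque([start])
    edges[_canonical(start)] = {}
    while frontier:
        chrom = frontier.popleft()
        node = _canonical(chrom)
        for op in enumerate_operations(chrom, max_n=max(n, 6)):
            result = apply(op, chrom)
            nbr = _canonical(result)
            prev = edges[node].get(nbr)
            if prev is None or op.weight < prev:
                edges[node][nbr] = op.weight
            if nbr not in edges:
                edges[nbr] = {}
                frontier.append(result)
    return StateGraph(n=n, edges=edges)


def bfs_optimal_weight(g: GeneOrder, guard: int = 4, override: bool = False) -> int:
    """True minimum sorting weight of ``g`` by shortest path in the
    state graph."""
    import networkx as nx

    graph = build_state_graph(g.n, guard=guard, override=override)
    source = _canonical(from_gene_order(g))
    target = _canonical(identity_chromosome(g.n))
    return nx.dijkstra_path_length(
        graph.to_networkx(), source, target, weight="weight"
    )


def random_gene_order(n: int, seed: int) -> GeneOrder:
    """A uniform random signed gene order: uniform label permutation,
    independent fair sign flips.  Reproducible per seed."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = random.Random(seed)
    labels = list(range(1, n + 1))
    rng.shuffle(labels)
    genes = tuple(lab if rng.random() < 0.5 else -lab for lab in labels)
    return GeneOrder(genes)


def _random_operation(
    chrom: Chromosome, rng: random.Random, max_tries: int = 200
) -> CCLPOperation:
    """One random valid CCLP operation, drawn from biological coordinates."""
    from .cclp_ops import nonreversal_by_coords, reversal_by_segment

    n = chrom.n
    strand = chrom.pi_plus
    for _ in range(max_tries):
        try:
            if n < 2 or rng.random() < 0.5:
                # reversal of a random proper segment of the plus strand
                i = rng.randrange(n)
                length = rng.randint(1, max(1, n - 1))
                return reversal_by_segment(
                    chrom, strand[i], strand[(i + length - 1) % n]
                )
            i = rng.randrange(n)
            length = rng.randint(1, n - 1)
            seg_start = strand[i]
            seg_end = strand[(i + length - 1) % n]
            remainder = [e for e in strand if e not in _seg_set(strand, i, length)]
            op = nonreversal_by_coords(
                chrom,
                seg_start,
                seg_end,
                cut_offset=rng.randrange(length),
                paste_after=rng.choice(remainder),
                invert=rng.random() < 0.5,
            )
            if norm(op.as_permutation(n)) < 4:
                # a weight-2 encoding of a plain reversal: redraw, so
                # every emitted operation is worth its recorded weight
                continue
            return op
        except CCLPError:
            continue
    raise RuntimeError(f"no valid random operation found on {chrom} "
                       f"after {max_tries} tries")


def _seg_set(strand, i: int, length: int) -> set[int]:
    n = len(strand)
    return {strand[(i + k) % n] for k in range(length)}


def scramble(
    n: int, k: int, seed: int
) -> tuple[GeneOrder, list[CCLPOperation]]:
    """Apply k random CCLP operations to the identity chromosome.

    Returns the scrambled gene order and the applied operations; the
    optimal sorting weight of the result is at most the summed weight
    of the applied operations (with equality whenever k <= 1).
    """
    if n < 2 and k > 0:
        raise ValueError("no state-changing operation exists for n < 2")
    if k < 0:
        raise ValueError(f"need k >= 0, got {k}")
    rng = random.Random(seed)
    chrom = identity_chromosome(n)
    applied: list[CCLPOperation] = []
    for _ in range(k):
        op = _random_operation(chrom, rng)
        chrom = apply(op, chrom)
        applied.append(op)
    return canonical_gene_order(chrom), applied


def fixture_rows(
    seeds: range, n: int, k: int
) -> list[tuple[int, int, int, str, int]]:
    """TSV-ready regression rows: (seed, n, k, gene order, weight bound)."""
    rows = []
    for seed in seeds:
        order, ops = scramble(n, k, seed)
        bound = sum(op.weight for op in ops)
        rows.append((seed, n, k, " ".join(map(str, order.genes)), bound))
    return rows
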