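"""Permutation-group arithmetic over an explicit finite ground set.

Everything in this package reduces to a handful of facts about finite
permutations written in cycle notation: composition, inversion,
conjugation, the cycle decomposition, the cycle count ``n_c`` (which
*includes* fixed points, so it depends on the ground set), the norm
``||a|| = |E| - n_c(a)`` (the minimum number of 2-cycles whose product
is ``a``), and the divisibility relation ``a | b`` defined by
``||b a^-1|| = ||b|| - ||a||``.

A 2-cycle multiplied with a permutation acts either as a *split*
(fission: both elements in one cycle, cycle count goes up by one) or a
*join* (fusion: elements in two cycles, cycle count goes down by one).
Genome rearrangements are built out of such 2-cycle products.

Permutations carry their ground set explicitly because the cycle count
of e.g. ``(1,3,2)(5,6)`` over ``{1..6}`` is 3, not 2: the fixed point 4
contributes a 1-cycle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

__all__ = [
    "GroundSet",
    "Cycle",
    "Permutation",
    "make_permutation",
    "identity",
    "compose",
    "inverse",
    "conjugate",
    "cycle_decomposition",
    "count_cycles",
    "norm",
    "divides",
    "classify_2cycle",
    "parse_permutation",
]


class PermutationError(ValueError):
    """Raised for malformed cycles, mappings or ground-set mismatches."""


@dataclass(frozen=True)
class GroundSet:
    """A finite set of nonzero integers on which permutations act."""

    elements: frozenset[int]

    def __post_init__(self) -> None:
        if not self.elements:
            raise PermutationError("ground set must be nonempty")
        if 0 in self.elements:
            raise PermutationError("0 is not a valid ground-set element")

    @classmethod
    def unsigned(cls, n: int) -> "GroundSet":
        """The plain set {1, ..., n}."""
        if n < 1:
            raise PermutationError(f"need n >= 1, got {n}")
        return cls(frozenset(range(1, n + 1)))

    @classmethod
    def signed(cls, n: int) -> "GroundSet":
        """The signed set {+-1, ..., +-n} used for two-strand chromosomes."""
        if n < 1:
            raise PermutationError(f"need n >= 1, got {n}")
        return cls(frozenset(range(1, n + 1)) | frozenset(range(-n, 0)))

    @property
    def is_signed(self) -> bool:
        return all(-e in self.elements for e in self.elements)

    def __contains__(self, e: int) -> bool:
        return e in self.elements

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.elements))


class Cycle(tuple):
    """A cyclic sequence of distinct elements, canonically rotated.

    Equality is rotation-invariant because construction always rotates
    the cycle to start at its minimum element (integer order, so
    negatives come first).
    """

    def __new__(cls, elements: Iterable[int]) -> "Cycle":
        elems = tuple(elements)
        if len(set(elems)) != len(elems):
            raise PermutationError(f"repeated element in cycle {elems}")
        if not elems:
            raise PermutationError("empty cycle")
        k = elems.index(min(elems))
        return super().__new__(cls, elems[k:] + elems[:k])

    def __repr__(self) -> str:
        return "(" + ",".join(str(e) for e in self) + ")"

    def successor(self, e: int) -> int:
        i = self.index(e)
        return self[(i + 1) % len(self)]

    def predecessor(self, e: int) -> int:
        return self[self.index(e) - 1]


@dataclass(frozen=True)
class Permutation:
    """A bijection of a ground set onto itself, stored as a total mapping."""

    mapping: dict[int, int]
    ground_set: GroundSet
    _key: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        gs = self.ground_set.elements
        if set(self.mapping) != gs or set(self.mapping.values()) != gs:
            raise PermutationError("mapping is not a bijection of the ground set")
        object.__setattr__(self, "_key", frozenset(self.mapping.items()))

    def __call__(self, e: int) -> int:
        return self.mapping[e]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Permutation):
            return NotImplemented
        return self.ground_set == other.ground_set and self._key == other._key

    def __hash__(self) -> int:
        return hash((self.ground_set, self._key))

    def __mul__(self, other: "Permutation") -> "Permutation":
        return compose(self, other)

    @property
    def is_identity(self) -> bool:
        return all(v == k for k, v in self.mapping.items())

    def cycles(self, include_fixed: bool = False) -> list[Cycle]:
        return cycle_decomposition(self, include_fixed=include_fixed)

    def __str__(self) -> str:
        cyc = self.cycles()
        if not cyc:
            return "()"
        return "".join(repr(c) for c in cyc)


def _check_same_ground(a: Permutation, b: Permutation) -> None:
    if a.ground_set != b.ground_set:
        raise PermutationError("permutations act on different ground sets")


def make_permutation(
    cycles: Iterable[Iterable[int]], ground_set: GroundSet
) -> Permutation:
    """Build a permutation from disjoint cycles; unlisted elements are fixed."""
    mapping = {e: e for e in ground_set.elements}
    seen: set[int] = set()
    for raw in cycles:
        cyc = Cycle(raw)
        for e in cyc:
            if e not in ground_set:
                raise PermutationError(f"element {e} not in ground set")
            if e in seen:
                raise PermutationError(f"element {e} appears in two cycles")
            seen.add(e)
        for i, e in enumerate(cyc):
            mapping[e] = cyc[(i + 1) % len(cyc)]
    return Permutation(mapping, ground_set)


def identity(ground_set: GroundSet) -> Permutation:
    return Permutation({e: e for e in ground_set.elements}, ground_set)


def compose(a: Permutation, b: Permutation) -> Permutation:
    """The product ab, with ab(e) = a(b(e))."""
    _check_same_ground(a, b)
    return Permutation({e: a(b(e)) for e in b.ground_set.elements}, a.ground_set)


def inverse(a: Permutation) -> Permutation:
    return Permutation({v: k for k, v in a.mapping.items()}, a.ground_set)


def conjugate(a: Permutation, b: Permutation) -> Permutation:
    """The conjugation a . b = a b a^-1 (relabels b's cycles through a)."""
    _check_same_ground(a, b)
    # a b a^-1 maps a(e) -> a(b(e)), avoiding two full compositions.
    return Permutation({a(e): a(b(e)) for e in b.ground_set.elements}, a.ground_set)


def cycle_decomposition(a: Permutation, include_fixed: bool = False) -> list[Cycle]:
    """Disjoint cycles of ``a``, each starting at its minimum element,
    listed by increasing minimum."""
    seen: set[int] = set()
    cycles: list[Cycle] = []
    for start in sorted(a.ground_set.elements):
        if start in seen:
            continue
        orbit = [start]
        seen.add(start)
        e = a(start)
        while e != start:
            orbit.append(e)
            seen.add(e)
            e = a(e)
        if len(orbit) > 1 or include_fixed:
            cycles.append(Cycle(orbit))
    return cycles


def count_cycles(a: Permutation) -> int:
    """n_c(a): the number of disjoint cycles, counting fixed points."""
    return len(cycle_decomposition(a, include_fixed=True))


def norm(a: Permutation) -> int:
    """||a|| = |E| - n_c(a): the minimum number of 2-cycles composing a."""
    return len(a.ground_set) - count_cycles(a)


def divides(a: Permutation, b: Permutation) -> bool:
    """a | b  iff  ||b a^-1|| = ||b|| - ||a||.

    For a k-cycle this is equivalent to its elements appearing in the
    same cycle of ``b`` in the same cyclic order.
    """
    _check_same_ground(a, b)
    return norm(compose(b, inverse(a))) == norm(b) - norm(a)


def classify_2cycle(t: Cycle, b: Permutation) -> Literal["split", "join"]:
    """Whether the 2-cycle ``t`` acts on ``b`` as a fission or a fusion.

    ``split``: both elements lie in one cycle of ``b`` (cycle count +1);
    ``join``: they lie in two different cycles (cycle count -1).
    """
    if len(t) != 2:
        raise PermutationError(f"expected a 2-cycle, got {t!r}")
    x, y = t
    if x not in b.ground_set or y not in b.ground_set:
        raise PermutationError(f"2-cycle {t!r} not over the ground set")
    e = b(x)
    while e != x:
        if e == y:
            return "split"
        e = b(e)
    return "join"


_CYCLE_RE = re.compile(r"\(([^()]*)\)")


def parse_permutation(text: str, ground_set: GroundSet) -> Permutation:
    """Parse cycle notation like ``"(1,6,4)(2,5,3)"`` (whitespace ignored).

    ``"()"`` or an empty string denotes the identity.
    """
    compact = "".join(text.split())
    if compact in ("", "()"):
        return identity(ground_set)
    if not re.fullmatch(r"(\([^()]*\))+", compact):
        raise PermutationError(f"cannot parse cycle notation: {text!r}")
    cycles = []
    for body in _CYCLE_RE.findall(compact):
        if not body:
            continue
        try:
            cycles.append([int(tok) for tok in body.split(",")])
        except ValueError as exc:
            raise PermutationError(f"bad element in {body!r}") from exc
    return make_permutation(cycles, ground_set)
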