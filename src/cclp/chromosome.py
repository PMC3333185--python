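"""The two-strand signed chromosome model.

A chromosome with genes 1..n is modelled over the signed ground set
E = {+-1, ..., +-n}.  One DNA strand is an admissible n-cycle pi+ (it
never contains a gene together with its negation); the other strand is
its reverse complement pi- = Gamma (pi+)^-1 Gamma, where Gamma is the
sign-flip involution (1,-1)(2,-2)...(n,-n).  The chromosome itself is
the permutation pi = pi+ pi-: a product of two disjoint, mutually
complementary admissible cycles covering E.

User-facing gene orders are sequences of n distinct signed integers;
they are embedded as circular chromosomes (sorting by CCLP operations
is equivalent for circular and linear chromosomes, so the ``circular``
flag is retained for display only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .perm_algebra import (
    Cycle,
    GroundSet,
    Permutation,
    cycle_decomposition,
    make_permutation,
)

__all__ = [
    "GeneOrder",
    "Chromosome",
    "gamma",
    "is_admissible",
    "reverse_complement",
    "from_gene_order",
    "to_gene_order",
    "identity_chromosome",
]


class ChromosomeError(ValueError):
    """Raised for gene orders or permutations that are not chromosomes."""


@dataclass(frozen=True)
class GeneOrder:
    """A sequence of n distinct signed gene labels with |labels| = {1..n}."""

    genes: tuple[int, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        n = len(self.genes)
        if n == 0:
            raise ChromosomeError("empty gene order")
        if sorted(abs(g) for g in self.genes) != list(range(1, n + 1)):
            raise ChromosomeError(
                f"gene labels must be +-1..+-{n} each once, got {self.genes}"
            )

    @property
    def n(self) -> int:
        return len(self.genes)

    def __str__(self) -> str:
        tag = "circular" if self.circular else "linear"
        return f"{tag}: " + " ".join(str(g) for g in self.genes)

    @classmethod
    def parse(cls, text: str) -> "GeneOrder":
        """Parse ``"1 -4 -3 -2 5 6"`` with optional ``circular:``/``linear:`` tag."""
        s = text.strip()
        circular = True
        if ":" in s:
            tag, _, rest = s.partition(":")
            tag = tag.strip().lower()
            if tag not in ("circular", "linear"):
                raise ChromosomeError(f"unknown chromosome tag {tag!r}")
            circular = tag == "circular"
            s = rest
        tokens = s.replace(",", " ").split()
        if not tokens:
            raise ChromosomeError("no genes in input")
        genes = []
        for tok in tokens:
            try:
                genes.append(int(tok))
            except ValueError as exc:
                raise ChromosomeError(f"bad gene token {tok!r}") from exc
        return cls(tuple(genes), circular=circular)


@lru_cache(maxsize=None)
def gamma(n: int) -> Permutation:
    """The involution Gamma = (1,-1)(2,-2)...(n,-n) over {+-1..+-n}."""
    if n < 1:
        raise ChromosomeError(f"need n >= 1, got {n}")
    gs = GroundSet.signed(n)
    return Permutation({e: -e for e in gs.elements}, gs)


def is_admissible(c: Cycle) -> bool:
    """True iff no element occurs together with its negation (a DNA strand)."""
    s = set(c)
    return all(-e not in s for e in s)


def reverse_complement(strand: Cycle, n: int) -> Cycle:
    """The complementary strand Gamma (strand)^-1 Gamma: negate and reverse."""
    if not is_admissible(strand):
        raise ChromosomeError(f"strand {strand!r} is not admissible")
    return Cycle([-e for e in reversed(strand)])


@dataclass(frozen=True)
class Chromosome:
    """A two-strand chromosome pi = pi+ pi- over {+-1..+-n}."""

    pi_plus: Cycle
    n: int
    pi_minus: Cycle = field(init=False)

    def __post_init__(self) -> None:
        plus = Cycle(self.pi_plus)
        if len(plus) != self.n:
            raise ChromosomeError(
                f"strand has {len(plus)} elements, expected n={self.n}"
            )
        if not is_admissible(plus):
            raise ChromosomeError(f"strand {plus!r} is not admissible")
        if any(abs(e) > self.n or e == 0 for e in plus):
            raise ChromosomeError(f"strand {plus!r} not over +-1..+-{self.n}")
        if len({abs(e) for e in plus}) != self.n:
            raise ChromosomeError(f"strand {plus!r} misses some gene")
        object.__setattr__(self, "pi_plus", plus)
        object.__setattr__(self, "pi_minus", reverse_complement(plus, self.n))

    @property
    def ground_set(self) -> GroundSet:
        return GroundSet.signed(self.n)

    @property
    def permutation(self) -> Permutation:
        """pi = pi+ pi- as one permutation of {+-1..+-n}."""
        return make_permutation([self.pi_plus, self.pi_minus], self.ground_set)

    def strand_of(self, e: int) -> Cycle:
        if e in self.pi_plus:
            return self.pi_plus
        if e in self.pi_minus:
            return self.pi_minus
        raise ChromosomeError(f"element {e} not on either strand")

    def same_strand(self, x: int, y: int) -> bool:
        return (x in self.pi_plus) == (y in self.pi_plus)

    def __eq__(self, other: object) -> bool:
        # Chromosomes are equal as permutations: which strand is written
        # as pi+ is a choice of reading direction, not of molecule.
        if not isinstance(other, Chromosome):
            return NotImplemented
        if self.n != other.n:
            return False
        return self.pi_plus in (other.pi_plus, other.pi_minus)

    def __hash__(self) -> int:
        return hash((self.n, frozenset((self.pi_plus, self.pi_minus))))

    def __str__(self) -> str:
        return f"{self.pi_plus!r}{self.pi_minus!r}"

    @classmethod
    def from_permutation(cls, perm: Permutation, n: int) -> "Chromosome":
        """Rebuild a chromosome from pi = pi+ pi-; fails if ``perm`` is not
        a product of two complementary admissible strands."""
        cyc = cycle_decomposition(perm, include_fixed=True)
        if len(cyc) != 2:
            raise ChromosomeError(
                f"permutation has {len(cyc)} cycles, a chromosome has 2"
            )
        plus = cyc[0] if 1 in cyc[0] else cyc[1]
        minus = cyc[1] if plus is cyc[0] else cyc[0]
        chrom = cls(plus, n)
        if chrom.pi_minus != minus:
            raise ChromosomeError("cycles are not mutually reverse-complementary")
        return chrom


def from_gene_order(g: GeneOrder) -> Chromosome:
    """Embed a gene order as the chromosome whose pi+ is the cycle of its genes."""
    return Chromosome(Cycle(g.genes), g.n)


def to_gene_order(
    c: Chromosome, start_gene: int | None = None, circular: bool = True
) -> GeneOrder:
    """Linearize pi+ into a gene order.

    By default starts at the strand element with the smallest absolute
    value (so a chromosome whose pi+ contains +1 always reads
    ``(1, ...)``), which makes the printed form of a circular
    chromosome unique.
    """
    strand = c.pi_plus
    if start_gene is None:
        start_gene = min(strand, key=lambda e: (abs(e), e < 0))
    elif start_gene not in strand:
        if start_gene in c.pi_minus:
            strand = c.pi_minus
        else:
            raise ChromosomeError(f"start gene {start_gene} not on either strand")
    i = strand.index(start_gene)
    return GeneOrder(strand[i:] + strand[:i], circular=circular)


def identity_chromosome(n: int) -> Chromosome:
    """I = (1,2,...,n)(-n,...,-2,-1): the sorted reference chromosome."""
    if n < 1:
        raise ChromosomeError(f"need n >= 1, got {n}")
    return Chromosome(Cycle(range(1, n + 1)), n)


def canonical_gene_order(c: Chromosome) -> GeneOrder:
    """The unique reading of a circular chromosome starting at gene +1."""
    strand = c.pi_plus if 1 in c.pi_plus else c.pi_minus
    i = strand.index(1)
    return GeneOrder(strand[i:] + strand[:i])
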