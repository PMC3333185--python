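"""Cut-circularize-linearize-and-paste (CCLP) operations as 2-cycle products.

A CCLP operation cuts a segment out of a chromosome, joins it into a
temporary circle, linearizes the circle at some site, optionally
inverts the linearized segment, and pastes it back at some site.  The
eight cut/paste/invert combinations give seven state-changing
rearrangements (the eighth is the identity):

    case  circle cut    paste site    inverted   biological name
    I     original      original      yes        reversal
    II    new           original      no         transposition
    III   new           original      yes        two adjacent reversals
    IV    original      new           no         transposition
    V     original      new           yes        transversal
    VI    new           new           no         block-interchange
    VII   new           new           yes        two overlapping reversals

Algebraically a reversal is the product of two 2-cycles with the
chromosome: gamma = (pi Gamma(v), pi Gamma(u))(u, v), with u and v on
different strands.  A non-reversal CCLP operation is a product of four
2-cycles: two splits (u, v), (pi Gamma(v), pi Gamma(u)) excising the
segment and its complement as temporary circles, then two joins
(w, x), (beta pi Gamma(x), beta pi Gamma(w)) pasting them back, where
beta pi is the four-cycle state after the splits.  The mate of each
2-cycle is computed from the state it acts on; computing the mate
join from the original chromosome instead fails to reassemble the
inverted cases (compare the worked examples in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .chromosome import Chromosome, ChromosomeError, to_gene_order
from .perm_algebra import (
    Cycle,
    Permutation,
    classify_2cycle,
    compose,
    make_permutation,
)

__all__ = [
    "CCLPOperation",
    "CCLPError",
    "ConditionError",
    "NoOpError",
    "build_reversal",
    "reversal_by_segment",
    "build_nonreversal",
    "nonreversal_by_coords",
    "apply",
    "classify_case",
    "enumerate_operations",
]

CaseLabel = Literal["I", "II", "III", "IV", "V", "VI", "VII"]

_CASE_TABLE: dict[tuple[bool, bool, bool], CaseLabel] = {
    # (cut at original site, paste at original site, inverted)
    (True, True, True): "I",
    (False, True, False): "II",
    (False, True, True): "III",
    (True, False, False): "IV",
    (True, False, True): "V",
    (False, False, False): "VI",
    (False, False, True): "VII",
}


class CCLPError(ValueError):
    """Base class for invalid CCLP operation requests."""


class ConditionError(CCLPError):
    """A numbered precondition for a non-reversal CCLP operation failed."""

    def __init__(self, condition: int, message: str):
        self.condition = condition
        super().__init__(f"condition ({condition}) violated: {message}")


class NoOpError(CCLPError):
    """The requested 2-cycle product leaves the chromosome unchanged."""


@dataclass(frozen=True)
class CCLPOperation:
    """A reversal (two 2-cycles) or non-reversal CCLP operation (four).

    ``two_cycles`` is stored in application order: the first 2-cycle
    multiplies the chromosome first.  ``params`` records the defining
    pairs ((u, v),) for a reversal or ((u, v), (w, x)) for a
    non-reversal operation, with the convention that the excised
    temporary circle is the one containing u.
    """

    two_cycles: tuple[Cycle, ...]
    kind: Literal["reversal", "non_reversal"]
    weight: int
    params: tuple[tuple[int, int], ...]
    case_label: Optional[CaseLabel] = None

    def __post_init__(self) -> None:
        expected = {"reversal": (2, 1), "non_reversal": (4, 2)}[self.kind]
        if (len(self.two_cycles), self.weight) != expected:
            raise CCLPError(
                f"{self.kind} operation needs {expected[0]} 2-cycles "
                f"and weight {expected[1]}"
            )
        if any(len(t) != 2 for t in self.two_cycles):
            raise CCLPError("every factor must be a 2-cycle")

    def as_permutation(self, n: int) -> Permutation:
        """The product of the 2-cycles (leftmost factor applied last)."""
        from .perm_algebra import GroundSet, identity

        perm = identity(GroundSet.signed(n))
        for t in self.two_cycles:
            perm = compose(make_permutation([t], perm.ground_set), perm)
        return perm

    def to_record(self, before: Chromosome) -> dict:
        after = apply(self, before)
        return {
            "kind": self.kind,
            "case": self.case_label,
            "weight": self.weight,
            "two_cycles": [list(t) for t in self.two_cycles],
            "before": list(to_gene_order(before).genes),
            "after": list(to_gene_order(after).genes),
        }


def _two_cycle_perm(pair: Cycle, pi: Chromosome) -> Permutation:
    return make_permutation([pair], pi.ground_set)


def apply(op: CCLPOperation, pi: Chromosome) -> Chromosome:
    """Multiply the operation's 2-cycles with pi; validate the result."""
    perm = pi.permutation
    for t in op.two_cycles:
        perm = compose(make_permutation([t], pi.ground_set), perm)
    try:
        return Chromosome.from_permutation(perm, pi.n)
    except ChromosomeError as exc:
        raise CCLPError(f"operation is invalid on this chromosome: {exc}") from exc


def build_reversal(pi: Chromosome, u: int, v: int) -> CCLPOperation:
    """The reversal gamma = (pi Gamma(v), pi Gamma(u))(u, v), weight 1.

    Requires u and v on different strands (i.e. (u, v) does not divide
    pi); the reversed segment runs from u to -v along u's strand.
    """
    P = pi.permutation
    if u == v or u not in pi.ground_set or v not in pi.ground_set:
        raise CCLPError(f"need two distinct elements of E, got ({u}, {v})")
    if pi.same_strand(u, v):
        raise CCLPError(
            f"(u, v) = ({u}, {v}) divides pi (same strand); "
            "a reversal needs u and v on different strands"
        )
    t1 = Cycle((u, v))
    t2 = Cycle((P(-v), P(-u)))
    op = CCLPOperation(
        two_cycles=(t1, t2),
        kind="reversal",
        weight=1,
        params=((u, v),),
        case_label="I",
    )
    if apply(op, pi) == pi:
        raise NoOpError(f"reversal ({u}, {v}) leaves the chromosome unchanged")
    return op


def reversal_by_segment(pi: Chromosome, first: int, last: int) -> CCLPOperation:
    """Reversal of the strand segment running from ``first`` to ``last``."""
    strand = pi.strand_of(first)
    if last not in strand:
        raise CCLPError(f"{first} and {last} are not on the same strand")
    return build_reversal(pi, first, -last)


def _segment(pi: Chromosome, start: int, end: int) -> list[int]:
    strand = pi.strand_of(start)
    if end not in strand:
        raise CCLPError(f"{start} and {end} are not on the same strand")
    seg = [start]
    e = start
    while e != end:
        e = strand.successor(e)
        seg.append(e)
    return seg


def build_nonreversal(
    pi: Chromosome, u: int, v: int, w: int, x: int
) -> CCLPOperation:
    """The non-reversal CCLP operation defined by the 2-cycle pairs (u,v), (w,x).

    Preconditions (each reported by number when violated):
      (1) (u, v) divides pi  -- u and v on one strand, so (u, v) and its
          mate split the two strands, excising two complementary circles;
      (2) (w, x) does not divide (u, v)pi -- the joins paste the circles
          back rather than cutting further;
      (3) w != Gamma(x) -- the joins do not merge a circle with its own
          complement;
      (4) (w, Gamma(x)) or (Gamma(w), x) does not divide (u, v)pi -- the
          rejoined strands are admissible.
    """
    P = pi.permutation
    for e in (u, v, w, x):
        if e not in pi.ground_set:
            raise CCLPError(f"element {e} not in E")
    if u == v:
        raise ConditionError(1, "u and v must be distinct")
    if not pi.same_strand(u, v):
        raise ConditionError(1, f"({u}, {v}) does not divide pi")
    t1 = Cycle((u, v))
    uvP = compose(_two_cycle_perm(t1, pi), P)
    if w == x:
        raise ConditionError(2, "w and x must be distinct")
    if classify_2cycle(Cycle((w, x)), uvP) == "split":
        raise ConditionError(2, f"({w}, {x}) divides (u, v)pi")
    if w == -x:
        raise ConditionError(3, f"w = Gamma(x) = {w}")
    div_w_gx = classify_2cycle(Cycle((w, -x)), uvP) == "split"
    div_gw_x = classify_2cycle(Cycle((-w, x)), uvP) == "split"
    if div_w_gx and div_gw_x:
        raise ConditionError(
            4, f"both ({w}, {-x}) and ({-w}, {x}) divide (u, v)pi"
        )
    t2 = Cycle((P(-v), P(-u)))
    state = compose(_two_cycle_perm(t2, pi), uvP)  # beta pi: four cycles
    t3 = Cycle((w, x))
    t4 = Cycle((state(-x), state(-w)))  # mate join from the post-split state
    op = CCLPOperation(
        two_cycles=(t1, t2, t3, t4),
        kind="non_reversal",
        weight=2,
        params=((u, v), (w, x)),
    )
    result = apply(op, pi)
    if result == pi:
        raise NoOpError(
            f"(u,v,w,x) = ({u},{v},{w},{x}) cuts and re-pastes identically"
        )
    label = _classify_from_state(pi, state, u, v, t3, t4)
    return CCLPOperation(
        two_cycles=op.two_cycles,
        kind="non_reversal",
        weight=2,
        params=op.params,
        case_label=label,
    )


def nonreversal_by_coords(
    pi: Chromosome,
    segment_start: int,
    segment_end: int,
    cut_offset: int = 0,
    paste_after: int | None = None,
    invert: bool = False,
) -> CCLPOperation:
    """Build a non-reversal CCLP operation from biological coordinates.

    The excised segment runs from ``segment_start`` to ``segment_end``
    along their common strand and is joined into a temporary circle.
    ``cut_offset`` says where the circle is linearized: 0 re-opens the
    original join site, offset c starts the linearized segment at the
    c-th segment element.  The (possibly inverted) segment is pasted
    back immediately after the remainder element ``paste_after``
    (default: the element just before the cut, i.e. the original site).
    """
    seg = _segment(pi, segment_start, segment_end)
    strand = pi.strand_of(segment_start)
    if len(seg) >= pi.n:
        raise CCLPError("segment may not cover the whole strand")
    u = segment_start
    v = strand.successor(segment_end)
    if paste_after is None:
        paste_after = strand.predecessor(segment_start)
    if paste_after not in strand or paste_after in seg:
        raise CCLPError(
            f"paste site {paste_after} is not on the remaining strand"
        )
    nxt = strand.successor(paste_after)
    x = v if nxt == u else nxt
    c = cut_offset % len(seg)
    w = -seg[c - 1] if invert else seg[c]
    return build_nonreversal(pi, u, v, w, x)


def _classify_from_state(
    pi: Chromosome,
    state: Permutation,
    u: int,
    v: int,
    t3: Cycle,
    t4: Cycle,
) -> CaseLabel:
    """Derive the case label from the four-cycle state and the joins.

    Convention: the excised temporary circle A is the cycle of the
    post-split state containing u; the remainder B contains v.  The
    join touching B determines everything: its B-side element is the
    paste site (original iff it is v) and its other end lies in A
    (not inverted; original cut iff it is u) or in the complement of A
    (inverted; original cut iff it is -predecessor(u in A... i.e.
    Gamma of A's last element)).
    """
    cycles = {c[0]: c for c in _cycles_of(state)}
    A = next(c for c in cycles.values() if u in c)
    B = next(c for c in cycles.values() if v in c)
    join = t3 if (t3[0] in B or t3[1] in B) else t4
    xb = join[0] if join[0] in B else join[1]
    ws = join[1] if xb == join[0] else join[0]
    A_bar = next(c for c in cycles.values() if -u in c)
    if ws in A:
        inverted = False
        cut_orig = ws == u
    elif ws in A_bar:
        inverted = True
        cut_orig = ws == -A.predecessor(u)
    else:  # pragma: no cover - excluded by the admissibility conditions
        raise CCLPError("join does not touch the excised circle")
    paste_orig = xb == v
    key = (cut_orig, paste_orig, inverted)
    if key == (True, True, False):
        raise NoOpError("cut and paste at the original sites without inversion")
    return _CASE_TABLE[key]


def _cycles_of(perm: Permutation) -> list[Cycle]:
    return perm.cycles(include_fixed=True)


def classify_case(op: CCLPOperation, pi: Chromosome) -> CaseLabel:
    """The rearrangement case of ``op`` acting on ``pi`` (reversals are I)."""
    if op.kind == "reversal":
        return "I"
    (u, v), _ = op.params
    P = pi.permutation
    t1, t2, t3, t4 = op.two_cycles
    state = compose(
        _two_cycle_perm(t2, pi), compose(_two_cycle_perm(t1, pi), P)
    )
    return _classify_from_state(pi, state, u, v, t3, t4)


def enumerate_operations(
    pi: Chromosome, max_n: int = 6, override: bool = False
) -> list[CCLPOperation]:
    """All valid CCLP operations on pi, deduplicated by resulting chromosome.

    Exhaustive over (u, v, w, x), so exponentially many states are
    touched; guarded to small n unless ``override`` is set.
    """
    n = pi.n
    if n > max_n and not override:
        raise CCLPError(
            f"enumerate_operations guard: n={n} > {max_n} "
            f"(~{4 * n * n * (2 * n) * (2 * n)} candidate products; "
            "pass override=True to force)"
        )
    ops: list[CCLPOperation] = []
    seen: set[Chromosome] = set()
    elements = sorted(pi.ground_set.elements)
    # reversals: u and v on different strands
    for u in elements:
        for v in elements:
            if u >= v or pi.same_strand(u, v):
                continue
            try:
                op = build_reversal(pi, u, v)
            except NoOpError:
                continue
            result = apply(op, pi)
            if result not in seen:
                seen.add(result)
                ops.append(op)
    # non-reversal CCLP operations: (u, v) on one strand, (w, x) joins
    seen_nr: set[Chromosome] = set()
    for strand in (pi.pi_plus, pi.pi_minus):
        for i, u in enumerate(strand):
            for v in strand[i + 1 :]:
                for a, w in enumerate(elements):
                    for x in elements[a + 1 :]:
                        try:
                            op = build_nonreversal(pi, u, v, w, x)
                        except (ConditionError, NoOpError):
                            continue
                        result = apply(op, pi)
                        if result not in seen_nr:
                            seen_nr.add(result)
                            ops.append(op)
    return ops
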