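"""Optimal weighted sorting of a chromosome by CCLP operations.

With reversals weighted 1 and non-reversal CCLP operations weighted 2,
the minimum weight needed to transform a chromosome pi into the sorted
reference I = (1,2,...,n)(-n,...,-2,-1) is

    (|E| - n_c(I pi^-1)) / 2  =  ||I pi^-1|| / 2,

where I pi^-1 is the *residual*: the permutation that multiplied with
pi gives I.  The bound follows from counting 2-cycles: a reversal
contributes two factors to the residual and a non-reversal operation
four, so each unit of weight can reduce the residual norm by at most 2.

The sorter attains the bound greedily.  Each iteration scans adjacent
pairs (x, y) in the cycles of the residual (x, y adjacent means the
residual maps x to y):

* if some pair lies on one strand of pi (a *split pair*), the two
  splits beta = (pi Gamma(y), pi Gamma(x))(x, y) excise complementary
  temporary circles, and a rejoin pair (x', y') adjacent in
  I (beta pi)^-1 always exists whose joins reassemble two admissible
  strands -- a non-reversal CCLP operation, dropping the residual norm
  by 4 at weight 2;

* otherwise every adjacent pair spans both strands, and the first pair
  of the first nontrivial residual cycle yields a reversal, dropping
  the norm by 2 at weight 1.

The per-iteration work is a scan over adjacent pairs, O(n), so a
sorting sequence of delta operations costs O(delta n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .cclp_ops import (
    CCLPOperation,
    _classify_from_state,
    apply as apply_op,
    build_reversal,
)
from .chromosome import (
    Chromosome,
    GeneOrder,
    from_gene_order,
    identity_chromosome,
    to_gene_order,
)
from .perm_algebra import (
    Cycle,
    Permutation,
    classify_2cycle,
    compose,
    inverse,
    make_permutation,
    norm,
)

__all__ = [
    "SortingTrace",
    "residual",
    "lower_bound_weight",
    "find_split_pair",
    "find_rejoin_pair",
    "sort_chromosome",
    "distance",
]


class SortingError(RuntimeError):
    """An algorithm invariant failed -- this should never happen on valid input."""


@dataclass(frozen=True)
class SortingTrace:
    """The ordered operations sorting ``start`` into the identity."""

    start: Chromosome
    operations: tuple[CCLPOperation, ...]
    intermediates: tuple[Chromosome, ...]  # chromosome after each operation
    norm_drops: tuple[int, ...]

    @property
    def total_weight(self) -> int:
        return sum(op.weight for op in self.operations)

    @property
    def delta(self) -> int:
        return len(self.operations)

    def to_json(self, circular: bool = True, indent: int | None = None) -> str:
        records = []
        cur = self.start
        for op, after, drop in zip(
            self.operations, self.intermediates, self.norm_drops
        ):
            rec = op.to_record(cur)
            rec["norm_drop"] = drop
            records.append(rec)
            cur = after
        payload = {
            "input": list(to_gene_order(self.start).genes),
            "n": self.start.n,
            "circular": circular,
            "operations": records,
            "total_weight": self.total_weight,
            "delta": self.delta,
        }
        return json.dumps(payload, indent=indent)

    def to_table(self) -> str:
        lines = ["step\tcase\tweight\tresult"]
        for i, (op, after) in enumerate(
            zip(self.operations, self.intermediates), start=1
        ):
            order = " ".join(str(g) for g in to_gene_order(after).genes)
            lines.append(f"{i}\t{op.case_label}\t{op.weight}\t{order}")
        return "\n".join(lines)


def residual(pi: Chromosome) -> Permutation:
    """I pi^-1: the permutation whose product with pi is the identity
    chromosome."""
    I = identity_chromosome(pi.n).permutation
    return compose(I, inverse(pi.permutation))


def lower_bound_weight(pi: Chromosome) -> int:
    """The minimum CCLP sorting weight (2n - n_c(I pi^-1)) / 2."""
    h = norm(residual(pi))
    if h % 2:  # mate cycles pair up, so the residual norm is always even
        raise SortingError(f"residual norm {h} is odd for {pi}")
    return h // 2


def _adjacent_pairs(perm: Permutation):
    """Adjacent pairs (x, perm(x)) scanned in canonical cycle order."""
    for cyc in perm.cycles(include_fixed=False):
        k = len(cyc)
        for i in range(k):
            yield cyc[i], cyc[(i + 1) % k]


def find_split_pair(
    pi: Chromosome, res: Permutation | None = None
) -> Optional[tuple[int, int]]:
    """First adjacent residual pair (x, y) lying on a single strand of pi."""
    if res is None:
        res = residual(pi)
    for x, y in _adjacent_pairs(res):
        if pi.same_strand(x, y):
            return x, y
    return None


def find_rejoin_pair(state: Permutation, n: int) -> tuple[int, int]:
    """First adjacent pair (x', y') of I (beta pi)^-1 whose joins rebuild
    a chromosome.

    ``state`` is beta pi: the four pairwise-complementary cycles left
    after the two splits.  The pair (x', y') together with its mate
    (beta pi Gamma(y'), beta pi Gamma(x')) must fuse the four cycles
    into two admissible strands; such a pair always exists, so failing
    to find one is a hard error, never silently ignored.
    """
    I = identity_chromosome(n).permutation
    res = compose(I, inverse(state))
    for xp, yp in _adjacent_pairs(res):
        if classify_2cycle(Cycle((xp, yp)), state) == "split":
            continue  # not a join on the four-cycle state
        t3 = Cycle((xp, yp))
        t4 = Cycle((state(-yp), state(-xp)))
        perm = compose(
            make_permutation([t4], state.ground_set),
            compose(make_permutation([t3], state.ground_set), state),
        )
        try:
            Chromosome.from_permutation(perm, n)
        except Exception:
            continue
        return xp, yp
    raise SortingError(
        "no admissible rejoin pair exists in the four-cycle state "
        f"{state} -- this contradicts the split/rejoin guarantee"
    )


def sort_chromosome(pi: Chromosome) -> SortingTrace:
    """Sort pi into I with a minimum-weight sequence of CCLP operations.

    Per step the residual norm is asserted to drop by exactly twice the
    operation weight, so the final weight meets the lower bound.
    """
    n = pi.n
    cur = pi
    ops: list[CCLPOperation] = []
    inters: list[Chromosome] = []
    drops: list[int] = []
    res = residual(cur)
    while not res.is_identity:
        norm_before = norm(res)
        pair = find_split_pair(cur, res)
        if pair is not None:
            x, y = pair
            P = cur.permutation
            t1 = Cycle((x, y))
            t2 = Cycle((P(-y), P(-x)))
            state = compose(
                make_permutation([t2], P.ground_set),
                compose(make_permutation([t1], P.ground_set), P),
            )
            xp, yp = find_rejoin_pair(state, n)
            t3 = Cycle((xp, yp))
            t4 = Cycle((state(-yp), state(-xp)))
            label = _classify_from_state(cur, state, x, y, t3, t4)
            op = CCLPOperation(
                two_cycles=(t1, t2, t3, t4),
                kind="non_reversal",
                weight=2,
                params=((x, y), (xp, yp)),
                case_label=label,
            )
        else:
            # every adjacent residual pair spans both strands: reversal
            cyc = res.cycles(include_fixed=False)[0]
            op = build_reversal(cur, cyc[0], cyc[1])
        cur = apply_op(op, cur)
        res = residual(cur)
        drop = norm_before - norm(res)
        if drop != 2 * op.weight:
            raise SortingError(
                f"operation {op.params} dropped the residual norm by {drop}, "
                f"expected {2 * op.weight}"
            )
        ops.append(op)
        inters.append(cur)
        drops.append(drop)
    trace = SortingTrace(
        start=pi,
        operations=tuple(ops),
        intermediates=tuple(inters),
        norm_drops=tuple(drops),
    )
    return trace


def distance(g: GeneOrder) -> int:
    """The optimal CCLP sorting weight of a gene order, in O(n) time."""
    return lower_bound_weight(from_gene_order(g))
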