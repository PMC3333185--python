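# cclp — sorting signed gene orders by cut-circularize-linearize-and-paste operations

Genome rearrangement studies compare species by the large-scale
operations — reversals, transpositions, block-interchanges — needed to
turn one gene order into another. A **cut-circularize-linearize-and-paste
(CCLP) operation** subsumes all of these with one primitive that also
occurs in the immune response of higher animals: cut a segment out of a
chromosome, join its ends into a temporary circle, re-open the circle
at any site, optionally invert the linearized segment, and paste it
back anywhere. The eight cut/paste/invert combinations give seven
distinct rearrangements (cases I–VII): reversal, two kinds of
transposition, transversal, block-interchange, and two double-reversal
variants.

Because reversals are observed far more often than other rearrangements,
this package solves the **weighted** sorting problem with reversals at
weight 1 and all other CCLP operations at weight 2. It is intended for
researchers in comparative genomics and phylogenetics who need exact
weighted rearrangement distances and explicit optimal sorting scenarios
for single (circular or linear) chromosomes.

## The model

A chromosome with genes 1..n is a permutation of E = {±1, …, ±n}: the
product π = π⁺π⁻ of its two complementary DNA strands, where the strand
π⁺ is an *admissible* n-cycle (never containing a gene together with
its negation) and π⁻ = Γ(π⁺)⁻¹Γ is its reverse complement under the
sign-flip involution Γ = (1,−1)(2,−2)⋯(n,−n). With ‖α‖ = |E| − n_c(α)
the minimum number of 2-cycles composing α (n_c counts cycles including
fixed points), the residual Iπ⁻¹ against the sorted chromosome
I = (1,…,n)(−n,…,−1) governs everything:

* a reversal is a product of two 2-cycles with π and lowers ‖Iπ⁻¹‖ by
  at most 2; any other CCLP operation is a product of four 2-cycles
  and lowers it by at most 4;
* hence the optimal sorting weight is at least ‖Iπ⁻¹‖ / 2 — and the
  algorithm implemented here always attains it:
  each iteration scans the adjacent pairs of the residual's cycles for
  a pair lying on a single strand (which yields a norm-drop-4
  non-reversal operation via a split/rejoin construction) and otherwise
  applies a norm-drop-2 reversal. The whole sort runs in O(δn) time
  for δ operations; the distance alone is O(n).

## Worked example

```
$ cclp distance "1 3 2"
2
$ cclp sort "1 3 2"
input: circular: 1 3 2
step	case	weight	result
1	IV	2	1 2 3
total weight 2 in 1 operation(s)
$ cclp sort "1 -4 -3 -2 5 6"
input: circular: 1 -4 -3 -2 5 6
step	case	weight	result
1	I	1	1 2 3 4 5 6
total weight 1 in 1 operation(s)
```

`1 3 2` is one transposition away from the identity: a single
non-reversal CCLP operation (here classified as case IV, a
transposition) of weight 2 sorts it, matching the distance printed by
the O(n) formula. `1 -4 -3 -2 5 6` carries one inverted block, so a
single reversal (case I, weight 1) suffices. `--format json` emits the
full machine-readable trace (the 2-cycles of every operation and every
intermediate gene order), which `cclp verify trace.json` re-applies and
checks bit-exactly.

Classification and seeded simulation:

```
$ cclp classify "1 2 3 4 5 6" "1 5 3 4 2 6"
VI
$ cclp simulate --n 6 --ops 2 --seed 5 --count 2
seed	n	k	order	weight_bound
5	6	2	1 3 -2 -5 4 6	4
6	6	2	1 6 -4 -3 2 -5	4
```

The same functionality is available as a library:

```python
from cclp import GeneOrder, from_gene_order, sort_chromosome, distance

trace = sort_chromosome(from_gene_order(GeneOrder((1, 5, 3, 4, 2, 6))))
trace.total_weight      # 2 — one block-interchange
distance(GeneOrder((1, 5, 3, 4, 2, 6)))   # 2, without building a trace
```

## Layout

| module | contents |
| --- | --- |
| `cclp.perm_algebra` | cycles, composition, conjugation, norm, divisibility, split/join |
| `cclp.chromosome` | Γ, admissible strands, reverse complement, gene-order embedding |
| `cclp.cclp_ops` | reversal and non-reversal operation construction, application, case classification, exhaustive enumeration |
| `cclp.sorter` | residual, weight lower bound, the optimal sorting algorithm, traces |
| `cclp.oracle_fixtures` | brute-force norm, shortest-path state-graph oracle, seeded generators |
| `cclp.cli` | `cclp sort / distance / classify / simulate / verify` |

See `docs/methods.md` for the algorithmic details, parameter choices
and limitations.
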