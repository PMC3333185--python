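# Methods

## The two-strand chromosome model

A chromosome on n genes is represented over the signed set
E = {±1, …, ±n} as the permutation π = π⁺π⁻, where the strand π⁺ is an
admissible n-cycle (it contains exactly one of +i, −i for every gene i)
and π⁻ = Γ(π⁺)⁻¹Γ is its reverse complement (Γ is the sign-flip
involution). A user-facing gene order (g₁, …, g_n) is embedded as the
cycle (g₁, …, g_n); all sorting happens on the circular model, since a
CCLP operation acting across any fixed gene has an equivalent one that
avoids it, making the circular and linear problems equivalent. The
`circular`/`linear` flag on a gene order is therefore carried for
display only.

Two chromosomes are equal when they are equal as permutations of E:
which strand is written as π⁺ is a reading convention, not a property
of the molecule. The canonical printed form reads the strand containing
+1 starting at +1; this makes traces and state-graph nodes unique.

## Operations as 2-cycle products

Multiplying a permutation by a 2-cycle either splits one cycle in two
(both elements in one cycle) or joins two cycles (elements in different
cycles). On this foundation:

* **Reversal** (weight 1): for u, v on *different* strands,
  γ = (πΓ(v), πΓ(u))(u, v) reverses the strand segment running from u
  to −v — two 2-cycles.
* **Non-reversal CCLP operation** (weight 2): for u, v on *one*
  strand, the splits (u, v) and (πΓ(v), πΓ(u)) excise a segment and
  its complement as two temporary circles, leaving a four-cycle state
  βπ; two joins (w, x) and (βπΓ(x), βπΓ(w)) then paste the circles
  back. The validity conditions are checked exactly and violations are
  reported by number: (1) (u, v) divides π; (2) (w, x) does not divide
  (u, v)π; (3) w ≠ Γ(x); (4) (w, Γ(x)) or (Γ(w), x) does not divide
  (u, v)π.

The mate of every 2-cycle is computed from **the state it acts on**:
splits use πΓ, joins use βπΓ. Using πΓ for the joins as well breaks
every inverted case (segment pasted into the complementary strand)
while leaving the non-inverted cases unchanged, because the inverted
joins touch elements whose images the splits have already moved; the
worked examples in the test suite pin this down.

Constructors exist in both vocabularies: algebraic
(`build_reversal(π, u, v)`, `build_nonreversal(π, u, v, w, x)`) and
biological (`reversal_by_segment`, `nonreversal_by_coords` taking
segment endpoints, a circle cut offset, a paste site and an inversion
flag). Products that cut and re-paste identically are rejected as
no-ops rather than returned with positive weight.

## Case classification

The seven rearrangement kinds are determined by three booleans —
circle cut at the original join site or a new one, paste at the
original cut site or a new one, inverted or not — with (original,
original, not inverted) being the identity. Classification of an
*operation* is exact because the operation records (u, v, w, x): the
excised circle is by convention the post-split cycle containing u, and
the join touching the remainder cycle (the one containing v) yields
both booleans directly.

Classifying a bare before/after *pair* of gene orders is genuinely
underdetermined — (1,2,3,4,5,6) → (1,3,4,2,5,6) is a case II
transposition when genes 2–4 are taken as the excised circle and a
case IV transposition when gene 2 is — so the CLI `classify` command
enumerates all single operations linking the pair, restricts to
minimum weight, and reports the smallest case number if several labels
remain. For the seven canonical worked examples the label is unique.

## The sorting algorithm

Let I = (1,…,n)(−n,…,−1) and call Iπ⁻¹ the residual. Each sorting
iteration scans the adjacent pairs (x, y) (meaning the residual maps x
to y) of the residual's cycles, in canonical order: cycles by
increasing minimum element, each read from its minimum.

1. If some adjacent pair lies on a single strand of π (a *split
   pair*), apply the non-reversal operation built from it: the splits
   β = (πΓ(y), πΓ(x))(x, y) leave four cycles, and a *rejoin pair*
   (x′, y′) — an adjacent pair of I(βπ)⁻¹ whose joins reassemble two
   admissible strands — always exists. It is found by the same O(n)
   adjacent-pair scan with an admissibility check per candidate; a
   constructive case analysis also proves existence, but the scan is
   simpler and is what the complexity bound charges for. Failure to
   find a pair would falsify the underlying guarantee and raises a
   hard error rather than continuing silently. Residual norm −4,
   weight 2.
2. Otherwise every adjacent pair spans both strands, and the first
   pair of the first nontrivial residual cycle gives a reversal.
   Residual norm −2, weight 1.

Each operation removes residual norm at a rate of 2 per unit weight,
the best possible, so the total weight equals the lower bound
‖Iπ⁻¹‖/2 = (2n − n_c(Iπ⁻¹))/2 — an exact optimum, not a heuristic.
The per-step drop is asserted at run time on every step. Fixing the
scan order makes any two runs on the same input produce identical
traces; any qualifying pair would preserve optimality, so the
tie-break is purely for reproducibility.

The residual norm of a valid chromosome is always even (cycles of the
residual pair up into mates), so the optimal weight is an integer; an
odd norm raises instead of silently rounding.

Complexity: composition and cycle scans are O(n) per step on plain
mappings, giving O(δn) for δ operations; `distance` computes only
n_c(Iπ⁻¹) in O(n).

## Oracles and synthetic data

The test suite never trusts the implementation to check itself:

* `brute_force_norm` finds minimal 2-cycle factorizations by
  breadth-first search over group products (guarded to |E| ≤ 6) and
  validates ‖α‖ = |E| − n_c(α) exhaustively through size 5.
* `build_state_graph`/`bfs_optimal_weight` enumerate *all* CCLP
  operations on every chromosome of small n (guarded to n ≤ 4; 48
  canonical states at n = 4) and compute true optimal weights by
  Dijkstra, independently of the sorter and the norm formula. The
  sorter is compared against this oracle exhaustively at n = 3 and on
  a 100-state seeded sample at n = 4.
* Array-level oracles in the tests re-derive every operation by direct
  cut/rotate/invert/insert list manipulation, exhaustively over all
  segments, cut sites, paste sites and inversion flags for n ≤ 4.

`random_gene_order(n, seed)` draws a uniform label permutation with
independent fair sign flips. `scramble(n, k, seed)` applies k random
valid operations to the identity (reversal or non-reversal with equal
probability, coordinates uniform over valid choices) and returns the
result with the applied operations, so the optimal distance of the
output is bounded by the applied weight. Non-reversal draws whose four
2-cycles multiply to a norm-2 permutation — weight-2 encodings of a
plain reversal, exactly the case-I-shaped products — are redrawn, so
every emitted operation is worth its recorded weight and single-step
scrambles sit at distance exactly equal to their weight.

These generators emulate rearrangement scenarios with uniform random
operations; real genomes have length-biased, hotspot-structured
rearrangements and gene families (duplicates), none of which are
modelled. Passing tests certify algebraic correctness and optimality
of the distance/scenario computation, not biological realism of the
scenarios.

## Problem sizes and defaults

Randomized checks default to n = 8 genes (large enough that all seven
cases occur in traces, small enough that hundreds of runs are
instantaneous); exhaustive oracle comparisons run at n ≤ 4 and
exhaustive algebra checks at |E| ≤ 5, the sizes at which full
enumeration is exact rather than sampled. The acceptance script pools
100 seeded runs at n = 8. Weights are fixed at 1 (reversal) and
2 (non-reversal); the optimality argument is specific to this 1:2
ratio and the package deliberately exposes no other weighting.

## Known limitations

* Single chromosomes only: no translocations, fusions or fissions.
* Genes are abstract signed labels; no sequence-level handling and no
  duplicated genes.
* The equal-weights variant of the sorting problem (where the greedy
  preference for non-reversal operations is no longer optimal in
  weight per norm unit) is out of scope.
* `enumerate_operations`, `brute_force_norm` and the state graph are
  exponential by design and guarded; they are oracles for small
  instances, not tools for real data.
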