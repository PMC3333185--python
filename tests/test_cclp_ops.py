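"""CCLP operations: the seven worked cases, equivalence with direct
array manipulation, precondition numbering, enumeration validity."""

import pytest

from cclp import (
    CCLPError,
    ConditionError,
    GeneOrder,
    NoOpError,
    apply,
    build_nonreversal,
    build_reversal,
    canonical_gene_order,
    classify_case,
    enumerate_operations,
    from_gene_order,
    identity_chromosome,
    is_admissible,
    nonreversal_by_coords,
    reversal_by_segment,
    to_gene_order,
)
from conftest import SEVEN_CASES, all_signed_orders


def canon(genes):
    return canonical_gene_order(from_gene_order(GeneOrder(genes))).genes


class TestSevenCases:
    @pytest.mark.parametrize(
        "label,cut,paste,invert,expected",
        SEVEN_CASES,
        ids=[row[0] for row in SEVEN_CASES],
    )
    def test_case_result_and_label(self, identity6, label, cut, paste, invert, expected):
        if label == "I":
            op = reversal_by_segment(identity6, 2, 4)
        else:
            op = nonreversal_by_coords(
                identity6, 2, 4, cut_offset=cut, paste_after=paste, invert=invert
            )
        assert to_gene_order(apply(op, identity6)).genes == expected
        assert op.case_label == label
        assert classify_case(op, identity6) == label
        assert op.weight == (1 if label == "I" else 2)

    def test_case_I_also_expressible_as_four_2cycles(self, identity6):
        # cutting at the original site, inverting and pasting at the
        # original site is the reversal, here built the weight-2 way
        op = nonreversal_by_coords(
            identity6, 2, 4, cut_offset=0, paste_after=1, invert=True
        )
        assert to_gene_order(apply(op, identity6)).genes == (1, -4, -3, -2, 5, 6)
        assert op.case_label == "I"


def oracle_reverse(genes, i, j):
    """Reverse positions i..j of a linear reading and flip their signs."""
    seg = tuple(-g for g in reversed(genes[i : j + 1]))
    return genes[:i] + seg + genes[j + 1 :]


def oracle_cclp(genes, i, j, c, r, invert):
    """Direct cut-circularize-linearize-paste on the array: cut positions
    i..j, open the circle at offset c, optionally invert, insert after
    position r of the remainder."""
    seg = list(genes[i : j + 1])
    rem = list(genes[:i]) + list(genes[j + 1 :])
    lin = seg[c:] + seg[:c]
    if invert:
        lin = [-g for g in reversed(lin)]
    return tuple(rem[: r + 1] + lin + rem[r + 1 :])


class TestReversalMatchesArrayOracle:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exhaustive_segments(self, n):
        for genes in all_signed_orders(n):
            pi = from_gene_order(GeneOrder(genes))
            for i in range(n):
                for j in range(i, n):
                    expected = oracle_reverse(genes, i, j)
                    try:
                        op = reversal_by_segment(pi, genes[i], genes[j])
                    except NoOpError:
                        # reversing the whole circle is the same molecule
                        assert canon(expected) == canon(genes)
                        continue
                    assert canonical_gene_order(apply(op, pi)).genes == canon(expected)

    def test_single_gene_segment_flips_one_sign(self):
        pi = from_gene_order(GeneOrder((1, 2, 3, 4, 5, 6)))
        op = reversal_by_segment(pi, 3, 3)
        assert to_gene_order(apply(op, pi)).genes == (1, 2, -3, 4, 5, 6)

    def test_same_strand_pair_rejected(self, identity6):
        with pytest.raises(CCLPError, match="different strands"):
            build_reversal(identity6, 2, 4)


class TestNonReversalMatchesArrayOracle:
    @pytest.mark.parametrize("n", [3, 4])
    def test_exhaustive_cut_paste_invert(self, n):
        for genes in all_signed_orders(n):
            pi = from_gene_order(GeneOrder(genes))
            for i in range(n):
                for j in range(i, n):
                    if j - i + 1 >= n:
                        continue
                    rem = list(genes[:i]) + list(genes[j + 1 :])
                    for c in range(j - i + 1):
                        for r in range(len(rem)):
                            for invert in (False, True):
                                expected = oracle_cclp(genes, i, j, c, r, invert)
                                try:
                                    op = nonreversal_by_coords(
                                        pi,
                                        genes[i],
                                        genes[j],
                                        cut_offset=c,
                                        paste_after=rem[r],
                                        invert=invert,
                                    )
                                except NoOpError:
                                    assert canon(expected) == canon(genes)
                                    continue
                                assert (
                                    canonical_gene_order(apply(op, pi)).genes
                                    == canon(expected)
                                ), (genes, i, j, c, r, invert)

    def test_every_application_yields_a_valid_chromosome(self):
        # admissibility and two complementary strands are re-checked by
        # the Chromosome constructor on every apply
        pi = from_gene_order(GeneOrder((1, -3, 2, 4)))
        for op in enumerate_operations(pi):
            res = apply(op, pi)
            assert is_admissible(res.pi_plus) and is_admissible(res.pi_minus)
            assert set(res.pi_plus) | set(res.pi_minus) == set(
                pi.ground_set.elements
            )


class TestNonReversalConditions:
    def test_condition_1_same_strand(self, identity6):
        with pytest.raises(ConditionError, match=r"\(1\)") as e:
            build_nonreversal(identity6, 2, -4, 3, 6)
        assert e.value.condition == 1

    def test_condition_2_join_required(self, identity6):
        # (w, x) = (3, 4) stays inside the excised circle (2,3,4)
        with pytest.raises(ConditionError, match=r"\(2\)") as e:
            build_nonreversal(identity6, 2, 5, 3, 4)
        assert e.value.condition == 2

    def test_condition_3_not_a_sign_pair(self, identity6):
        with pytest.raises(ConditionError, match=r"\(3\)") as e:
            build_nonreversal(identity6, 2, 5, 3, -3)
        assert e.value.condition == 3

    def test_condition_4_admissibility(self, identity6):
        # joining the circle (2,3,4) to its own complement (-4,-3,-2)
        with pytest.raises(ConditionError, match=r"\(4\)") as e:
            build_nonreversal(identity6, 2, 5, 3, -2)
        assert e.value.condition == 4

    def test_noop_rejected(self, identity6):
        with pytest.raises(NoOpError):
            nonreversal_by_coords(
                identity6, 2, 4, cut_offset=0, paste_after=1, invert=False
            )


class TestEnumeration:
    def test_no_operations_on_single_gene(self):
        assert enumerate_operations(identity_chromosome(1)) == []

    def test_guard_fails_loudly(self):
        with pytest.raises(CCLPError, match="guard"):
            enumerate_operations(identity_chromosome(7))

    def test_n3_reachable_states_cover_all_coordinate_outcomes(self):
        genes = (1, 2, 3)
        pi = from_gene_order(GeneOrder(genes))
        reached = {
            canonical_gene_order(apply(op, pi)).genes
            for op in enumerate_operations(pi)
        }
        expected = set()
        n = 3
        for i in range(n):
            for j in range(i, n):
                if j - i + 1 < n:
                    rem_len = n - (j - i + 1)
                    for c in range(j - i + 1):
                        for r in range(rem_len):
                            for inv in (False, True):
                                out = oracle_cclp(genes, i, j, c, r, inv)
                                if canon(out) != canon(genes):
                                    expected.add(canon(out))
                expected.add(canon(oracle_reverse(genes, i, j)))
        expected.discard(canon(genes))
        assert expected <= reached

    def test_classification_total_on_enumerated_ops(self):
        pi = from_gene_order(GeneOrder((1, 3, -2, 4)))
        labels = {classify_case(op, pi) for op in enumerate_operations(pi)}
        assert labels <= {"I", "II", "III", "IV", "V", "VI", "VII"}
        assert "I" in labels

    def test_results_are_deduplicated(self):
        pi = identity_chromosome(3)
        ops = enumerate_operations(pi)
        by_kind = {}
        for op in ops:
            key = (op.kind, canonical_gene_order(apply(op, pi)).genes)
            assert key not in by_kind, "duplicate result for same kind"
            by_kind[key] = op


class TestRecords:
    def test_json_record_shape(self, identity6):
        op = reversal_by_segment(identity6, 2, 4)
        rec = op.to_record(identity6)
        assert rec["kind"] == "reversal"
        assert rec["case"] == "I"
        assert rec["weight"] == 1
        assert rec["before"] == [1, 2, 3, 4, 5, 6]
        assert rec["after"] == [1, -4, -3, -2, 5, 6]
        assert len(rec["two_cycles"]) == 2
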