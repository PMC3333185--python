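"""Shared fixtures: the seven worked rearrangement cases and small-state
enumeration helpers."""

from itertools import permutations, product

import pytest

from cclp import GeneOrder, from_gene_order

# The seven rearrangement kinds on the chromosome (1,2,3,4,5,6), all
# acting on the segment with genes 2,3,4: each row is
# (label, cut_offset, paste_after, invert, expected gene order), where
# cut_offset 0 reopens the circle at its join site, cut_offset 1 cuts
# at the new site between genes 2 and 3, and paste_after 1 / 5 are the
# original and new insertion sites.
SEVEN_CASES = [
    ("I", 0, 1, True, (1, -4, -3, -2, 5, 6)),
    ("II", 1, 1, False, (1, 3, 4, 2, 5, 6)),
    ("III", 1, 1, True, (1, -2, -4, -3, 5, 6)),
    ("IV", 0, 5, False, (1, 5, 2, 3, 4, 6)),
    ("V", 0, 5, True, (1, 5, -4, -3, -2, 6)),
    ("VI", 1, 5, False, (1, 5, 3, 4, 2, 6)),
    ("VII", 1, 5, True, (1, 5, -2, -4, -3, 6)),
]


def all_signed_orders(n):
    """Every signed gene order on n genes (n! * 2^n linear readings)."""
    for perm in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield tuple(p * s for p, s in zip(perm, signs))


@pytest.fixture
def identity6():
    return from_gene_order(GeneOrder((1, 2, 3, 4, 5, 6)))
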