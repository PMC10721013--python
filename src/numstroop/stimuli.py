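"""Builders for the three stimulus sets used by the simulated studies.

* ``build_validation_set`` -- the 144-pair numerical Stroop validation design:
  all ordered unequal numerical pairs from {1, 2, 8, 9} crossed with all
  ordered unequal physical-rank pairs from {1, 2, 8, 9} (ranks a, b, h, i).
* ``build_reduced_set`` -- the 16-combination design used for the math-anxiety
  comparison: digit pairs 1-2, 1-8, 2-9, 8-9 in both orders, crossed with the
  two assignments of the physical ranks {2, 8} (font sizes 40 and 80).
* ``build_pairs72`` -- all 72 ordered unequal single-digit pairs 1..9 with no
  physical dimension (symbolic comparison task).
"""

from __future__ import annotations

from itertools import permutations

from .network import StimulusPair

STROOP_SIZES = (1, 2, 8, 9)
REDUCED_DIGIT_PAIRS = ((1, 2), (1, 8), (2, 9), (8, 9))
REDUCED_PHYS_RANKS = (2, 8)  # font size 40 -> rank 2, font size 80 -> rank 8


def build_validation_set() -> list[StimulusPair]:
    """The 12 x 12 = 144 Stroop pairs (equal sizes excluded on each dimension);
    exactly half are congruent."""
    num_pairs = list(permutations(STROOP_SIZES, 2))
    phys_pairs = list(permutations(STROOP_SIZES, 2))
    return [
        StimulusPair(nl, nr, pl, pr)
        for nl, nr in num_pairs
        for pl, pr in phys_pairs
    ]


def build_reduced_set() -> list[StimulusPair]:
    """The 16 unique combinations of the four digit pairs (both orders) with
    the two physical-size assignments; 8 congruent, 8 incongruent."""
    out = []
    for a, b in REDUCED_DIGIT_PAIRS:
        for nl, nr in ((a, b), (b, a)):
            for pl, pr in (
                (REDUCED_PHYS_RANKS[0], REDUCED_PHYS_RANKS[1]),
                (REDUCED_PHYS_RANKS[1], REDUCED_PHYS_RANKS[0]),
            ):
                out.append(StimulusPair(nl, nr, pl, pr))
    return out


def build_pairs72() -> list[StimulusPair]:
    """All ordered unequal single-digit pairs, physical dimension absent."""
    return [StimulusPair(a, b) for a, b in permutations(range(1, 10), 2)]
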