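"""Deterministic hand-set weight patterns and degenerate stimuli for testing.

Every fixture is generated programmatically; none is stored on disk.  The
patterns expose specific structural properties of the network:

* ``one-hot-left`` / ``one-hot-right`` -- +1 from the named field's nodes to
  its "own side larger" comparison node only.
* ``monotone-ramp`` -- weights rise linearly along the number line toward each
  side's "larger" node and fall away from it, so the net-input margin always
  favours the truly larger side; correct on all 72 pairs by construction.
* ``symmetric`` -- the ramp pattern, which is exactly mirror-symmetric:
  swapping the two stimuli swaps the winning response and preserves the
  response time.
* ``zero`` -- all-zero weights: no drive, every trial times out.
"""

from __future__ import annotations

import numpy as np

from .network import StimulusPair
from .weights import ComparisonWeights

PATTERNS = ("one-hot-left", "one-hot-right", "monotone-ramp", "symmetric", "zero")


def make_fixture(pattern: str) -> ComparisonWeights:
    """Build one of the named hand-set weight patterns."""
    w = np.zeros((2, 18))
    if pattern == "one-hot-left":
        w[0, :9] = 1.0
    elif pattern == "one-hot-right":
        w[1, 9:] = 1.0
    elif pattern in ("monotone-ramp", "symmetric"):
        ramp = np.linspace(-1.0, 1.0, 9)
        # "left larger" rises with the left field and falls with the right
        w[0, :9] = ramp
        w[0, 9:] = -ramp
        w[1, :9] = -ramp
        w[1, 9:] = ramp
    elif pattern == "zero":
        pass
    else:
        raise ValueError(f"unknown fixture pattern: {pattern!r}")
    return ComparisonWeights(w, trained=pattern != "zero")


def degenerate_stimuli() -> list[StimulusPair]:
    """Edge-case stimulus pairs: extreme and minimal distances, with and
    without the physical dimension."""
    return [
        StimulusPair(1, 9),
        StimulusPair(9, 1),
        StimulusPair(4, 5),
        StimulusPair(1, 8, 2, 8),
        StimulusPair(1, 2, 8, 2),
        StimulusPair(8, 9, 9, 8),
    ]
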