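"""Feedforward weights from the two number-line fields to the comparison nodes.

Each single-digit comparison module owns one weight matrix of shape (2, 18):
row 0 feeds the "left larger" comparison node, row 1 the "right larger" node;
columns 0..8 are the left number-line field (magnitudes 1..9) and columns 9..17
the right field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

WEIGHT_SHAPE = (2, 18)
SCHEMA_VERSION = 1


@dataclass
class ComparisonWeights:
    """Trained (or hand-set) input->comparison weights of one module."""

    w: np.ndarray
    trained: bool = False
    n_trials_trained: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != WEIGHT_SHAPE:
            raise ValueError(
                f"weights must have shape {WEIGHT_SHAPE}, got {self.w.shape}"
            )
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if self.n_trials_trained < 0:
            raise ValueError("n_trials_trained must be >= 0")

    @classmethod
    def zeros(cls) -> "ComparisonWeights":
        return cls(np.zeros(WEIGHT_SHAPE))

    def copy(self) -> "ComparisonWeights":
        return ComparisonWeights(self.w.copy(), self.trained, self.n_trials_trained)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComparisonWeights):
            return NotImplemented
        return (
            np.array_equal(self.w, other.w)
            and self.trained == other.trained
            and self.n_trials_trained == other.n_trials_trained
        )


def save_weights(weights: ComparisonWeights, path: str | Path, *, module: str = "") -> None:
    """Write weights as JSON.  Floats are serialised via repr, so a load
    followed by a save round-trips bit-exactly."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "module": module,
        "trained": weights.trained,
        "n_trials_trained": weights.n_trials_trained,
        "w": weights.w.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_weights(path: str | Path) -> ComparisonWeights:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported weight-file schema_version: {version!r}")
    return ComparisonWeights(
        np.array(payload["w"], dtype=float),
        trained=bool(payload["trained"]),
        n_trials_trained=int(payload["n_trials_trained"]),
    )
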