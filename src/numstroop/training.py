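"""Delta-rule training of the single-digit comparison modules.

Each module learns to map two place-coded number-line fields onto its "left
larger" / "right larger" comparison nodes.  Digit pairs are sampled with
frequencies mirroring everyday number usage (small digits far more often than
large ones), which is what produces the problem-size effect: the weight margin
for 1 vs 2 ends up larger than for 8 vs 9.  The comparison nodes use a
logistic output during training; the delta rule moves each weight by
learning_rate x (target - output) x input activation, with target 1 for the
node on the truly larger side and 0 for the other.

Training streams are strictly sequential per (participant, module) so that a
checkpoint taken at trial c inside a longer run is bit-identical to the end
weights of a run of exactly c trials with the same seed (the nesting property
used by the reduced-learning studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .network import StimulusPair, encode_number, run_trial
from .params import ModelParameters
from .weights import ComparisonWeights

_TARGET_LEFT = np.array([1.0, 0.0])
_TARGET_RIGHT = np.array([0.0, 1.0])


@dataclass(frozen=True)
class TrainingSchedule:
    """Total trial count plus the intermediate checkpoints to snapshot."""

    total_trials: int
    checkpoints: tuple[int, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.total_trials < 1:
            raise ValueError("total_trials must be >= 1")
        cps = tuple(int(c) for c in self.checkpoints)
        if any(not (1 <= c <= self.total_trials) for c in cps):
            raise ValueError("checkpoints must lie in [1, total_trials]")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("checkpoints must be strictly increasing")
        object.__setattr__(self, "checkpoints", cps)

    @property
    def all_checkpoints(self) -> tuple[int, ...]:
        """Checkpoints including the final trial count."""
        if self.checkpoints and self.checkpoints[-1] == self.total_trials:
            return self.checkpoints
        return self.checkpoints + (self.total_trials,)


def sample_training_pair(
    freq_table, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw an ordered unequal digit pair, each digit with probability
    proportional to its frequency; the whole pair is redrawn on equality."""
    freq = np.asarray(freq_table, dtype=float)
    if np.count_nonzero(freq) < 2:
        raise ValueError("frequency table must have at least two nonzero entries")
    cum = np.cumsum(freq)
    cum /= cum[-1]
    while True:
        a = int(np.searchsorted(cum, rng.random(), side="right")) + 1
        b = int(np.searchsorted(cum, rng.random(), side="right")) + 1
        if a != b:
            return a, b


def _pair_encodings(params: ModelParameters) -> np.ndarray:
    """(9, 9, 18) lookup table of concatenated field encodings."""
    codes = np.stack([encode_number(n, params) for n in range(1, 10)])
    table = np.empty((9, 9, 18))
    for a in range(9):
        for b in range(9):
            table[a, b, :9] = codes[a]
            table[a, b, 9:] = codes[b]
    return table


def delta_update(
    weights: ComparisonWeights,
    pair: tuple[int, int],
    params: ModelParameters,
    _x: np.ndarray | None = None,
) -> ComparisonWeights:
    """One delta-rule step on the given ordered pair (in place)."""
    a, b = pair
    if _x is None:
        _x = np.concatenate(
            [encode_number(a, params), encode_number(b, params)]
        )
    y = expit(weights.w @ _x - params.comparison_bias)
    target = _TARGET_LEFT if a > b else _TARGET_RIGHT
    weights.w += params.learning_rate * (target - y)[:, None] * _x[None, :]
    return weights


def train_module(
    schedule: TrainingSchedule,
    params: ModelParameters,
    seed: int | np.random.SeedSequence | None = None,
) -> dict[int, ComparisonWeights]:
    """Train one comparison module, returning weights at every checkpoint.

    One sequential sampling stream drives the whole run, so the weights
    emitted at checkpoint c equal the final weights of a run of exactly c
    trials with the same seed.  The final trial count is always included as a
    checkpoint.
    """
    if seed is None:
        seed = schedule.seed if schedule.seed is not None else params.seed
    rng = np.random.default_rng(seed)
    freq = np.asarray(params.freq_table, dtype=float)
    if np.count_nonzero(freq) < 2:
        raise ValueError("frequency table must have at least two nonzero entries")
    cum = np.cumsum(freq)
    cum /= cum[-1]
    table = _pair_encodings(params)
    lr = params.learning_rate
    bias = params.comparison_bias
    w = np.zeros((2, 18))
    wanted = set(schedule.all_checkpoints)
    out: dict[int, ComparisonWeights] = {}
    for t in range(1, schedule.total_trials + 1):
        while True:
            a = int(np.searchsorted(cum, rng.random(), side="right"))
            b = int(np.searchsorted(cum, rng.random(), side="right"))
            if a != b:
                break
        x = table[a, b]
        y = expit(w @ x - bias)
        target = _TARGET_LEFT if a > b else _TARGET_RIGHT
        w += lr * (target - y)[:, None] * x[None, :]
        if t in wanted:
            out[t] = ComparisonWeights(w.copy(), trained=True, n_trials_trained=t)
    return out


def all_ordered_pairs() -> list[tuple[int, int]]:
    """All 72 ordered unequal single-digit pairs."""
    return [(a, b) for a in range(1, 10) for b in range(1, 10) if a != b]


def evaluate_module_accuracy(
    weights: ComparisonWeights, params: ModelParameters
) -> float:
    """Fraction of the 72 ordered pairs answered correctly in comparison-only
    trials (timeouts count as errors)."""
    n_correct = 0
    for a, b in all_ordered_pairs():
        result = run_trial(
            StimulusPair(a, b), weights, None, params, task="comparison"
        )
        n_correct += result.correct
    return n_correct / 72.0
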