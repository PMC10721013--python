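"""Model parameters for the dual-route number comparison network.

All constants of the network live in a single immutable container so that a
simulation is fully specified by (parameters, weights, stimulus).  Defaults are
the published constants of the model family: accumulation rate ``tau`` = 0.25,
response threshold ``theta`` = 0.75, lateral inhibition ``w_inh`` = -0.5, trial
cutoff ``t_max`` = 200, task-demand activations 1.0 (relevant) / 0.15
(irrelevant), and task-demand weights initialised at 0.5.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


def digit_frequency_table(exponent: float = 1.25) -> tuple[float, ...]:
    """Digit-presentation probabilities proportional to n**-exponent, n = 1..9.

    Everyday number usage is heavily skewed toward small numbers, with corpus
    counts falling off faster than 1/n; a power law with exponent 1.25
    reproduces that skew, and through frequency-weighted training it produces
    the problem-size effect (1 vs 2 easier than 8 vs 9) together with the
    barely-learned 8-vs-9 discrimination that drives the errors of the Stroop
    simulations.  ``exponent=1`` gives the plain harmonic profile.
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    raw = [float(n) ** -exponent for n in range(1, 10)]
    total = sum(raw)
    return tuple(r / total for r in raw)


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the network, its training, and the attention manipulation.

    Parameters
    ----------
    tau
        Rate of activation accumulation per time step (dimensionless, in (0, 1]).
    theta
        Response threshold: a trial ends when a response node reaches it.
    w_inh
        Lateral inhibitory weight between the two response nodes (<= 0).
    t_max
        Maximum number of time steps per trial; reaching it without a decision
        is recorded as a timeout.
    d_relevant, d_irrelevant
        Task-demand activation assigned to the task-relevant and -irrelevant
        dimension (top-down vs stimulus-driven attention).
    attention_scale_numerical, attention_scale_physical
        Multiplicative attention factors in [0, 1] applied to the task-demand
        activation of each stimulus dimension; 0.95 on the numerical dimension
        is the high-math-anxiety manipulation.
    td_weight_init
        Initial weight from task-demand nodes to comparison-layer nodes.
    learning_rate
        Delta-rule step size for training the input->comparison weights.
    numberline_sigma
        Width (standard deviation, in number-line units) of the Gaussian
        place-code activation profile.
    comparison_bias
        Optional firing threshold of the comparison nodes' logistic output:
        activation is logistic(net - comparison_bias).  The default 0 is the
        plain logistic resting at 0.5; the same nonlinearity is used during
        delta-rule training and trial dynamics.
    freq_table
        Sampling probability of digits 1..9 during training; must sum to 1.
    n_train
        Default number of training trials per comparison module.
    seed
        Default RNG seed.
    """

    tau: float = 0.25
    theta: float = 0.75
    w_inh: float = -0.5
    t_max: int = 200
    d_relevant: float = 1.0
    d_irrelevant: float = 0.15
    attention_scale_numerical: float = 1.0
    attention_scale_physical: float = 1.0
    td_weight_init: float = 0.5
    learning_rate: float = 0.012
    numberline_sigma: float = 0.6
    comparison_bias: float = 0.0
    freq_table: tuple[float, ...] = dataclasses.field(
        default_factory=digit_frequency_table
    )
    n_train: int = 100_000
    seed: int = 2023

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.theta <= 0.0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.w_inh > 0.0:
            raise ValueError(f"w_inh must be <= 0, got {self.w_inh}")
        if self.t_max < 1:
            raise ValueError(f"t_max must be >= 1, got {self.t_max}")
        for name in ("attention_scale_numerical", "attention_scale_physical"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.d_relevant < 0.0 or self.d_irrelevant < 0.0:
            raise ValueError("task-demand activations must be non-negative")
        if self.learning_rate <= 0.0:
            raise ValueError("learning_rate must be positive")
        if self.numberline_sigma < 0.0:
            raise ValueError("numberline_sigma must be non-negative")
        if self.comparison_bias < 0.0:
            raise ValueError("comparison_bias must be non-negative")
        if self.n_train < 0:
            raise ValueError("n_train must be non-negative")
        freq = tuple(float(f) for f in self.freq_table)
        if len(freq) != 9:
            raise ValueError("freq_table must have exactly 9 entries")
        if any(f < 0.0 for f in freq):
            raise ValueError("freq_table entries must be non-negative")
        if not math.isclose(sum(freq), 1.0, rel_tol=0.0, abs_tol=1e-12):
            raise ValueError("freq_table must sum to 1 within 1e-12")
        object.__setattr__(self, "freq_table", freq)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)
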