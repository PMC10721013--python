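"""Cognitive control: task-demand gating, response-conflict energy, and the
conflict-gated Hebbian adaptation rule.

The task demand layer holds one node per stimulus dimension (numerical,
physical).  Its activation multiplicatively gates the flow from that
dimension's comparison nodes to the response layer, implementing top-down
(relevant dimension, activation 1.0) versus stimulus-driven (irrelevant
dimension, activation 0.15) attention.  Attention impairments scale these
activations; anxiety is modelled as a reduced scale on the numerical node.

Conflict is the energy in the response layer: the product of the two mutually
inhibiting response nodes' activations.  The adaptation rule that would use
this signal to retune the demand->comparison weights is implemented but ships
disabled; no simulation here adapts attention within or across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters

#: Column layout of the task-demand weight matrix: demand node (row) x
#: comparison node (column: numerical-left, numerical-right, physical-left,
#: physical-right).
TD_SHAPE = (2, 4)


@dataclass
class TaskDemandState:
    """Activations and outgoing weights of the task demand layer.

    ``d_numerical`` / ``d_physical`` are the base activations assigned by task
    relevance; ``attention_numerical`` / ``attention_physical`` are the
    multiplicative attention scales in [0, 1].  The effective activation that
    gates a route is base x scale.
    """

    d_numerical: float
    d_physical: float
    attention_numerical: float = 1.0
    attention_physical: float = 1.0
    td_weights: np.ndarray = field(default_factory=lambda: np.full(TD_SHAPE, 0.5))

    def __post_init__(self) -> None:
        if self.d_numerical < 0 or self.d_physical < 0:
            raise ValueError("task-demand activations must be >= 0")
        for name in ("attention_numerical", "attention_physical"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.td_weights = np.asarray(self.td_weights, dtype=float)
        if self.td_weights.shape != TD_SHAPE:
            raise ValueError(f"td_weights must have shape {TD_SHAPE}")

    @property
    def effective_numerical(self) -> float:
        return self.d_numerical * self.attention_numerical

    @property
    def effective_physical(self) -> float:
        return self.d_physical * self.attention_physical

    def copy(self) -> "TaskDemandState":
        return TaskDemandState(
            self.d_numerical,
            self.d_physical,
            self.attention_numerical,
            self.attention_physical,
            self.td_weights.copy(),
        )


def demand_for_task(task: str, params: ModelParameters) -> TaskDemandState:
    """Assign task-demand activations for a task.

    ``numerical`` (numerical Stroop) and ``comparison`` (symbolic comparison,
    physical module off) make the numerical dimension relevant; ``physical``
    (physical Stroop) reverses relevance.  Attention scales are taken from the
    parameters and applied per dimension, not per relevance.
    """
    if task in ("numerical", "comparison"):
        d_num, d_phys = params.d_relevant, params.d_irrelevant
    elif task == "physical":
        d_num, d_phys = params.d_irrelevant, params.d_relevant
    else:
        raise ValueError(f"unknown task: {task!r}")
    return TaskDemandState(
        d_numerical=d_num,
        d_physical=d_phys,
        attention_numerical=params.attention_scale_numerical,
        attention_physical=params.attention_scale_physical,
        td_weights=np.full(TD_SHAPE, params.td_weight_init),
    )


def gate(
    c_numerical: np.ndarray,
    c_physical: np.ndarray | None,
    demand: TaskDemandState,
) -> np.ndarray:
    """Response drive per side from gated comparison activations.

    drive[side] = sum over modules of comparison activation x effective demand
    activation x demand->comparison weight.  ``c_physical`` may be None when
    the physical module is off (symbolic comparison task).
    """
    c_num = np.asarray(c_numerical, dtype=float)
    eff_num = demand.effective_numerical
    drive = c_num * eff_num * demand.td_weights[0, 0:2]
    if c_physical is not None:
        c_phys = np.asarray(c_physical, dtype=float)
        drive = drive + c_phys * demand.effective_physical * demand.td_weights[1, 2:4]
    return drive


def conflict_energy(
    response_activations: np.ndarray, *, w_inh: float | None = None, scaled: bool = False
) -> float:
    """Energy in the response layer: the product of the response activations.

    With ``scaled=True`` the Hopfield-style variant -2 * w_inh * a_left *
    a_right is returned instead (requires ``w_inh``); the default is the raw
    product.
    """
    a = np.asarray(response_activations, dtype=float)
    if a.shape != (2,):
        raise ValueError("expected exactly two response activations")
    if np.any(a < 0):
        raise ValueError("response activations must be >= 0")
    e = float(a[0] * a[1])
    if scaled:
        if w_inh is None:
            raise ValueError("scaled energy requires w_inh")
        e *= -2.0 * w_inh
    return e


def hebbian_adapt(
    demand: TaskDemandState,
    conflict: float,
    pre: np.ndarray,
    post: np.ndarray,
    *,
    enabled: bool,
    rate: float | None = None,
) -> TaskDemandState:
    """Conflict-gated Hebbian update of the demand->comparison weights.

    When enabled, each weight moves by rate x conflict x pre x post, where
    ``pre`` is the (2,) vector of effective demand activations and ``post``
    the (4,) vector of comparison activations; weights are floored at 0.  When
    disabled the state is returned unchanged, bit-exactly.  Disabled is the
    default for every shipped simulation.
    """
    if not enabled:
        return demand
    if rate is None:
        raise ValueError(
            "adaptation enabled but no rate given; supply control.adaptation.params"
        )
    if conflict < 0:
        raise ValueError("conflict must be >= 0")
    pre = np.asarray(pre, dtype=float).reshape(2, 1)
    post = np.asarray(post, dtype=float).reshape(1, 4)
    new = demand.copy()
    new.td_weights = np.maximum(0.0, new.td_weights + rate * conflict * (pre @ post))
    return new


def apply_attention_impairment(
    params: ModelParameters, which: str, scale: float
) -> ModelParameters:
    """Return parameters with the attention scale of the named dimension(s) set.

    ``which`` is "numerical", "physical" or "both"; ``scale`` must lie in
    (0, 1].  All other parameters are untouched.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"attention scale must be in (0, 1], got {scale}")
    if which == "numerical":
        return params.replace(attention_scale_numerical=scale)
    if which == "physical":
        return params.replace(attention_scale_physical=scale)
    if which == "both":
        return params.replace(
            attention_scale_numerical=scale, attention_scale_physical=scale
        )
    raise ValueError(f"unknown dimension: {which!r}")
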