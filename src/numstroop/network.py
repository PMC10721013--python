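"""The dual-route comparison network: place-code encoding, comparison-layer
propagation, gated response accumulation with lateral inhibition, and
single-trial simulation.

Architecture
------------
Two single-digit comparison modules (numerical size, physical size) each hold
two number-line fields of nine place-coded nodes (magnitudes 1..9) feeding two
comparison nodes ("left larger", "right larger") through trained weights.
Comparison activation is gated by the task demand layer and accumulated by two
response nodes coupled by lateral inhibition (w_inh).  A trial ends when a
response node reaches the threshold theta, or at t_max steps (timeout).  The
number of steps taken is the simulated response time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import TaskDemandState, conflict_energy, demand_for_task, gate
from .params import ModelParameters
from .weights import ComparisonWeights

TASKS = ("numerical", "physical", "comparison")


def encode_number(n: int, params: ModelParameters) -> np.ndarray:
    """Place-code a magnitude on the nine-node number line.

    Node j (magnitude j) is activated by a Gaussian profile centred on n with
    constant width ``numberline_sigma`` (linear scaling, constant
    variability):  a_j = exp(-(j - n)^2 / (2 sigma^2)).  At sigma -> 0 the code
    degenerates to a one-hot vector at node n.
    """
    if not isinstance(n, (int, np.integer)) or not (1 <= n <= 9):
        raise ValueError(f"magnitude must be an integer in 1..9, got {n!r}")
    nodes = np.arange(1, 10, dtype=float)
    sigma = params.numberline_sigma
    if sigma == 0.0:
        return (nodes == n).astype(float)
    return np.exp(-((nodes - n) ** 2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class StimulusPair:
    """One trial's stimuli: numerical sizes and (optionally) physical ranks.

    Physical sizes are ranks a..i mapped onto 1..9 on an identical number
    line; they are absent for the pure symbolic comparison task.
    """

    num_left: int
    num_right: int
    phys_left: int | None = None
    phys_right: int | None = None

    def __post_init__(self) -> None:
        for v in (self.num_left, self.num_right):
            if not (1 <= v <= 9):
                raise ValueError(f"numerical size must be in 1..9, got {v}")
        if self.num_left == self.num_right:
            raise ValueError("numerical sizes must differ")
        if (self.phys_left is None) != (self.phys_right is None):
            raise ValueError("physical sizes must be given for both sides or neither")
        if self.phys_left is not None:
            for v in (self.phys_left, self.phys_right):
                if not (1 <= v <= 9):
                    raise ValueError(f"physical rank must be in 1..9, got {v}")
            if self.phys_left == self.phys_right:
                raise ValueError("physical ranks must differ")

    @property
    def has_physical(self) -> bool:
        return self.phys_left is not None


def congruency_of(stimulus: StimulusPair) -> str:
    """"congruent" iff the numerically larger side is also the physically
    larger side, else "incongruent"."""
    if not stimulus.has_physical:
        raise ValueError("congruency requires both stimulus dimensions")
    num_side = stimulus.num_left > stimulus.num_right
    phys_side = stimulus.phys_left > stimulus.phys_right
    return "congruent" if num_side == phys_side else "incongruent"


def distance_class(a: int, b: int) -> str:
    """Distance classification for the four-size Stroop design {1, 2, 8, 9}:
    distances 1 and 6 are "small" (close), 7 and 8 are "large" (far)."""
    d = abs(a - b)
    if d in (1, 6):
        return "small"
    if d in (7, 8):
        return "large"
    raise ValueError(
        f"distance {d} undefined for the four-size design (sizes must come from"
        " {1, 2, 8, 9})"
    )


@dataclass
class NetworkState:
    """State of the comparison and response layers at one time step.

    ``c_numerical`` / ``c_physical`` are the comparison nodes' *integrated net
    inputs*; the comparison activation visible to the response layer is the
    logistic of the integrator (the same output nonlinearity the weights were
    trained under), so comparison activations always lie in (0, 1).
    ``c_physical`` is None when the physical module is off.  A freshly reset
    state is all-zero at step 0.
    """

    c_numerical: np.ndarray
    c_physical: np.ndarray | None
    response: np.ndarray
    step: int = 0

    def comparison_activations(
        self, bias: float = 0.0
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Logistic comparison-node outputs (numerical, physical), with the
        firing threshold ``bias`` subtracted from the integrated input."""
        from scipy.special import expit

        act_num = expit(self.c_numerical - bias)
        act_phys = (
            None if self.c_physical is None else expit(self.c_physical - bias)
        )
        return act_num, act_phys

    @classmethod
    def zeros(cls, physical: bool = True) -> "NetworkState":
        return cls(
            c_numerical=np.zeros(2),
            c_physical=np.zeros(2) if physical else None,
            response=np.zeros(2),
            step=0,
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.c_numerical.copy(),
            None if self.c_physical is None else self.c_physical.copy(),
            self.response.copy(),
            self.step,
        )


def comparison_net_input(
    left: np.ndarray, right: np.ndarray, weights: ComparisonWeights
) -> np.ndarray:
    """Net input to the ("left larger", "right larger") comparison nodes:
    the weighted sum over all 18 number-line nodes of both fields."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != (9,) or right.shape != (9,):
        raise ValueError("number-line fields must be 9-vectors")
    return weights.w @ np.concatenate([left, right])


def stimulus_net_inputs(
    stimulus: StimulusPair,
    weights_numerical: ComparisonWeights,
    weights_physical: ComparisonWeights | None,
    params: ModelParameters,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Constant within-trial net inputs to both modules' comparison nodes."""
    net_num = comparison_net_input(
        encode_number(stimulus.num_left, params),
        encode_number(stimulus.num_right, params),
        weights_numerical,
    )
    net_phys = None
    if weights_physical is not None and stimulus.has_physical:
        net_phys = comparison_net_input(
            encode_number(stimulus.phys_left, params),
            encode_number(stimulus.phys_right, params),
            weights_physical,
        )
    return net_num, net_phys


def step_dynamics(
    state: NetworkState,
    net_numerical: np.ndarray,
    net_physical: np.ndarray | None,
    demand: TaskDemandState,
    params: ModelParameters,
) -> NetworkState:
    """Advance the network one time step.

    Activation cascades input -> comparison -> response within the step:
    comparison nodes first accumulate their (static) net input at rate tau
    into their integrators, whose logistic is the comparison activation; the
    response nodes then accumulate the gated comparison output of the updated
    comparison layer plus lateral inhibition w_inh times the other response
    node's previous activation, also at rate tau.  Response activations are
    firing rates bounded in [0, 1]: floored at 0 so inhibition cannot drive a
    node to negative firing, and saturating at 1.
    """
    tau = params.tau
    c_num = state.c_numerical + tau * np.asarray(net_numerical)
    c_phys = None
    if state.c_physical is not None:
        if net_physical is None:
            net_physical = np.zeros(2)
        c_phys = state.c_physical + tau * np.asarray(net_physical)
    new = NetworkState(c_num, c_phys, state.response, state.step)
    act_num, act_phys = new.comparison_activations(params.comparison_bias)
    drive = gate(act_num, act_phys, demand)
    inhibition = params.w_inh * state.response[::-1]
    response = np.clip(state.response + tau * (drive + inhibition), 0.0, 1.0)
    return NetworkState(c_num, c_phys, response, state.step + 1)


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``response`` is "left", "right" or "none" (timeout / unresolved tie);
    ``rt`` is the integer number of steps taken (t_max on timeout); ``correct``
    scores the response against the task-relevant dimension; the conflict
    trace holds the response-layer energy at every step up to rt.
    """

    response: str
    rt: int
    correct: bool
    conflict_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.response not in ("left", "right", "none"):
            raise ValueError(f"invalid response: {self.response!r}")
        self.conflict_trace = np.asarray(self.conflict_trace, dtype=float)
        if self.response == "none" and self.correct:
            raise ValueError("a timeout cannot be correct")
        if len(self.conflict_trace) != self.rt:
            raise ValueError("conflict trace length must equal rt")


def _correct_side(stimulus: StimulusPair, task: str) -> str:
    if task == "physical":
        return "left" if stimulus.phys_left > stimulus.phys_right else "right"
    return "left" if stimulus.num_left > stimulus.num_right else "right"


def run_trial(
    stimulus: StimulusPair,
    weights_numerical: ComparisonWeights,
    weights_physical: ComparisonWeights | None,
    params: ModelParameters,
    task: str = "numerical",
    demand: TaskDemandState | None = None,
    initial_state: NetworkState | None = None,
) -> TrialResult:
    """Simulate one trial to threshold or timeout.

    The network is reset to all-zero activations (trials are independent)
    unless an explicit ``initial_state`` is supplied for diagnostics.  For
    ``task="comparison"`` the physical module is turned off and the stimulus
    may omit physical sizes.  If both response nodes reach theta on the same
    step the more active one wins; an exact tie is recorded as no response.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task: {task!r}")
    physical_on = task != "comparison" and weights_physical is not None
    if task == "physical" and not stimulus.has_physical:
        raise ValueError("the physical task requires physical stimulus sizes")
    if demand is None:
        demand = demand_for_task(task, params)
    net_num, net_phys = stimulus_net_inputs(
        stimulus, weights_numerical, weights_physical if physical_on else None, params
    )
    if initial_state is None:
        state = NetworkState.zeros(physical=physical_on)
    else:
        if initial_state.step != 0:
            raise ValueError("initial_state must start at step 0")
        state = initial_state.copy()
    trace: list[float] = []
    correct_side = _correct_side(stimulus, task)
    while state.step < params.t_max:
        state = step_dynamics(state, net_num, net_phys, demand, params)
        trace.append(conflict_energy(state.response))
        r = state.response
        if r.max() >= params.theta:
            if r[0] > r[1]:
                response = "left"
            elif r[1] > r[0]:
                response = "right"
            else:  # exact tie: conservative no-decision
                response = "none"
            return TrialResult(
                response=response,
                rt=state.step,
                correct=(response == correct_side),
                conflict_trace=np.array(trace),
            )
    return TrialResult(
        response="none",
        rt=params.t_max,
        correct=False,
        conflict_trace=np.array(trace),
    )
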