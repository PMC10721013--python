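"""Participant-level simulation harness for the simulated studies.

A *participant* is a seed: each simulated participant owns private training
streams (one per comparison module) derived from the design's master seed, and
every condition of a design references the same participant store.  Matched
low/high math-anxiety conditions therefore run on identical weights per
participant by construction -- conditions cannot own weights, only reference
them -- which is what makes their trial-by-trial response times comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import apply_attention_impairment
from .network import (
    StimulusPair,
    congruency_of,
    distance_class,
    run_trial,
)
from .params import ModelParameters
from .stimuli import build_pairs72, build_reduced_set, build_validation_set
from .training import TrainingSchedule, train_module
from .weights import ComparisonWeights

MODULES = ("numerical", "physical")

_SET_BUILDERS = {
    "validation-144": build_validation_set,
    "reduced-16": build_reduced_set,
    "pairs-72": build_pairs72,
}


@dataclass(frozen=True)
class Condition:
    """One cell of a design: a label plus its manipulations.

    ``attention`` maps a dimension ("numerical", "physical" or "both") to a
    scale in (0, 1]; ``checkpoint`` selects trained weights at a given trial
    count (None = fully trained); ``theta`` overrides the response threshold.
    """

    label: str
    attention: tuple[tuple[str, float], ...] = ()
    checkpoint: int | None = None
    theta: float | None = None

    def apply(self, params: ModelParameters) -> ModelParameters:
        for which, scale in self.attention:
            params = apply_attention_impairment(params, which, scale)
        if self.theta is not None:
            params = params.replace(theta=self.theta)
        return params


@dataclass(frozen=True)
class ExperimentDesign:
    """Task, stimulus set, participant count and conditions of one study."""

    task: str
    stimulus_set: str
    conditions: tuple[Condition, ...]
    n_participants: int = 30
    seed: int = 2023
    custom_stimuli: tuple[StimulusPair, ...] | None = None

    def __post_init__(self) -> None:
        if self.task not in ("numerical", "physical", "comparison"):
            raise ValueError(f"unknown task: {self.task!r}")
        if self.stimulus_set not in (*_SET_BUILDERS, "custom"):
            raise ValueError(f"unknown stimulus set: {self.stimulus_set!r}")
        if self.stimulus_set == "custom" and not self.custom_stimuli:
            raise ValueError("custom stimulus set requires custom_stimuli")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        stimuli = self.stimuli()
        has_phys = all(s.has_physical for s in stimuli)
        if self.task in ("numerical", "physical") and not has_phys:
            raise ValueError(f"the {self.task} task requires both dimensions")
        if self.stimulus_set == "pairs-72" and any(s.has_physical for s in stimuli):
            raise ValueError("pairs-72 forbids the physical dimension")

    def stimuli(self) -> list[StimulusPair]:
        if self.stimulus_set == "custom":
            return list(self.custom_stimuli)
        return _SET_BUILDERS[self.stimulus_set]()

    def participant_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.n_participants)


class ParticipantStore:
    """Checkpointed weights per (participant, module), trained once per design.

    The store is keyed by participant index; both comparison modules of a
    participant are trained independently on private streams spawned from the
    participant's seed, so LMA/HMA conditions drawing from the same store see
    identical weights.
    """

    def __init__(self) -> None:
        self._weights: dict[tuple[int, str], dict[int, ComparisonWeights]] = {}

    @classmethod
    def train(
        cls,
        params: ModelParameters,
        n_participants: int,
        seed: int,
        checkpoints: tuple[int, ...] = (),
        total_trials: int | None = None,
        modules: tuple[str, ...] = MODULES,
    ) -> "ParticipantStore":
        total = params.n_train if total_trials is None else total_trials
        schedule = TrainingSchedule(total_trials=total, checkpoints=checkpoints)
        store = cls()
        for pid, pseed in enumerate(np.random.SeedSequence(seed).spawn(n_participants)):
            module_seeds = pseed.spawn(len(MODULES))
            for module, mseed in zip(MODULES, module_seeds):
                if module not in modules:
                    continue
                store._weights[(pid, module)] = train_module(
                    schedule, params, seed=mseed
                )
        return store

    def put(
        self, participant: int, module: str, checkpoints: dict[int, ComparisonWeights]
    ) -> None:
        self._weights[(participant, module)] = dict(checkpoints)

    def get(
        self, participant: int, module: str, checkpoint: int | None = None
    ) -> ComparisonWeights:
        try:
            by_cp = self._weights[(participant, module)]
        except KeyError:
            raise KeyError(
                f"no weights trained for participant {participant}, module {module!r}"
            ) from None
        if checkpoint is None:
            checkpoint = max(by_cp)
        if checkpoint not in by_cp:
            raise KeyError(
                f"no checkpoint at {checkpoint} trials for participant "
                f"{participant}, module {module!r}; have {sorted(by_cp)}"
            )
        return by_cp[checkpoint]

    @property
    def participants(self) -> list[int]:
        return sorted({pid for pid, _ in self._weights})

    def save(self, directory, manifest_extra: dict | None = None) -> None:
        """Write one JSON weight file per (participant, module, checkpoint)
        plus a manifest listing them."""
        import json
        from pathlib import Path

        from .weights import save_weights

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for (pid, module), by_cp in sorted(self._weights.items()):
            for cp, weights in sorted(by_cp.items()):
                name = f"p{pid:03d}_{module}_{cp}.json"
                save_weights(weights, directory / name, module=module)
                entries.append(
                    {
                        "participant": pid,
                        "module": module,
                        "checkpoint": cp,
                        "file": name,
                    }
                )
        manifest = {"schema_version": 1, "weights": entries}
        if manifest_extra:
            manifest.update(manifest_extra)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "ParticipantStore":
        import json
        from pathlib import Path

        from .weights import load_weights

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        store = cls()
        for entry in manifest["weights"]:
            key = (int(entry["participant"]), entry["module"])
            store._weights.setdefault(key, {})[int(entry["checkpoint"])] = load_weights(
                directory / entry["file"]
            )
        return store


def _maybe_distance_class(a: int, b: int) -> str | None:
    try:
        return distance_class(a, b)
    except ValueError:
        return None


def run_design(
    design: ExperimentDesign,
    params: ModelParameters,
    store: ParticipantStore | None = None,
) -> pd.DataFrame:
    """Simulate every condition x participant x stimulus of a design.

    Returns a trial table with one row per trial carrying the stimulus
    descriptors, congruency and distance classes, the response, the response
    time in steps, correctness, and the conflict-energy trace (as a tuple, in
    the ``conflict_trace`` column).  Trial-to-trial adaptation is off and
    activations are reset per trial, so rows are independent.
    """
    if store is None:
        checkpoints = tuple(
            sorted({c.checkpoint for c in design.conditions if c.checkpoint})
        )
        modules = MODULES if design.task != "comparison" else ("numerical",)
        store = ParticipantStore.train(
            params,
            design.n_participants,
            design.seed,
            checkpoints=checkpoints,
            modules=modules,
        )
    stimuli = design.stimuli()
    rows = []
    for condition in design.conditions:
        cond_params = condition.apply(params)
        for pid in range(design.n_participants):
            w_num = store.get(pid, "numerical", condition.checkpoint)
            w_phys = (
                store.get(pid, "physical", condition.checkpoint)
                if design.task != "comparison"
                else None
            )
            for trial_index, stim in enumerate(stimuli):
                res = run_trial(
                    stim, w_num, w_phys, cond_params, task=design.task
                )
                rows.append(
                    {
                        "condition": condition.label,
                        "participant": pid,
                        "task": design.task,
                        "trial_index": trial_index,
                        "num_left": stim.num_left,
                        "num_right": stim.num_right,
                        "phys_left": stim.phys_left,
                        "phys_right": stim.phys_right,
                        "congruency": congruency_of(stim)
                        if stim.has_physical
                        else None,
                        "num_distance": abs(stim.num_left - stim.num_right),
                        "num_distance_class": _maybe_distance_class(
                            stim.num_left, stim.num_right
                        ),
                        "phys_distance_class": _maybe_distance_class(
                            stim.phys_left, stim.phys_right
                        )
                        if stim.has_physical
                        else None,
                        "response": res.response,
                        "rt": res.rt,
                        "correct": res.correct,
                        "conflict_trace": tuple(res.conflict_trace),
                    }
                )
    return pd.DataFrame(rows)


TRIAL_CSV_COLUMNS = [
    "participant",
    "task",
    "trial_index",
    "num_left",
    "num_right",
    "phys_left",
    "phys_right",
    "congruency",
    "num_distance_class",
    "phys_distance_class",
    "response",
    "rt",
    "correct",
]


def export_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write the trial-level CSV (one row per trial, canonical columns,
    plus the condition label when more than one condition is present)."""
    cols = list(TRIAL_CSV_COLUMNS)
    if trials["condition"].nunique() > 1:
        cols = ["condition"] + cols
    trials[cols].to_csv(path, index=False)


def run_threshold_sweep(
    design: ExperimentDesign,
    theta_values,
    params: ModelParameters,
    store: ParticipantStore | None = None,
) -> pd.DataFrame:
    """Re-run a design at each response threshold (speed-accuracy trade-off).

    Returns one row per (theta, condition) with the mean correct-trial RT and
    the error percentage.
    """
    theta_values = [float(t) for t in theta_values]
    if any(t <= 0 for t in theta_values):
        raise ValueError("theta values must be positive")
    if store is None:
        checkpoints = tuple(
            sorted({c.checkpoint for c in design.conditions if c.checkpoint})
        )
        modules = MODULES if design.task != "comparison" else ("numerical",)
        store = ParticipantStore.train(
            params,
            design.n_participants,
            design.seed,
            checkpoints=checkpoints,
            modules=modules,
        )
    out = []
    for theta in theta_values:
        trials = run_design(design, params.replace(theta=theta), store=store)
        for label, group in trials.groupby("condition", sort=False):
            correct = group[group["correct"]]
            out.append(
                {
                    "theta": theta,
                    "condition": label,
                    "mean_rt": correct["rt"].mean() if len(correct) else np.nan,
                    "error_pct": 100.0 * (1.0 - group["correct"].mean()),
                    "n_trials": len(group),
                }
            )
    return pd.DataFrame(out)
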