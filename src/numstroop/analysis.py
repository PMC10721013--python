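"""Condition summaries and derived effect measures.

All measures are computed from the raw trial table by direct passes (no
incremental accumulators), mirroring how the behavioural literature scores
these tasks: mean response times over correct ("successful") trials, hit
percentages per congruency cell with timeouts counted as misses, and
difference scores -- the size congruity (interference) effect in time steps
and the hits-based interference index in percentage points, where larger
values mean more interference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def summarise(trials: pd.DataFrame, grouping) -> pd.DataFrame:
    """Group-wise mean correct-trial RT, error % and hit %.

    ``grouping`` is a column name or list of names.  Groups with no correct
    trial get a missing (NaN) mean RT and 100% errors.  Rows are ordered
    deterministically by the group key.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    if isinstance(grouping, str):
        grouping = [grouping]
    rows = []
    for key, group in trials.groupby(grouping, sort=True, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        correct = group[group["correct"]]
        rows.append(
            {
                **dict(zip(grouping, key)),
                "mean_rt": correct["rt"].mean() if len(correct) else np.nan,
                "pct_errors": 100.0 * (1.0 - group["correct"].mean()),
                "pct_hits": 100.0 * group["correct"].mean(),
                "n_trials": len(group),
            }
        )
    return pd.DataFrame(rows)


def interference_indices(trials: pd.DataFrame) -> dict[str, float]:
    """Interference difference scores from the congruency cells.

    * ``rt_interference`` -- incongruent minus congruent mean correct-trial RT
      (the size congruity effect, in steps).
    * ``hits_interference`` -- congruent hit % minus incongruent hit %
      (percentage points).

    A missing congruency cell raises; a cell with no correct trial yields NaN
    for the RT index (flagged missing, never treated as zero).
    """
    cells = summarise(trials, "congruency").set_index("congruency")
    for cell in ("congruent", "incongruent"):
        if cell not in cells.index:
            raise ValueError(f"missing {cell} cell")
    rt = cells.loc["incongruent", "mean_rt"] - cells.loc["congruent", "mean_rt"]
    hits = cells.loc["congruent", "pct_hits"] - cells.loc["incongruent", "pct_hits"]
    return {"rt_interference": float(rt), "hits_interference": float(hits)}


def distance_effect(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct-trial RT per numerical distance, with the fitted slope.

    The numerical distance effect is present when mean RT falls with distance;
    it is operationalised as a negative least-squares slope of the
    per-distance means on distance (the table carries the slope in
    ``attrs["slope"]``).
    """
    table = summarise(trials, "num_distance")
    ok = table["mean_rt"].notna()
    slope = np.nan
    if ok.sum() >= 2:
        slope = float(
            np.polyfit(table.loc[ok, "num_distance"], table.loc[ok, "mean_rt"], 1)[0]
        )
    table.attrs["slope"] = slope
    return table


def size_effect(trials: pd.DataFrame) -> float:
    """Problem-size interference in steps: mean correct RT over the extreme
    large pairs {8-9, 9-8} minus the extreme small pairs {1-2, 2-1}."""
    pairs = trials[["num_left", "num_right"]].apply(frozenset, axis=1)
    small = trials[(pairs == frozenset({1, 2})) & trials["correct"]]
    large = trials[(pairs == frozenset({8, 9})) & trials["correct"]]
    if small.empty or large.empty:
        raise ValueError(
            "size effect requires correct trials on both the {1,2} and {8,9} pairs"
        )
    return float(large["rt"].mean() - small["rt"].mean())


def energy_timecourse(
    trials: pd.DataFrame, selector=None
) -> pd.DataFrame:
    """Mean conflict energy per time step across the selected trials.

    ``selector`` is an optional boolean mask or callable on the trial table.
    Traces are aligned at step 1; ragged tails are averaged over however many
    trials reach each step, with that count reported per step rather than
    truncated silently.  Returns columns step, mean_energy, sem_energy, n.
    """
    if selector is not None:
        mask = selector(trials) if callable(selector) else selector
        trials = trials[mask]
    if trials.empty:
        raise ValueError("selector matches no trials")
    traces = [np.asarray(t, dtype=float) for t in trials["conflict_trace"]]
    max_len = max(len(t) for t in traces)
    rows = []
    for step in range(max_len):
        vals = np.array([t[step] for t in traces if len(t) > step])
        rows.append(
            {
                "step": step + 1,
                "mean_energy": vals.mean(),
                "sem_energy": vals.std(ddof=1) / np.sqrt(len(vals))
                if len(vals) > 1
                else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def export_energy_csv(trials: pd.DataFrame, path) -> None:
    """Long-format per-step energy CSV: participant, trial_index, step, energy."""
    rows = []
    for _, row in trials.iterrows():
        for step, energy in enumerate(row["conflict_trace"], start=1):
            rows.append(
                {
                    "participant": row["participant"],
                    "trial_index": row["trial_index"],
                    "step": step,
                    "energy": energy,
                }
            )
    pd.DataFrame(rows, columns=["participant", "trial_index", "step", "energy"]).to_csv(
        path, index=False
    )
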