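"""Tabular schemas and readers/writers for trial and spike data.

Two plain tables carry a dataset:

* **trial table** — one row per trial with task factors, the display
  arrangement (``loc_obj1..loc_obj4`` give the location of each object),
  the targets of the problem (``targets``, semicolon-joined object ids),
  the choice, outcome flags and event timestamps in seconds from trial
  start.
* **spike table** — long format, one row per spike:
  ``cell_id, session_id, problem_id, cycle, trial_in_cycle, spike_time_s``
  with times relative to the trial start.

A third small table describes the cells (``cell_id, session_id,
animal_id, region``).  CSV and Parquet are both supported, chosen by
file extension.  A stable integer ``trial_uid`` is assigned to the trial
table on load and used to join spikes to trials.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .task import (
    N_OBJECTS,
    ProblemRecord,
    TrialRecord,
    classify_problem,
)

TRIAL_COLUMNS = [
    "session_id", "animal_id", "problem_id", "n_targets", "object_set",
    "cycle", "trial_in_cycle",
    "loc_obj1", "loc_obj2", "loc_obj3", "loc_obj4",
    "targets", "chosen_object", "chosen_location",
    "correct", "rewarded", "aborted",
    "t_ch_on", "t_go", "t_touch", "t_fb_on",
]

SPIKE_COLUMNS = [
    "cell_id", "session_id", "problem_id", "cycle", "trial_in_cycle", "spike_time_s",
]

CELL_COLUMNS = ["cell_id", "session_id", "animal_id", "region"]

TRIAL_KEY = ["session_id", "problem_id", "cycle", "trial_in_cycle"]


def _opt(x) -> float:
    return math.nan if x is None else float(x)


def problems_to_frame(problems: Sequence[ProblemRecord]) -> pd.DataFrame:
    """Flatten problem records into the trial table, adding ``trial_uid``,
    ``response_type`` and the per-cycle ``n_already_sampled`` count."""
    rows = []
    for prob in problems:
        rtypes = classify_problem(prob)
        sampled_before: dict[int, set] = {}
        for trial, rtype in zip(prob.trials, rtypes):
            seen = sampled_before.setdefault(trial.cycle, set())
            rows.append({
                "session_id": trial.session_id,
                "animal_id": trial.animal_id,
                "problem_id": trial.problem_id,
                "n_targets": trial.n_targets,
                "object_set": trial.object_set,
                "cycle": trial.cycle,
                "trial_in_cycle": trial.trial_in_cycle,
                **{f"loc_obj{o}": trial.arrangement[o] for o in range(1, N_OBJECTS + 1)},
                "targets": ";".join(str(o) for o in sorted(prob.target_objects)),
                "chosen_object": _opt(trial.chosen_object),
                "chosen_location": _opt(trial.chosen_location),
                "correct": bool(trial.correct),
                "rewarded": bool(trial.rewarded),
                "aborted": bool(trial.aborted),
                "t_ch_on": _opt(trial.t_ch_on),
                "t_go": _opt(trial.t_go),
                "t_touch": _opt(trial.t_touch),
                "t_fb_on": _opt(trial.t_fb_on),
                "response_type": rtype.value,
                "n_already_sampled": len(seen),
                "n_found_before": len(seen & prob.target_objects),
            })
            if not trial.failed:
                seen.add(trial.chosen_object)
    frame = pd.DataFrame(
        rows, columns=TRIAL_COLUMNS + ["response_type", "n_already_sampled", "n_found_before"])
    return add_trial_uid(frame)


def frame_to_problems(frame: pd.DataFrame) -> list[ProblemRecord]:
    """Rebuild problem records from a trial table (inverse of
    :func:`problems_to_frame` up to derived columns)."""
    problems: list[ProblemRecord] = []
    for (_, problem_id), grp in frame.groupby(["session_id", "problem_id"], sort=False):
        grp = grp.sort_values(["cycle", "trial_in_cycle"])
        first = grp.iloc[0]
        targets = frozenset(int(t) for t in str(first["targets"]).split(";"))
        trials = []
        for _, row in grp.iterrows():
            chosen = row["chosen_object"]
            trials.append(TrialRecord(
                session_id=str(row["session_id"]),
                animal_id=str(row["animal_id"]),
                problem_id=str(problem_id),
                n_targets=int(row["n_targets"]),
                object_set=int(row["object_set"]),
                cycle=int(row["cycle"]),
                trial_in_cycle=int(row["trial_in_cycle"]),
                arrangement={o: int(row[f"loc_obj{o}"]) for o in range(1, N_OBJECTS + 1)},
                chosen_object=None if pd.isna(chosen) else int(chosen),
                chosen_location=None if pd.isna(row["chosen_location"]) else int(row["chosen_location"]),
                correct=bool(row["correct"]),
                rewarded=bool(row["rewarded"]),
                aborted=bool(row["aborted"]),
                t_ch_on=None if pd.isna(row["t_ch_on"]) else float(row["t_ch_on"]),
                t_go=None if pd.isna(row["t_go"]) else float(row["t_go"]),
                t_touch=None if pd.isna(row["t_touch"]) else float(row["t_touch"]),
                t_fb_on=None if pd.isna(row["t_fb_on"]) else float(row["t_fb_on"]),
            ))
        problems.append(ProblemRecord(
            problem_id=str(problem_id),
            n_targets=int(first["n_targets"]),
            object_set=int(first["object_set"]),
            target_objects=targets,
            trials=trials,
        ))
    return problems


DERIVED_COLUMNS = ["response_type", "n_already_sampled", "n_found_before"]


def ensure_derived(trials: pd.DataFrame) -> pd.DataFrame:
    """Guarantee the derived columns (response type, per-cycle sampling
    counts) are present, recomputing them from the raw table if needed."""
    if all(c in trials.columns for c in DERIVED_COLUMNS):
        return trials
    rebuilt = problems_to_frame(frame_to_problems(trials))
    merged = trials.drop(columns=DERIVED_COLUMNS, errors="ignore").merge(
        rebuilt[TRIAL_KEY + DERIVED_COLUMNS], on=TRIAL_KEY, how="left",
        validate="one_to_one")
    return add_trial_uid(merged)


def add_trial_uid(trials: pd.DataFrame) -> pd.DataFrame:
    trials = trials.reset_index(drop=True).copy()
    trials["trial_uid"] = np.arange(len(trials), dtype=np.int64)
    return trials


def attach_trial_uid(spikes: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Join spikes to trials on the four-column trial key, adding
    ``trial_uid`` and the CH/FB event times needed for alignment."""
    key_cols = trials[TRIAL_KEY + ["trial_uid", "t_ch_on", "t_fb_on"]]
    merged = spikes.merge(key_cols, on=TRIAL_KEY, how="left", validate="many_to_one")
    if merged["trial_uid"].isna().any():
        bad = merged[merged["trial_uid"].isna()].head()
        raise ValueError(f"spikes reference unknown trials, e.g.\n{bad}")
    merged["trial_uid"] = merged["trial_uid"].astype(np.int64)
    return merged


def _read(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write(frame: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".parquet", ".pq"}:
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    frame = _read(Path(path))
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return ensure_derived(add_trial_uid(frame))


def write_trials(trials: pd.DataFrame, path) -> None:
    _write(trials.drop(columns=["trial_uid"], errors="ignore"), Path(path))


def read_spikes(path) -> pd.DataFrame:
    frame = _read(Path(path))
    missing = set(SPIKE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    return frame


def write_spikes(spikes: pd.DataFrame, path) -> None:
    _write(spikes[SPIKE_COLUMNS], Path(path))


def read_cells(path) -> pd.DataFrame:
    frame = _read(Path(path))
    missing = set(CELL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return frame


def write_cells(cells: pd.DataFrame, path) -> None:
    cols = [c for c in cells.columns if c in CELL_COLUMNS or c.startswith("truth_")]
    _write(cells[cols], Path(path))


def validate_trials(trials: pd.DataFrame) -> list[dict]:
    """Schema checks on a trial table; returns a list of violations
    (empty when the table passes)."""
    issues: list[dict] = []
    loc_cols = [f"loc_obj{o}" for o in range(1, N_OBJECTS + 1)]
    locs = trials[loc_cols].to_numpy()
    bad_arr = np.sort(locs, axis=1) != np.arange(1, N_OBJECTS + 1)
    for idx in np.nonzero(bad_arr.any(axis=1))[0]:
        issues.append({"row": int(idx), "check": "arrangement_bijection",
                       "detail": f"locations {locs[idx].tolist()}"})
    times = trials[["t_ch_on", "t_go", "t_touch", "t_fb_on"]].to_numpy(dtype=float)
    diffs = np.diff(times, axis=1)
    with np.errstate(invalid="ignore"):
        bad_order = np.any((diffs <= 0) & ~np.isnan(diffs), axis=1)
    for idx in np.nonzero(bad_order)[0]:
        issues.append({"row": int(idx), "check": "event_ordering",
                       "detail": f"times {times[idx].tolist()}"})
    resp = trials.dropna(subset=["chosen_object"])
    chosen_loc = np.array([
        row[f"loc_obj{int(row['chosen_object'])}"] for _, row in resp.iterrows()
    ])
    mism = resp["chosen_location"].to_numpy(dtype=float) != chosen_loc
    for idx in resp.index[mism]:
        issues.append({"row": int(idx), "check": "chosen_location_consistency",
                       "detail": "chosen_location disagrees with arrangement"})
    bad_reward = trials["rewarded"] & ~trials["correct"]
    for idx in trials.index[bad_reward]:
        issues.append({"row": int(idx), "check": "reward_implies_correct", "detail": ""})
    return issues


def validate_spikes(spikes: pd.DataFrame, trials: pd.DataFrame) -> list[dict]:
    """Spike-table checks: known trials, non-negative times."""
    issues: list[dict] = []
    try:
        merged = attach_trial_uid(spikes, trials)
    except ValueError as err:
        return [{"row": -1, "check": "spike_trial_join", "detail": str(err)}]
    neg = merged["spike_time_s"].to_numpy() < 0
    for idx in np.nonzero(neg)[0][:50]:
        issues.append({"row": int(idx), "check": "spike_time_nonnegative",
                       "detail": f"t={merged['spike_time_s'].iloc[idx]}"})
    return issues
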