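"""Synthetic behavioral sessions and Poisson-spiking populations.

The behavioral agent emulates a well-trained animal playing the
four-cycle object search task: Cycle 1 is a (nearly) revisit-free random
search; after the Cycle-1 reward the agent usually acquires the target
assignment in one shot and exploits it for Cycles 2-4; occasionally
learning fails, in which case Cycle 2 opens with at least one error
before the targets are acquired.  Lapses are controlled by explicit
probabilities so chance-level and optimal agents are both limiting
cases.

The spiking population contains explore-preferring and
exploit-preferring cells whose preference is *conjunctive* with trial
phase — a cell's rate gain acts either around choice-array onset (CH) or
around feedback onset (FB), not both — plus outcome-tuned cells,
object/location tuning, and untuned cells.  Spiking is an inhomogeneous
Poisson process with piecewise-constant rate per trial epoch.  Ground
truth (cell labels, per-problem learning outcome, per-trial latent
state) is returned for downstream validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .task import N_CYCLES, N_OBJECTS, ProblemRecord, TrialRecord

# trial event timing ranges (seconds): wait before choice array, delay
# to GO, reaction time, touch hold before feedback, feedback duration
WAIT_RANGE = (0.8, 1.2)
DELAY_RANGE = (1.2, 2.0)
RT_RANGE = (0.15, 0.8)
HOLD_RANGE = (0.35, 0.45)
FB_DURATION = 0.3

#: phase gate around each aligned event: gain acts from 200 ms before
#: onset through 500 ms after (sustained pre-onset preference)
PHASE_GATE = (-0.2, 0.5)

MAX_TRIALS_PER_CYCLE = 20


@dataclass
class AgentConfig:
    """Behavioral agent parameters.

    ``p_revisit_lapse`` is the per-opportunity probability that a
    previously sampled object re-enters the Cycle-1 choice pool (an
    imperfect-memory lapse): at 0 the search is revisit-free, at 1 the
    agent is memoryless and revisits at the chance rate
    ``n_sampled / 4``.  ``p_exploit_error_by_cycle`` gives the
    probability that an exploit-cycle choice lapses to a non-target,
    non-increasing over cycles.  ``favored_location_bias`` is the extra
    probability mass the first Cycle-1 choice places on one display
    location.
    """

    p_learn_one_shot: float = 0.9
    p_revisit_lapse: float = 0.35
    p_exploit_error_by_cycle: dict[int, float] = field(
        default_factory=lambda: {2: 0.12, 3: 0.05, 4: 0.03})
    favored_location_bias: float = 0.6
    favored_location: int = 2
    p_no_response: float = 0.01
    p_abort: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.p_learn_one_shot, self.p_revisit_lapse,
                 self.favored_location_bias, self.p_no_response, self.p_abort,
                 *self.p_exploit_error_by_cycle.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all agent probabilities must lie in [0, 1]")
        errs = [self.p_exploit_error_by_cycle.get(c, 0.0) for c in range(2, N_CYCLES + 1)]
        if any(b > a + 1e-12 for a, b in zip(errs, errs[1:])):
            raise ValueError("p_exploit_error_by_cycle must be non-increasing in cycle")


def optimal_agent(seed: int = 0) -> AgentConfig:
    """Lapse-free agent: revisit-free search, perfect one-shot learning."""
    return AgentConfig(p_learn_one_shot=1.0, p_revisit_lapse=0.0,
                       p_exploit_error_by_cycle={2: 0.0, 3: 0.0, 4: 0.0},
                       favored_location_bias=0.0, p_no_response=0.0,
                       p_abort=0.0, seed=seed)


def memoryless_agent(seed: int = 0) -> AgentConfig:
    """Chance agent: Cycle-1 choices uniform over all four objects."""
    cfg = optimal_agent(seed)
    cfg.p_revisit_lapse = 1.0
    return cfg


@dataclass
class PopulationConfig:
    """Spiking-population parameters.

    Fractions give the share of cells with a cycle preference at each
    phase (explore = higher rate in the explore state, exploit the
    reverse); defaults follow typical prefrontal proportions (~7%/10%
    explore/exploit at CH, ~6%/15% at FB).  ``state_gain`` multiplies
    the baseline rate in the preferred state within the cell's phase
    gate.  Baselines are log-normal in spikes/s; object and location
    tuning are multiplicative log-normal factors applied while the
    choice is on screen.  ``failed_state_persistence`` is the
    probability that the explore state carries through the first correct
    Cycle-2 trial after a failed-learning error.
    ``graded_expectancy`` (default 0: binary state, the null ground
    truth for expectancy analyses) ramps the explore-state gain down
    across Cycle-1 sampling positions.  ``cross_phase_leakage`` (default
    0: absolute phase conjunction) lets a fraction of the state gain act
    in the cell's non-preferred phase.
    """

    n_cells: int = 64
    fraction_explore_ch: float = 0.07
    fraction_exploit_ch: float = 0.10
    fraction_explore_fb: float = 0.06
    fraction_exploit_fb: float = 0.15
    state_gain: float = 1.8
    baseline_log_mean: float = 1.8   # exp(1.8) ~ 6 spikes/s median
    baseline_log_sd: float = 0.5
    object_tuning_sd: float = 0.15
    location_tuning_sd: float = 0.15
    fraction_outcome_cells: float = 0.0
    outcome_gain: float = 1.5
    trial_rate_jitter_sd: float = 0.0  # extra log-normal rate jitter; 0 = pure Poisson
    failed_state_persistence: float = 0.5
    graded_expectancy: float = 0.0
    cross_phase_leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_explore_ch + self.fraction_exploit_ch > 1 or \
           self.fraction_explore_fb + self.fraction_exploit_fb > 1:
            raise ValueError("cycle-preferring fractions must sum to <= 1 per phase")
        if self.state_gain < 0 or self.outcome_gain < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class GroundTruth:
    """Generator-side labels used to score the analyses."""

    cells: pd.DataFrame          # cell_id, truth_label, truth_phase, truth_outcome
    problems: pd.DataFrame       # session_id, problem_id, learned (bool)
    trial_states: pd.DataFrame   # session_id, problem_id, cycle, trial_in_cycle, explore_state
    agent: dict
    population: dict

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "problems": self.problems.to_dict(orient="list"),
            "trial_states": self.trial_states.to_dict(orient="list"),
            "agent": self.agent,
            "population": self.population,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            cells=pd.DataFrame(payload["cells"]),
            problems=pd.DataFrame(payload["problems"]),
            trial_states=pd.DataFrame(payload["trial_states"]),
            agent=payload["agent"],
            population=payload["population"],
        )


# ---------------------------------------------------------------------------
# behavior


def _draw_times(rng: np.random.Generator) -> tuple[float, float, float, float]:
    t_ch = rng.uniform(*WAIT_RANGE)
    t_go = t_ch + rng.uniform(*DELAY_RANGE)
    t_touch = t_go + rng.uniform(*RT_RANGE)
    t_fb = t_touch + rng.uniform(*HOLD_RANGE)
    return t_ch, t_go, t_touch, t_fb


def _choose_cycle1(rng, sampled: set[int], lapse: float) -> int:
    # each sampled object is forgotten (re-enters the pool) independently
    pool = [o for o in range(1, N_OBJECTS + 1)
            if o not in sampled or rng.random() < lapse]
    if not pool:  # every object sampled and remembered; cycle should have ended
        pool = list(range(1, N_OBJECTS + 1))
    return int(rng.choice(pool))


def simulate_behavior(
    n_problems: int,
    agent: AgentConfig,
    seed: Optional[int] = None,
    *,
    session_id: str = "S001",
    animal_id: str = "A",
    n_targets_schedule: Optional[Sequence[int]] = None,
    block_size: int = 8,
) -> list[ProblemRecord]:
    """Simulate one session of ``n_problems`` problems.

    1- and 2-target problems alternate in blocks of ``block_size`` (they
    were blocked so the animal knew the target count in advance); the
    two object sets alternate problem by problem.  Targets are drawn
    uniformly per problem; the display arrangement is a fresh uniform
    bijection on every trial.  Event timestamps are drawn from the task
    timing ranges.
    """
    rng = np.random.default_rng(agent.seed if seed is None else seed)
    if n_targets_schedule is None:
        n_targets_schedule = [1 + (i // block_size) % 2 for i in range(n_problems)]
    problems: list[ProblemRecord] = []
    for p_idx in range(n_problems):
        n_targets = int(n_targets_schedule[p_idx])
        object_set = 1 + p_idx % 2
        targets = set(rng.choice(np.arange(1, N_OBJECTS + 1), size=n_targets,
                                 replace=False).tolist())
        problem_id = f"{session_id}-P{p_idx + 1:03d}"
        prob = ProblemRecord(problem_id=problem_id, n_targets=n_targets,
                             object_set=object_set, target_objects=frozenset(targets))
        learned = rng.random() < agent.p_learn_one_shot
        prob.learned = learned  # type: ignore[attr-defined]  # consumed by simulate_population
        for cycle in range(1, N_CYCLES + 1):
            remaining = set(targets)
            sampled: set[int] = set()
            acquired = learned or cycle >= 3  # failed learners recover within Cycle 2
            trial_idx = 1
            while remaining and trial_idx <= MAX_TRIALS_PER_CYCLE:
                arrangement = {o: int(l) for o, l in zip(
                    range(1, N_OBJECTS + 1), rng.permutation(N_OBJECTS) + 1)}
                failed_kind = None
                u = rng.random()
                if u < agent.p_no_response:
                    failed_kind = "no_response"
                elif u < agent.p_no_response + agent.p_abort:
                    failed_kind = "abort"
                t_ch, t_go, t_touch, t_fb = _draw_times(rng)
                common = dict(session_id=session_id, animal_id=animal_id,
                              problem_id=problem_id, n_targets=n_targets,
                              object_set=object_set, cycle=cycle,
                              trial_in_cycle=trial_idx, arrangement=arrangement)
                if failed_kind == "abort":
                    prob.trials.append(TrialRecord(**common, aborted=True, t_ch_on=t_ch))
                    trial_idx += 1
                    continue
                if failed_kind == "no_response":
                    prob.trials.append(TrialRecord(**common, t_ch_on=t_ch, t_go=t_go))
                    trial_idx += 1
                    continue
                if cycle == 1:
                    if trial_idx == 1 and rng.random() < agent.favored_location_bias:
                        obj = next(o for o, l in arrangement.items()
                                   if l == agent.favored_location)
                    else:
                        obj = _choose_cycle1(rng, sampled, agent.p_revisit_lapse)
                else:
                    p_err = agent.p_exploit_error_by_cycle.get(cycle, 0.0)
                    if not acquired:
                        # failed learning: open the cycle with an error
                        nontargets = [o for o in range(1, N_OBJECTS + 1)
                                      if o not in targets]
                        obj = int(rng.choice(nontargets))
                        acquired = True       # the error's feedback completes learning
                    elif rng.random() < p_err:
                        wrong = [o for o in range(1, N_OBJECTS + 1) if o not in remaining]
                        obj = int(rng.choice(wrong))
                    else:
                        obj = int(rng.choice(sorted(remaining)))
                correct = obj in remaining
                prob.trials.append(TrialRecord(
                    **common, chosen_object=obj, correct=correct, rewarded=correct,
                    t_ch_on=t_ch, t_go=t_go, t_touch=t_touch, t_fb_on=t_fb))
                sampled.add(obj)
                if correct:
                    remaining.discard(obj)
                trial_idx += 1
        problems.append(prob)
    return problems


# ---------------------------------------------------------------------------
# population


def _assign_cell_labels(rng, pop: PopulationConfig) -> pd.DataFrame:
    n = pop.n_cells
    labels = [("none", "none")] * n
    counts = {
        ("explore", "CH"): pop.fraction_explore_ch,
        ("exploit", "CH"): pop.fraction_exploit_ch,
        ("explore", "FB"): pop.fraction_explore_fb,
        ("exploit", "FB"): pop.fraction_exploit_fb,
    }
    order = rng.permutation(n)
    pos = 0
    for (lab, ph), frac in counts.items():
        k = int(round(frac * n))
        for i in order[pos:pos + k]:
            labels[i] = (lab, ph)
        pos += k
    n_out = int(round(pop.fraction_outcome_cells * n))
    outcome = np.array(["none"] * n, dtype=object)
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else []
    for i in out_idx:
        outcome[i] = "correct" if rng.random() < 0.5 else "error"
    return pd.DataFrame({
        "truth_label": [l for l, _ in labels],
        "truth_phase": [p for _, p in labels],
        "truth_outcome": outcome,
    })


def _trial_states(problems: Sequence[ProblemRecord], rng,
                  persistence: float) -> pd.DataFrame:
    """Latent explore/exploit state per trial, shared across cells.

    Explore on every Cycle-1 trial.  On failed-learning problems the
    explore state persists through Cycle-2 error trials and, with
    probability ``persistence``, through the first correct Cycle-2 trial
    that follows them; exploit otherwise.
    """
    rows = []
    for prob in problems:
        learned = getattr(prob, "learned", True)
        carried = False
        seen_c2_error = False
        for t in prob.trials:
            if t.cycle == 1:
                state = True
            elif t.cycle == 2 and not learned:
                if t.failed:
                    state = seen_c2_error and carried
                elif not t.correct:
                    state = True
                    seen_c2_error = True
                    carried = rng.random() < persistence
                elif seen_c2_error and carried:
                    state = True
                    carried = False  # one-shot switch completes after this trial
                else:
                    state = False
            else:
                state = False
            rows.append({"session_id": t.session_id, "problem_id": t.problem_id,
                         "cycle": t.cycle, "trial_in_cycle": t.trial_in_cycle,
                         "explore_state": bool(state)})
    return pd.DataFrame(rows)


def _epoch_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Flat per-epoch table (one row per piecewise-constant rate segment)."""
    rows = []
    pre, post = PHASE_GATE
    for row in trials.itertuples():
        t_ch, t_fb = row.t_ch_on, row.t_fb_on
        if np.isnan(t_ch):
            continue
        edges = [0.0, t_ch + pre, t_ch + post]
        kinds = ["base", "CH"]
        if not np.isnan(t_fb):
            edges += [t_fb + pre, t_fb + post]
            kinds += ["base", "FB"]
        edges.append(edges[-1] + 0.3)
        kinds.append("base")
        for (a, b), kind in zip(zip(edges, edges[1:]), kinds):
            if b > a:
                rows.append((row.trial_uid, a, b, kind))
    out = pd.DataFrame(rows, columns=["trial_uid", "start", "end", "kind"])
    return out


def simulate_population(
    problems: Sequence[ProblemRecord],
    pop: PopulationConfig,
    seed: Optional[int] = None,
    *,
    region: str = "PFC",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a spiking population over simulated behavior.

    Returns ``(cells, spikes, ground_truth)`` where ``cells`` and
    ``spikes`` follow the tabular schemas of :mod:`explorexploit.io`.
    Cells are dealt round-robin over the sessions present in
    ``problems``; each cell fires only on its own session's trials.
    Rates are piecewise-constant per epoch (baseline outside the two
    phase gates) and spikes are Poisson within each segment.
    """
    rng = np.random.default_rng(pop.seed if seed is None else seed)
    trials = eio.problems_to_frame(problems)
    if trials[["t_ch_on"]].isna().all().all():
        raise ValueError("problems carry no event timestamps")
    states = _trial_states(problems, rng, pop.failed_state_persistence)
    trials = trials.merge(states, on=eio.TRIAL_KEY, how="left", validate="one_to_one")

    labels = _assign_cell_labels(rng, pop)
    sessions = sorted(trials["session_id"].unique())
    animal_of = trials.drop_duplicates("session_id").set_index("session_id")["animal_id"]
    cells = labels.copy()
    cells.insert(0, "cell_id", [f"C{i + 1:04d}" for i in range(pop.n_cells)])
    cells.insert(1, "session_id", [sessions[i % len(sessions)] for i in range(pop.n_cells)])
    cells.insert(2, "animal_id", cells["session_id"].map(animal_of))
    cells.insert(3, "region", region)

    epochs_by_session = {
        s: _epoch_table(trials[trials["session_id"] == s]) for s in sessions
    }
    tcols = trials.set_index("trial_uid")
    spike_frames = []
    for cell in cells.itertuples():
        ep = epochs_by_session[cell.session_id]
        t = tcols.loc[ep["trial_uid"].to_numpy()]
        baseline = float(rng.lognormal(pop.baseline_log_mean, pop.baseline_log_sd))
        obj_f = rng.lognormal(0.0, pop.object_tuning_sd, size=N_OBJECTS)
        loc_f = rng.lognormal(0.0, pop.location_tuning_sd, size=N_OBJECTS)

        rate = np.full(len(ep), baseline)
        in_phase = ep["kind"].to_numpy() == cell.truth_phase
        other_phase = (ep["kind"].to_numpy() != "base") & ~in_phase
        explore = t["explore_state"].to_numpy(dtype=bool)
        pos = t["n_already_sampled"].to_numpy(dtype=float)
        if cell.truth_label == "explore":
            g = np.where(explore, pop.state_gain, 1.0)
            if pop.graded_expectancy > 0:
                ramp = 1.0 - pop.graded_expectancy * np.minimum(pos, 3) / 3.0
                g = 1.0 + (g - 1.0) * np.where(explore, ramp, 1.0)
        elif cell.truth_label == "exploit":
            g = np.where(~explore, pop.state_gain, 1.0)
            if pop.graded_expectancy > 0:
                ramp = pop.graded_expectancy * np.minimum(pos, 3) / 3.0
                g = np.where(explore, 1.0 + (pop.state_gain - 1.0) * ramp, g)
        else:
            g = np.ones(len(ep))
        rate *= np.where(in_phase, g, 1.0)
        if pop.cross_phase_leakage > 0:
            leak = 1.0 + (g - 1.0) * pop.cross_phase_leakage
            rate *= np.where(other_phase, leak, 1.0)

        chosen = t["chosen_object"].to_numpy(dtype=float)
        chosen_loc = t["chosen_location"].to_numpy(dtype=float)
        has_choice = ~np.isnan(chosen)
        stim = in_phase | other_phase
        tuning = np.ones(len(ep))
        idx = has_choice & stim
        tuning[idx] = (obj_f[chosen[idx].astype(int) - 1]
                       * loc_f[chosen_loc[idx].astype(int) - 1])
        rate *= tuning
        if cell.truth_outcome != "none":
            correct = t["correct"].to_numpy(dtype=bool)
            hit = (ep["kind"].to_numpy() == "FB") & (
                correct if cell.truth_outcome == "correct" else ~correct)
            rate *= np.where(hit, pop.outcome_gain, 1.0)
        if pop.trial_rate_jitter_sd > 0:
            uids, inv = np.unique(ep["trial_uid"].to_numpy(), return_inverse=True)
            jit = rng.lognormal(0.0, pop.trial_rate_jitter_sd, size=len(uids))
            rate *= jit[inv]

        dur = (ep["end"] - ep["start"]).to_numpy()
        counts = rng.poisson(rate * dur)
        total = int(counts.sum())
        if total == 0:
            continue
        starts = ep["start"].to_numpy().repeat(counts)
        times = starts + rng.random(total) * dur.repeat(counts)
        uid = ep["trial_uid"].to_numpy().repeat(counts)
        frame = pd.DataFrame({"trial_uid": uid, "spike_time_s": times})
        frame = frame.sort_values(["trial_uid", "spike_time_s"])
        meta = tcols.loc[frame["trial_uid"].to_numpy(),
                         ["session_id", "problem_id", "cycle", "trial_in_cycle"]]
        frame = pd.concat([meta.reset_index(drop=True),
                           frame["spike_time_s"].reset_index(drop=True)], axis=1)
        frame.insert(0, "cell_id", cell.cell_id)
        spike_frames.append(frame)

    spikes = (pd.concat(spike_frames, ignore_index=True)
              if spike_frames else pd.DataFrame(columns=eio.SPIKE_COLUMNS))
    truth = GroundTruth(
        cells=cells[["cell_id", "truth_label", "truth_phase", "truth_outcome"]].copy(),
        problems=pd.DataFrame({
            "session_id": [p.trials[0].session_id for p in problems],
            "problem_id": [p.problem_id for p in problems],
            "learned": [bool(getattr(p, "learned", True)) for p in problems],
        }),
        trial_states=states,
        agent={}, population=asdict(pop),
    )
    return cells[eio.CELL_COLUMNS], spikes, truth


def simulate_dataset(
    *,
    n_sessions: int = 2,
    n_problems: int = 24,
    agent: Optional[AgentConfig] = None,
    pop: Optional[PopulationConfig] = None,
    seed: int = 0,
    region: str = "PFC",
    block_size: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: behavior for several sessions plus one
    population; returns ``(trials, spikes, cells, truth)``.

    Sessions are split between two animals (A and B), as in a two-animal
    experiment.
    """
    agent = agent or AgentConfig()
    pop = pop or PopulationConfig()
    ss = np.random.SeedSequence(seed)
    beh_seeds = ss.spawn(n_sessions)
    problems: list[ProblemRecord] = []
    for i in range(n_sessions):
        animal = "A" if i < (n_sessions + 1) // 2 else "B"
        problems += simulate_behavior(
            n_problems, agent, seed=beh_seeds[i].generate_state(1)[0] % (2**31),
            session_id=f"S{i + 1:03d}", animal_id=animal, block_size=block_size)
    pop_seed = ss.spawn(1)[0].generate_state(1)[0] % (2**31)
    cells, spikes, truth = simulate_population(problems, pop, seed=pop_seed, region=region)
    trials = eio.problems_to_frame(problems)
    truth.agent = {k: v for k, v in asdict(agent).items()}
    return trials, spikes, cells, truth


FIXTURE_SCALES = {
    # n_sessions, n_problems per session, n_cells
    "tiny": (2, 16, 16),
    "paper-like": (60, 136, 254),
}


def make_fixture(scale: str, seed: int, outdir) -> dict:
    """Write a dataset (trials/spikes/cells CSV + ground-truth JSON).

    ``tiny`` completes in seconds and is meant for smoke tests;
    ``paper-like`` matches the recorded experiment's footprint
    (60 sessions, ~69+67 problems each, 254 cells) and takes minutes.
    Deterministic given ``seed``.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    n_sessions, n_problems, n_cells = FIXTURE_SCALES[scale]
    trials, spikes, cells, truth = simulate_dataset(
        n_sessions=n_sessions, n_problems=n_problems,
        pop=PopulationConfig(n_cells=n_cells, fraction_outcome_cells=0.2),
        seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "spikes": outdir / "spikes.csv",
        "cells": outdir / "cells.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    eio.write_trials(trials, paths["trials"])
    eio.write_spikes(spikes, paths["spikes"])
    eio.write_cells(cells, paths["cells"])
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
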