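"""Calibration and ground-truth-recovery experiments.

These drivers wire the simulator to the analysis stack under controlled
study conditions: analytic chance expectations against Monte-Carlo
agents, type-I-error calibration of the selection ANOVA and of the
permutation test on null populations, parameter recovery of labeled
cells, the one-shot transition signature, and the phase-conjunction
contrast of the cross-generalization matrix.  They back both the test
suite and the reproduction script.

Populations are simulated in cell chunks so large calibrations keep a
modest memory footprint.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import io as eio
from . import population as popm
from . import selection as sel
from . import simulate as sim


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# behavioral chance expectations


def search_expectation_sim(n_problems: int, n_targets: int, seed: int) -> dict:
    """Mean Cycle-1 search length of the optimal (revisit-free) agent."""
    problems = sim.simulate_behavior(
        n_problems, sim.optimal_agent(), seed=seed,
        n_targets_schedule=[n_targets] * n_problems)
    lengths = np.array([len(p.cycles()[1]) for p in problems], dtype=float)
    return {"mean": float(lengths.mean()),
            "se": float(lengths.std(ddof=1) / math.sqrt(len(lengths))),
            "n": n_problems}


def revisit_chance_sim(n_problems: int, seed: int) -> pd.DataFrame:
    """Cycle-1 revisit percentage of the memoryless agent per number of
    objects already sampled, with the analytic chance expectation."""
    from .task import chance_revisit_probability

    problems = sim.simulate_behavior(n_problems, sim.memoryless_agent(), seed=seed)
    frame = eio.problems_to_frame(problems)
    c1 = frame[(frame["cycle"] == 1) & frame["chosen_object"].notna()]
    rows = []
    for k in range(4):
        sub = c1[c1["n_already_sampled"] == k]
        obs = sub["response_type"].isin(["NT_revisit", "T_revisit"]).mean()
        p = chance_revisit_probability(k)
        rows.append({"n_already_sampled": k, "n_trials": len(sub),
                     "observed_pct": 100 * obs, "expected_pct": 100 * p,
                     "se_pct": 100 * math.sqrt(max(p * (1 - p), 1e-12) / max(len(sub), 1))})
    return pd.DataFrame(rows)


def first_choice_target_sim(n_problems: int, seed: int) -> dict:
    """Fraction of first Cycle-1 choices that hit a target, per problem
    type (analytically 0.25 for 1-target, 0.5 for 2-target)."""
    out = {}
    for i, ntg in enumerate((1, 2)):
        problems = sim.simulate_behavior(
            n_problems, sim.AgentConfig(), seed=seed + i,
            n_targets_schedule=[ntg] * n_problems)
        first_correct = []
        for p in problems:
            responses = [t for t in p.cycles()[1] if not t.failed]
            if responses:
                first_correct.append(responses[0].correct)
        frac = float(np.mean(first_correct))
        out[ntg] = {"fraction": frac,
                    "se": math.sqrt(frac * (1 - frac) / len(first_correct)),
                    "n": len(first_correct)}
    return out


# ---------------------------------------------------------------------------
# selection calibration and recovery


def _null_population(n_cells: int, seed: int) -> sim.PopulationConfig:
    return sim.PopulationConfig(n_cells=n_cells, fraction_explore_ch=0.0,
                                fraction_exploit_ch=0.0, fraction_explore_fb=0.0,
                                fraction_exploit_fb=0.0, seed=seed)


def null_selection_calibration(
    n_cells: int = 1000,
    seed: int = 0,
    n_problems: int = 30,
    chunk: int = 125,
    alpha: float = 0.05,
) -> dict:
    """Type-I calibration of the selection ANOVA and validation t-test.

    Simulates ``n_cells`` cells with no cycle preference (object and
    location tuning retained) over one session and measures (a) the
    cycle-main-effect rejection rate across all cell x phase tests and
    (b) among the (falsely) selected cells, how often the independent
    validation-half t-test also rejects.  Cross-validation guarantees
    (b) stays at the nominal level; selection bias would inflate it far
    above alpha.
    """
    beh_seed, *pop_seeds = _seeds(seed, 1 + math.ceil(n_cells / chunk))
    problems = sim.simulate_behavior(n_problems, sim.AgentConfig(), seed=beh_seed)
    trials = eio.problems_to_frame(problems)
    results = []
    done = 0
    for i, pseed in enumerate(pop_seeds):
        size = min(chunk, n_cells - done)
        done += size
        pop = _null_population(size, pseed)
        cells, spikes, _ = sim.simulate_population(problems, pop, seed=pseed)
        cells = cells.assign(cell_id=[f"chunk{i}_{c}" for c in cells["cell_id"]])
        spikes = spikes.assign(cell_id=[f"chunk{i}_{c}" for c in spikes["cell_id"]])
        aligned = sel.align_spikes(spikes, trials)
        split = sel.split_trials(trials, cells, seed=pseed)
        results.append(sel.select_cells(trials, aligned, cells, split,
                                        alpha=alpha))
    table = pd.concat(results, ignore_index=True)
    selected = table[table["label"] != "none"]
    val_p = selected["val_p"].dropna()
    return {
        "n_tests": int(len(table)),
        "anova_rejection_rate": float((table["p_cycle"] < alpha).mean()),
        "n_selected": int(len(selected)),
        "validation_rejection_rate": float((val_p < alpha).mean()),
        "validation_mean_p": float(val_p.mean()),
    }


def recovery_experiment(
    seed: int = 0,
    n_sessions: int = 2,
    n_problems: int = 100,
    n_cells: int = 120,
    chunk: int = 30,
    alpha: float = 0.05,
) -> dict:
    """Ground-truth recovery of explore/exploit cells.

    Default population fractions and state gain; ~100 problems per
    session give well over 40 correct Cycle-1/Cycle-4 trials per cell in
    the selection half.  A labeled cell counts as recovered when the
    selection ANOVA flags it in its true phase with the matching label
    (which fixes the sign of the cycle preference).
    """
    beh_seed, *pop_seeds = _seeds(seed, 1 + math.ceil(n_cells / chunk))
    problems = []
    for s in range(n_sessions):
        problems += sim.simulate_behavior(
            n_problems, sim.AgentConfig(), seed=beh_seed + s,
            session_id=f"S{s + 1:03d}", animal_id="A" if s % 2 == 0 else "B")
    trials = eio.problems_to_frame(problems)
    recovered, total = 0, 0
    per_label: dict[str, list[int]] = {}
    done = 0
    for i, pseed in enumerate(pop_seeds):
        size = min(chunk, n_cells - done)
        done += size
        pop = sim.PopulationConfig(n_cells=size, seed=pseed)
        cells, spikes, truth = sim.simulate_population(problems, pop, seed=pseed)
        aligned = sel.align_spikes(spikes, trials)
        split = sel.split_trials(trials, cells, seed=pseed + 1)
        res = sel.select_cells(trials, aligned, cells, split, alpha=alpha)
        merged = res.merge(truth.cells, on="cell_id")
        labeled = merged[(merged["truth_label"] != "none")
                         & (merged["phase"] == merged["truth_phase"])]
        hit = labeled["label"] == labeled["truth_label"]
        recovered += int(hit.sum())
        total += int(len(labeled))
        for lab, h in zip(labeled["truth_label"], hit):
            per_label.setdefault(lab, []).append(int(h))
    return {
        "n_ground_truth_cells": total,
        "n_recovered": recovered,
        "recovery_fraction": recovered / total if total else float("nan"),
        "per_label": {k: float(np.mean(v)) for k, v in per_label.items()},
    }


# ---------------------------------------------------------------------------
# one-shot transition signature


def binary_switch_agent(seed: int = 0) -> sim.AgentConfig:
    """Agent whose only Cycle 2-4 errors come from failed one-shot
    learning, so every behavioral failed-learning trial reflects a
    genuine explore-state carry-over."""
    return sim.AgentConfig(p_learn_one_shot=0.75, p_revisit_lapse=0.1,
                           p_exploit_error_by_cycle={2: 0.0, 3: 0.0, 4: 0.0},
                           p_no_response=0.0, p_abort=0.0, seed=seed)


def one_shot_experiment(
    seed: int = 0,
    n_sessions: int = 2,
    n_problems: int = 120,
    n_cells: int = 96,
    n_permutations: int = 999,
) -> dict:
    """One-shot switch: single-cell cycle tests plus discriminant geometry."""
    beh_seed, pop_seed, split_seed, disc_seed = _seeds(seed, 4)
    agent = binary_switch_agent()
    problems = []
    for s in range(n_sessions):
        problems += sim.simulate_behavior(
            n_problems, agent, seed=beh_seed + s, session_id=f"S{s + 1:03d}",
            animal_id="A" if s % 2 == 0 else "B")
    trials = eio.problems_to_frame(problems)
    pop = sim.PopulationConfig(n_cells=n_cells, seed=pop_seed)
    cells, spikes, truth = sim.simulate_population(problems, pop, seed=pop_seed)
    aligned = sel.align_spikes(spikes, trials)
    split = sel.split_trials(trials, cells, seed=split_seed)
    selection = sel.select_cells(trials, aligned, cells, split)
    norms = sel.cell_norms(trials, aligned, cells, split)
    one_shot = sel.one_shot_cycle_analysis(trials, aligned, cells, selection,
                                           split, norms)
    failed = sel.failed_learning_analysis(trials, aligned, cells, selection,
                                          split, norms)
    discriminant = {}
    for i, phase in enumerate(sel.PHASES):
        res = popm.discriminant_analysis(trials, aligned, cells, phase,
                                         seed=disc_seed + i,
                                         n_permutations=n_permutations)
        discriminant[phase] = {
            "projections": res.projections,
            "p": {f"{a}_vs_{b}": v["p"]
                  for (a, b), v in res.permutation_p.items()},
        }
    return {"one_shot": one_shot, "failed_learning": failed,
            "discriminant": discriminant,
            "n_labeled": int((selection["label"] != "none").sum())}


# ---------------------------------------------------------------------------
# phase conjunction and permutation calibration


def crossgen_contrast_experiment(
    conjunctive: bool,
    seed: int = 0,
    n_splits: int = 12,
    n_sessions: int = 2,
    n_problems: int = 40,
    n_cells: int = 60,
) -> dict:
    """Within-phase minus cross-phase correlation contrast.

    ``conjunctive=True`` uses the default phase-conjunctive population;
    ``False`` lets the full state gain leak into the other phase
    (phase-general coding), for which the contrast should vanish.
    Repeats the random halving ``n_splits`` times and returns a
    t-interval for the mean contrast.
    """
    import scipy.stats as sps

    data_seed, *split_seeds = _seeds(seed, 1 + n_splits)
    pop = sim.PopulationConfig(n_cells=n_cells, state_gain=2.0,
                               cross_phase_leakage=0.0 if conjunctive else 1.0)
    trials, spikes, cells, _ = sim.simulate_dataset(
        n_sessions=n_sessions, n_problems=n_problems, pop=pop, seed=data_seed)
    aligned = sel.align_spikes(spikes, trials)
    contrasts = [popm.phase_block_contrast(
        popm.cross_generalization_matrix(trials, aligned, cells, seed=s))
        for s in split_seeds]
    arr = np.array(contrasts)
    se = arr.std(ddof=1) / math.sqrt(len(arr))
    t99 = sps.t.ppf(0.995, len(arr) - 1)
    return {"mean_contrast": float(arr.mean()), "se": float(se),
            "ci99": (float(arr.mean() - t99 * se), float(arr.mean() + t99 * se)),
            "contrasts": arr.tolist()}


def permutation_calibration(
    n_runs: int = 500,
    seed: int = 0,
    n_permutations: int = 199,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the projection permutation test.

    One dataset is simulated; the discriminant is fitted on the train
    half; then Cycle-4 *test* trials are randomly re-split into two
    pseudo-conditions ``n_runs`` times.  The two pseudo-conditions are
    exchangeable by construction, so p-values should be uniform and the
    rejection rate should match alpha.
    """
    data_seed, fit_seed, *run_seeds = _seeds(seed, 2 + n_runs)
    trials, spikes, cells, _ = sim.simulate_dataset(
        n_sessions=2, n_problems=40,
        pop=sim.PopulationConfig(n_cells=24), seed=data_seed)
    aligned = sel.align_spikes(spikes, trials)
    split = sel.split_trials(trials, cells, fit_seed, halves=("train", "test"))
    model = popm.fit_discriminant(trials, aligned, cells, split, "CH")
    base = trials[trials["correct"] & (trials["cycle"] == 4)]
    rates = sel.rate_table(aligned, trials, cells, model.window,
                           trial_uids=base["trial_uid"])
    rates = sel.restrict_to_half(rates, split, "test")
    uids = rates["trial_uid"].unique()
    pvals = []
    for rseed in run_seeds:
        rng = np.random.default_rng(rseed)
        mask = rng.random(len(uids)) < 0.5
        a = rates[rates["trial_uid"].isin(uids[mask])]
        b = rates[rates["trial_uid"].isin(uids[~mask])]
        res = popm.permutation_test(a, b, model, n=n_permutations, seed=rseed)
        pvals.append(res["p"])
    pvals = np.array(pvals)
    return {"n_runs": n_runs,
            "rejection_rate": float((pvals < alpha).mean()),
            "min_p": float(pvals.min()),
            "mean_p": float(pvals.mean())}
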