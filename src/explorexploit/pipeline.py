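"""End-to-end orchestration: simulate/load -> validate -> analyze -> report.

A single :class:`RunConfig` drives the whole pipeline with explicit
seeds for every source of randomness (simulation, selection split,
cross-generalization split, discriminant split), so identical
configuration yields identical numeric outputs.  Results are written as
tidy CSV/JSON files keyed by analysis, together with a manifest
recording the configuration, seeds and post-filter trial/cell counts at
every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import io as eio
from . import population as popm
from . import selection as sel
from . import simulate as sim
from .task import apply_problem_exclusion

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either the three input paths are given, or a dataset is simulated
    from the agent/population settings.  Analysis constants default to
    the standard protocol: 400 ms analysis windows, alpha = 0.05 with
    cross-validation as the guard against selection bias, 1000
    permutations, problems excluded at >= 6 failed trials in a cycle.
    """

    # inputs: either paths...
    trials_path: Optional[str] = None
    spikes_path: Optional[str] = None
    cells_path: Optional[str] = None
    # ...or simulation settings
    n_sessions: int = 4
    n_problems: int = 40
    agent: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)

    # seeds (all randomness flows from these)
    seed_simulation: int = 1
    seed_split_selection: int = 2
    seed_split_crossgen: int = 3
    seed_split_discriminant: int = 4

    # analysis constants
    alpha: float = 0.05
    window_width_s: float = 0.4
    n_permutations: int = 1000
    region: Optional[str] = None
    outdir: str = "results/run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "/".join(map(str, np.atleast_1d(k)))):
                _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def validate_dataset(trials: pd.DataFrame, spikes: pd.DataFrame,
                     cells: pd.DataFrame) -> dict:
    """Schema validation with line-level diagnostics."""
    issues = {
        "trials": eio.validate_trials(trials),
        "spikes": eio.validate_spikes(spikes, trials),
    }
    known_sessions = set(trials["session_id"])
    bad_cells = cells[~cells["session_id"].isin(known_sessions)]
    issues["cells"] = [{"row": int(i), "check": "cell_session_known",
                        "detail": str(r["session_id"])}
                       for i, r in bad_cells.iterrows()]
    ok = not any(v for v in issues.values())
    return {"pass": ok, "issues": issues}


def _load_or_simulate(config: RunConfig):
    if config.trials_path:
        trials = eio.read_trials(config.trials_path)
        spikes = eio.read_spikes(config.spikes_path)
        cells = eio.read_cells(config.cells_path)
        return trials, spikes, cells, None
    agent = sim.AgentConfig(**config.agent)
    pop = sim.PopulationConfig(**config.population)
    trials, spikes, cells, truth = sim.simulate_dataset(
        n_sessions=config.n_sessions, n_problems=config.n_problems,
        agent=agent, pop=pop, seed=config.seed_simulation)
    return trials, spikes, cells, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``outdir``.

    Stage order: schema validation, problem exclusion, behavioral
    summaries, cross-validated selection + validation, normalized group
    PSTHs, one-shot / failed-learning / expectancy analyses, outcome
    coding, temporal cross-generalization, and the population
    discriminant for both phases.  Returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    trials, spikes, cells, truth = _load_or_simulate(config)
    if config.region:
        cells = cells[cells["region"] == config.region].reset_index(drop=True)
        spikes = spikes[spikes["cell_id"].isin(cells["cell_id"])]
    report = validate_dataset(trials, spikes, cells)
    if not report["pass"]:
        raise ValueError(f"dataset failed validation: {report['issues']}")
    stages.append({"stage": "validate", "n_trials": len(trials),
                   "n_cells": len(cells), "n_spikes": len(spikes)})

    problems = eio.frame_to_problems(trials)
    kept, excl_log = apply_problem_exclusion(problems)
    trials = eio.problems_to_frame(kept)
    spikes = spikes.merge(trials[eio.TRIAL_KEY].drop_duplicates(), on=eio.TRIAL_KEY)
    stages.append({"stage": "exclusion", "n_problems_in": len(problems),
                   "n_problems_kept": len(kept),
                   "excluded": [e["problem_id"] for e in excl_log]})

    # behavior
    cyc = beh.summarize_cycles(trials)
    cyc.to_csv(outdir / "behavior_cycles.csv", index=False)
    revisit = beh.revisit_vs_chance(trials)
    revisit.to_csv(outdir / "behavior_revisit.csv", index=False)
    try:
        decline = beh.nontarget_decline_test(trials)
        decline_out = {f"{a}/{t}": {"anova": v["anova"],
                                    "tukey": None if v["tukey"] is None else v["tukey"]}
                       for (a, t), v in decline.items()}
    except ValueError as err:  # < 2 sessions per animal
        logger.warning("nontarget decline test skipped: %s", err)
        decline_out = {"skipped": str(err)}
    (outdir / "behavior_decline.json").write_text(
        json.dumps(_jsonable(decline_out), indent=1))
    stages.append({"stage": "behavior", "n_trials": len(trials)})

    # selection / validation
    aligned = sel.align_spikes(spikes, trials)
    split = sel.split_trials(trials, cells, config.seed_split_selection)
    selection = sel.select_cells(trials, aligned, cells, split,
                                 alpha=config.alpha)
    selection.to_csv(outdir / "selection.csv", index=False)
    validation = sel.validate_selection(selection)
    validation.to_csv(outdir / "validation.csv", index=False)
    norms = sel.cell_norms(trials, aligned, cells, split)
    stages.append({"stage": "selection",
                   "counts": selection.groupby(["phase", "label"])
                   .size().to_dict()})

    # normalized cross-validated PSTHs per phase (validation half, cycles 1 & 4)
    half = split[split["half"] == "validation"]
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    for phase in sel.PHASES:
        psth = sel.build_psth(trials, aligned, cells, phase, norms,
                              trial_uids=base["trial_uid"])
        psth.to_csv(outdir / f"psth_{phase.lower()}.csv")
    del half

    one_shot = sel.one_shot_cycle_analysis(trials, aligned, cells, selection,
                                           split, norms)
    failed = sel.failed_learning_analysis(trials, aligned, cells, selection,
                                          split, norms)
    sampling = sel.sampling_order_analysis(trials, aligned, cells, selection,
                                           split, norms)
    cor_err = sel.correct_error_analysis(trials, aligned, cells, selection,
                                         split, norms)
    discovery = sel.discovery_type_analysis(trials, aligned, cells, selection,
                                            split, norms)
    outcome = sel.outcome_coding_anova(trials, aligned, cells, selection,
                                       alpha=config.alpha)
    interaction = sel.object_interaction_screen(trials, aligned, cells,
                                                selection, split,
                                                alpha=config.alpha)
    outcome_out = {k: v for k, v in outcome.items() if k != "table"}
    (outdir / "single_cell.json").write_text(json.dumps(_jsonable({
        "one_shot_cycles": one_shot,
        "failed_learning": failed,
        "sampling_order": sampling,
        "correct_error": cor_err,
        "discovery_type": discovery,
        "outcome_coding": outcome_out,
        "object_interaction": interaction,
    }), indent=1))
    stages.append({"stage": "single_cell", "groups": len(one_shot)})

    # temporal cross-generalization
    xgen = popm.cross_generalization_matrix(trials, aligned, cells,
                                            config.seed_split_crossgen)
    xgen.to_csv(outdir / "crossgen_matrix.csv")
    stages.append({"stage": "crossgen",
                   "phase_block_contrast": popm.phase_block_contrast(xgen)})

    # population discriminant
    disc_out = {}
    for i, phase in enumerate(sel.PHASES):
        result = popm.discriminant_analysis(
            trials, aligned, cells, phase,
            seed=config.seed_split_discriminant + i,
            n_permutations=config.n_permutations)
        result.model.weights.rename("weight").to_csv(
            outdir / f"discriminant_weights_{phase.lower()}.csv")
        disc_out[phase] = {
            "projections": result.projections,
            "permutation_p": {f"{a}_vs_{b}": v["p"]
                              for (a, b), v in result.permutation_p.items()},
            "n_permutations": result.n_permutations,
            "coverage": result.coverage,
        }
    (outdir / "discriminant.json").write_text(json.dumps(_jsonable(disc_out),
                                                         indent=1))
    stages.append({"stage": "discriminant", "phases": list(disc_out)})

    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": stages,
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return manifest
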