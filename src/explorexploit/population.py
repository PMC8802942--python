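"""Population analyses: temporal cross-generalization and the
Cycle-1-vs-Cycle-4 mean-difference discriminant.

*Cross-generalization* asks whether the population's cycle preference
(per-cell Cycle 4 minus Cycle 1 rate difference) is the same code over
time: preference vectors computed in independent trial halves are
correlated across all pairs of 100 ms windows spanning the choice (CH)
and feedback (FB) phases.  A phase-conjunctive code gives strong
within-phase blocks and near-zero cross-phase correlations.

The *discriminant* is a deliberately simple population decoder: per
cell, firing rates are centered on the unweighted mean of the Cycle-1
and Cycle-4 train means and scaled by the unweighted mean of the two
across-trial SDs; the discriminant axis is the scaled Cycle-4 vector
minus the scaled Cycle-1 vector, and conditions are compared by the dot
product of their standardized population mean with this axis.
Inference uses a label-permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .selection import (
    WindowSpec,
    analysis_window,
    failed_learning_uids,
    rate_table,
    regular_cycle_uids,
    restrict_to_half,
    split_trials,
    unweighted_cell_means,
    with_factors,
)

logger = logging.getLogger(__name__)

#: four contiguous 100 ms windows from event onset, per phase
def crossgen_windows() -> list[WindowSpec]:
    wins = []
    for phase in ("CH", "FB"):
        for i in range(4):
            wins.append(WindowSpec(phase, round(0.1 * i, 4), 0.1))
    return wins


def window_label(win: WindowSpec) -> str:
    return f"{win.alignment}_{int(round(win.start * 1000))}"


def cycle_preference_vectors(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    split: pd.DataFrame,
    half: str,
    windows: Optional[Sequence[WindowSpec]] = None,
) -> pd.DataFrame:
    """Per-cell cycle preference (Cycle 4 - Cycle 1 mean rate) per window.

    Means are unweighted over touched location x number of targets to
    remove those factors; correct trials only; computed within one half
    of a fresh random split.  Returns cells x windows; cells with no
    Cycle-1 or Cycle-4 trials in the half get NaN (excluded pairwise
    from correlations downstream).
    """
    windows = list(windows) if windows is not None else crossgen_windows()
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    cols = {}
    for win in windows:
        rates = rate_table(aligned, trials, cells, win,
                           trial_uids=base["trial_uid"])
        rates = with_factors(rates, trials)
        rates = restrict_to_half(rates, split, half)
        per_cycle = {
            cyc: unweighted_cell_means(grp, by=("n_targets", "chosen_location"))
            for cyc, grp in rates.groupby("cycle")
        }
        cols[window_label(win)] = per_cycle.get(4, pd.Series(dtype=float)) \
            - per_cycle.get(1, pd.Series(dtype=float))
    out = pd.DataFrame(cols)
    out.index.name = "cell_id"
    return out


def cross_generalization_matrix(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    seed: int,
    method: str = "pearson",
) -> pd.DataFrame:
    """8x8 correlation matrix of half-A vs half-B preference vectors.

    Entry (i, j) correlates the half-A preference vector in window i
    with the half-B vector in window j over cells (pairwise-complete).
    The split is a fresh random halving, independent of the
    selection/validation split.  ``method`` is ``pearson`` (default) or
    ``spearman``.  Zero-variance vectors yield NaN entries and a log
    message.
    """
    if len(cells) < 3:
        raise ValueError("need at least 3 cells with data for correlations")
    split = split_trials(trials, cells, seed, halves=("A", "B"))
    va = cycle_preference_vectors(trials, aligned, cells, split, "A")
    vb = cycle_preference_vectors(trials, aligned, cells, split, "B")
    labels = va.columns
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for i in labels:
        for j in labels:
            joined = pd.concat([va[i], vb[j]], axis=1).dropna()
            if len(joined) < 3 or joined.iloc[:, 0].std() == 0 \
                    or joined.iloc[:, 1].std() == 0:
                logger.info("undefined correlation for (%s, %s)", i, j)
                mat.loc[i, j] = np.nan
            else:
                mat.loc[i, j] = joined.iloc[:, 0].corr(joined.iloc[:, 1],
                                                       method=method)
    return mat


def phase_block_contrast(matrix: pd.DataFrame) -> float:
    """Mean within-phase correlation minus mean cross-phase correlation.

    Positive values indicate a phase-conjunctive code (strong CH-CH and
    FB-FB blocks, weak CH-FB blocks).
    """
    is_ch = np.array([lbl.startswith("CH") for lbl in matrix.index])
    m = matrix.to_numpy(dtype=float)
    same = np.equal.outer(is_ch, is_ch)
    within = np.nanmean(m[same])
    across = np.nanmean(m[~same])
    return float(within - across)


# ---------------------------------------------------------------------------
# discriminant


@dataclass
class DiscriminantModel:
    """Frozen transform fitted on the train half of Cycles 1 and 4."""

    phase: str
    window: WindowSpec
    center: pd.Series
    scale: pd.Series
    weights: pd.Series

    @property
    def cell_ids(self) -> pd.Index:
        return self.weights.index


@dataclass
class DiscriminantResult:
    phase: str
    projections: dict
    permutation_p: dict
    n_permutations: int
    seed: int
    model: DiscriminantModel
    coverage: dict = field(default_factory=dict)


def _per_cycle_stats(rates: pd.DataFrame) -> pd.DataFrame:
    g = rates.groupby(["cell_id", "cycle"])["rate"]
    return pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)


def fit_discriminant(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    split: pd.DataFrame,
    phase: str,
) -> DiscriminantModel:
    """Fit center/scale/discriminant from the train half of Cycles 1 & 4.

    Per cell: center = (mean_C1 + mean_C4) / 2, scale = (sd_C1 + sd_C4)
    / 2 (unweighted across the two cycles), and the discriminant weight
    is ``(mean_C4 - center)/scale - (mean_C1 - center)/scale``.  Cells
    with zero or undefined scale get scale 1 and weight 0 (they cannot
    inform the axis) and are logged.
    """
    win = analysis_window(phase)
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    rates = rate_table(aligned, trials, cells, win, trial_uids=base["trial_uid"])
    rates = with_factors(rates, trials)
    rates = restrict_to_half(rates, split, "train")
    stats = _per_cycle_stats(rates).unstack("cycle")
    m1, m4 = stats[("mean", 1)], stats[("mean", 4)]
    s1, s4 = stats[("sd", 1)], stats[("sd", 4)]
    center = (m1 + m4) / 2.0
    scale = (s1 + s4) / 2.0
    bad = ~np.isfinite(scale) | (scale <= 0) | ~np.isfinite(center)
    if bad.any():
        logger.info("%d cell(s) with degenerate train scale; weight set to 0",
                    int(bad.sum()))
    scale = scale.where(~bad, 1.0)
    center = center.fillna(0.0)
    z1 = (m1 - center) / scale
    z4 = (m4 - center) / scale
    weights = (z4 - z1).where(~bad, 0.0).fillna(0.0)
    full_index = pd.Index(cells["cell_id"].unique(), name="cell_id")
    return DiscriminantModel(
        phase=phase, window=win,
        center=center.reindex(full_index).fillna(0.0),
        scale=scale.reindex(full_index).fillna(1.0),
        weights=weights.reindex(full_index).fillna(0.0),
    )


def project(model: DiscriminantModel, cond_means: pd.Series) -> float:
    """Project a per-cell condition-mean vector onto the discriminant.

    Means are centered and scaled with the frozen train statistics;
    cells with no data in the condition contribute 0 (their weight is
    masked for this projection).
    """
    z = (cond_means.reindex(model.cell_ids) - model.center) / model.scale
    z = z.fillna(0.0)
    return float(np.dot(z.to_numpy(), model.weights.to_numpy()))


def _cond_rates(trials, aligned, cells, window, trial_uids) -> pd.DataFrame:
    if len(trial_uids) == 0:
        return pd.DataFrame(columns=["cell_id", "trial_uid", "rate"])
    return rate_table(aligned, trials, cells, window, trial_uids=trial_uids)


def permutation_test(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    model: DiscriminantModel,
    n: int = 1000,
    seed: int = 0,
) -> dict:
    """Label-permutation test of the projection difference of two conditions.

    Per replicate, each cell's trials from the two conditions are
    pooled and the condition labels reshuffled; condition means are
    recomputed and re-projected on the *original* discriminant (center,
    scale and weights frozen from training).  The p-value is
    ``(#{permuted |diff| >= observed |diff|} + 1) / (n + 1)`` — the
    add-one rule keeps p strictly positive with floor ``1/(n+1)``.
    """
    if len(rates_a) == 0 or len(rates_b) == 0:
        raise ValueError("both conditions need at least one trial")
    if n < 100:
        logger.warning("permutation test with n=%d (< 100) is unreliable", n)
    rng = np.random.default_rng(seed)
    mean_a = rates_a.groupby("cell_id")["rate"].mean()
    mean_b = rates_b.groupby("cell_id")["rate"].mean()
    observed = project(model, mean_a) - project(model, mean_b)

    # permuted projection difference, accumulated cell by cell
    diff_perm = np.zeros(n)
    w = model.weights
    for cell_id in model.cell_ids:
        a = rates_a.loc[rates_a["cell_id"] == cell_id, "rate"].to_numpy()
        b = rates_b.loc[rates_b["cell_id"] == cell_id, "rate"].to_numpy()
        wi = float(w.loc[cell_id])
        if wi == 0.0 or (len(a) == 0 and len(b) == 0):
            continue
        pooled = np.concatenate([a, b])
        na = len(a)
        c = float(model.center.loc[cell_id])
        s = float(model.scale.loc[cell_id])
        perm = rng.permuted(np.broadcast_to(pooled, (n, len(pooled))).copy(), axis=1)
        za = (perm[:, :na].mean(axis=1) - c) / s if na else np.zeros(n)
        zb = (perm[:, na:].mean(axis=1) - c) / s if len(b) else np.zeros(n)
        diff_perm += wi * (za - zb)
    k = int(np.count_nonzero(np.abs(diff_perm) >= abs(observed)))
    return {"p": (k + 1) / (n + 1), "observed_diff": float(observed),
            "n_permutations": n}


DEFAULT_PAIRS = (
    ("C1_test", "C4_test"),
    ("C1_test", "C2"), ("C1_test", "C3"),
    ("C2", "C4_test"), ("C3", "C4_test"),
    ("C2_failed", "C1_test"), ("C2_failed", "C2"),
)


def discriminant_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    phase: str,
    seed: int,
    n_permutations: int = 1000,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> DiscriminantResult:
    """Full discriminant workflow for one phase.

    Train/test halving of Cycle-1/4 trials (fresh split, independent of
    selection), discriminant fitted on the train half, projections of
    C1/C4 test data, regular Cycle-2/3 trials and Cycle-2
    failed-learning trials, and permutation tests for the requested
    condition pairs.  Conditions without trials are reported as missing
    and their pairs skipped.
    """
    ss = np.random.SeedSequence(seed)
    split_seed, perm_seed0 = [int(s.generate_state(1)[0] % (2 ** 31))
                              for s in ss.spawn(2)]
    split = split_trials(trials, cells, split_seed, halves=("train", "test"))
    model = fit_discriminant(trials, aligned, cells, split, phase)
    win = model.window

    base = trials[trials["correct"]]
    regular = set(regular_cycle_uids(trials))
    failed = set(failed_learning_uids(trials))

    def half_rates(cycle, half):
        sub = base[base["cycle"] == cycle]
        rates = _cond_rates(trials, aligned, cells, win, sub["trial_uid"].to_numpy())
        return restrict_to_half(rates, split, half)

    cond_rates = {
        "C1_test": half_rates(1, "test"),
        "C4_test": half_rates(4, "test"),
        "C2": _cond_rates(trials, aligned, cells, win, np.array(
            [u for u in base.loc[base["cycle"] == 2, "trial_uid"] if u in regular])),
        "C3": _cond_rates(trials, aligned, cells, win, np.array(
            [u for u in base.loc[base["cycle"] == 3, "trial_uid"] if u in regular])),
        "C2_failed": _cond_rates(trials, aligned, cells, win, np.array(
            [u for u in base.loc[base["cycle"] == 2, "trial_uid"] if u in failed])),
    }
    projections, coverage = {}, {}
    for name, rates in cond_rates.items():
        if rates.empty:
            projections[name] = np.nan
            coverage[name] = 0
            continue
        means = rates.groupby("cell_id")["rate"].mean()
        projections[name] = project(model, means)
        coverage[name] = int(means.notna().sum())

    permutation_p = {}
    perm_seeds = np.random.SeedSequence(perm_seed0).spawn(len(pairs))
    for (a, b), pseed in zip(pairs, perm_seeds):
        if cond_rates[a].empty or cond_rates[b].empty:
            logger.info("skipping permutation %s vs %s: empty condition", a, b)
            continue
        res = permutation_test(cond_rates[a], cond_rates[b], model,
                               n=n_permutations,
                               seed=int(pseed.generate_state(1)[0] % (2 ** 31)))
        permutation_p[(a, b)] = res
    return DiscriminantResult(
        phase=phase, projections=projections, permutation_p=permutation_p,
        n_permutations=n_permutations, seed=seed, model=model,
        coverage=coverage)
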