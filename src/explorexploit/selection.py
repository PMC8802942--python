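"""Cross-validated explore/exploit cell identification and single-cell analyses.

The workflow mirrors a split-half design for unbiased selection:

1. Each cell's trials are randomly split into *selection* and
   *validation* halves (stratified over condition cells).
2. On the selection half, restricted to cycles 1 and 4 of correct
   trials, a factorial ANOVA of the windowed firing rate on
   cycle (1, 4) x number of targets (1, 2) x object set (1, 2) x
   touched location (1-4) is run separately for two 400 ms windows, one
   from choice-array onset (CH), one from feedback onset (FB).
3. Cells with a significant cycle main effect are labeled *explore*
   (Cycle 1 > Cycle 4) or *exploit* (Cycle 4 > Cycle 1), per phase.
4. The validation half provides unbiased PSTHs and across-cell t-tests
   confirming (or refuting) the cycle preference.

Later analyses (one-shot cycle transitions, failed learning, sampling
order, correct/error, discovery type, outcome coding) all operate on
the labeled groups using normalized validation-half activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import io as eio

logger = logging.getLogger(__name__)

PHASES = ("CH", "FB")
EVENT_COL = {"CH": "t_ch_on", "FB": "t_fb_on"}

#: minimum mean activity (spikes/s) for a cell to enter normalized PSTHs
MIN_NORM_RATE = 0.1

#: trial factors used for ANOVA and stratification
FACTOR_COLS = ["cycle", "n_targets", "object_set", "chosen_location"]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis window [start, start+width) in seconds
    relative to an alignment event (CH or FB onset)."""

    alignment: str
    start: float
    width: float

    def __post_init__(self) -> None:
        if self.alignment not in PHASES:
            raise ValueError(f"alignment must be one of {PHASES}")
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def end(self) -> float:
        return self.start + self.width


def analysis_window(phase: str, width: float = 0.4) -> WindowSpec:
    """The 400 ms from-event-onset window used for selection and tests."""
    return WindowSpec(phase, 0.0, width)


PSTH_STEP = 0.025
PSTH_WIDTH = 0.100
PSTH_CENTERS = np.round(np.arange(-0.200, 0.475 + PSTH_STEP / 2, PSTH_STEP), 4)


def psth_windows(phase: str) -> list[WindowSpec]:
    """28 overlapping 100 ms windows, centers -200..475 ms in 25 ms steps."""
    return [WindowSpec(phase, float(c) - PSTH_WIDTH / 2, PSTH_WIDTH)
            for c in PSTH_CENTERS]


# ---------------------------------------------------------------------------
# windowed rates


def window_rate(spike_times: Sequence[float], event_time: float,
                window: WindowSpec) -> float:
    """Firing rate (spikes/s) of one trial in a window around an event.

    Spikes falling exactly on the window end are excluded (half-open
    convention), so adjacent windows partition time.
    """
    if event_time is None or np.isnan(event_time):
        return np.nan
    t = np.asarray(spike_times, dtype=float) - event_time
    n = int(np.count_nonzero((t >= window.start) & (t < window.end)))
    return n / window.width


def align_spikes(spikes: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Join spikes to trials, attaching ``trial_uid`` and event times."""
    return eio.attach_trial_uid(spikes, trials)


def rate_table(
    aligned: pd.DataFrame,
    trials: pd.DataFrame,
    cells: pd.DataFrame,
    window: WindowSpec,
    trial_uids: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Per-trial window rates for every cell on its session's trials.

    Returns a long table ``(cell_id, trial_uid, rate)`` including
    explicit zero rows for trials without spikes in the window.  Trials
    lacking the alignment event are dropped (missing, not zero).
    """
    ev = EVENT_COL[window.alignment]
    tsub = trials[trials[ev].notna()]
    if trial_uids is not None:
        tsub = tsub[tsub["trial_uid"].isin(set(trial_uids))]
    grid = cells[["cell_id", "session_id"]].merge(
        tsub[["trial_uid", "session_id"]], on="session_id")[["cell_id", "trial_uid"]]
    rel = aligned["spike_time_s"].to_numpy() - aligned[ev].to_numpy()
    mask = (rel >= window.start) & (rel < window.end)
    hits = aligned.loc[mask, ["cell_id", "trial_uid"]]
    counts = hits.groupby(["cell_id", "trial_uid"]).size().rename("n")
    out = grid.merge(counts.reset_index(), on=["cell_id", "trial_uid"], how="left")
    out["rate"] = out["n"].fillna(0.0) / window.width
    return out.drop(columns="n")


def with_factors(rates: pd.DataFrame, trials: pd.DataFrame,
                 extra: Sequence[str] = ()) -> pd.DataFrame:
    cols = ["trial_uid", *FACTOR_COLS, "chosen_object", "correct", *extra]
    cols = list(dict.fromkeys(c for c in cols if c in trials.columns))
    return rates.merge(trials[cols], on="trial_uid", validate="many_to_one")


# ---------------------------------------------------------------------------
# trial splitting


def split_trials(
    trials: pd.DataFrame,
    cells: pd.DataFrame,
    seed: int,
    halves: tuple[str, str] = ("selection", "validation"),
    stratify: Sequence[str] = tuple(FACTOR_COLS),
) -> pd.DataFrame:
    """Random 50/50 split of each cell's trials, stratified by condition.

    Within each stratum (by default cycle x n_targets x object set x
    location) trials are alternately dealt to the two halves in a
    permuted order, so per-condition counts differ by at most one
    trial.  Fully reproducible from ``seed``; each cell receives an
    independent split.
    """
    strata = trials[list(stratify)].fillna(-1)
    stratum_codes = pd.factorize(
        pd.util.hash_pandas_object(strata, index=False))[0]
    by_session: dict[str, list[np.ndarray]] = {}
    for sess, grp in trials.groupby("session_id"):
        codes = stratum_codes[grp.index.to_numpy()]
        uids = grp["trial_uid"].to_numpy()
        by_session[sess] = [uids[codes == c] for c in np.unique(codes)]
    root = np.random.SeedSequence(seed)
    child = root.spawn(len(cells))
    rows = []
    for (cell, sess), cseed in zip(cells[["cell_id", "session_id"]].itertuples(index=False),
                                   child):
        rng = np.random.default_rng(cseed)
        for uids in by_session[sess]:
            order = rng.permutation(uids)
            offset = int(rng.integers(2))
            for i, uid in enumerate(order):
                rows.append((cell, uid, halves[(i + offset) % 2]))
    return pd.DataFrame(rows, columns=["cell_id", "trial_uid", "half"])


def half_uids(split: pd.DataFrame, cell_id: str, half: str) -> np.ndarray:
    sub = split[(split["cell_id"] == cell_id) & (split["half"] == half)]
    return sub["trial_uid"].to_numpy()


def _half_lookup(split: pd.DataFrame) -> pd.DataFrame:
    return split.set_index(["cell_id", "trial_uid"])["half"]


def restrict_to_half(rates: pd.DataFrame, split: pd.DataFrame, half: str) -> pd.DataFrame:
    """Keep only (cell, trial) pairs assigned to ``half``."""
    merged = rates.merge(split, on=["cell_id", "trial_uid"], how="left")
    return merged[merged["half"] == half].drop(columns="half")


# ---------------------------------------------------------------------------
# ANOVA and classification


def _anova_formula(df: pd.DataFrame, factors: Sequence[str],
                   interaction: Optional[tuple[str, str]] = None) -> tuple[str, list[str]]:
    kept, dropped = [], []
    for f in factors:
        if df[f].nunique(dropna=True) >= 2:
            kept.append(f)
        else:
            dropped.append(f)
    terms = [f"C({f})" for f in kept]
    if interaction and all(f in kept for f in interaction):
        terms.append(f"C({interaction[0]}):C({interaction[1]})")
    return "rate ~ " + " + ".join(terms) if terms else "rate ~ 1", dropped


def selection_anova(
    df: pd.DataFrame,
    factors: Sequence[str] = tuple(FACTOR_COLS),
    interaction: Optional[tuple[str, str]] = None,
) -> dict:
    """Type II main-effects ANOVA of per-trial rate on task factors.

    ``df`` holds one cell's trials with a ``rate`` column plus the
    factor columns.  Factors with a single observed level are dropped
    (and reported).  A zero-variance response yields p = 1 for every
    term rather than an error.  Returns ``{"p": {...}, "F": {...},
    "dropped": [...]}`` with keys per factor (and ``"factor_a:factor_b"``
    for the optional interaction).
    """
    df = df.dropna(subset=["rate"])
    out: dict = {"p": {}, "F": {}, "dropped": []}
    formula, dropped = _anova_formula(df, factors, interaction)
    out["dropped"] = dropped
    terms = [f for f in factors if f not in dropped]
    if interaction and all(f in terms for f in interaction):
        terms = terms + [f"{interaction[0]}:{interaction[1]}"]
    if len(df) < len(terms) + 2 or df["rate"].nunique() < 2 or not terms:
        for f in terms:
            out["p"][f] = 1.0
            out["F"][f] = 0.0
        return out
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1 or not np.isfinite(model.scale):
        # saturated or degenerate design: no error df to test against
        for f in terms:
            out["p"][f] = 1.0
            out["F"][f] = 0.0
        return out
    try:
        table = sm.stats.anova_lm(model, typ=2)
    except ValueError:
        for f in terms:
            out["p"][f] = 1.0
            out["F"][f] = 0.0
        return out
    for f in terms:
        row = f"C({f})" if ":" not in f else \
            f"C({f.split(':')[0]}):C({f.split(':')[1]})"
        if row in table.index:
            p = float(table.loc[row, "PR(>F)"])
            out["p"][f] = 1.0 if np.isnan(p) else p
            Fv = float(table.loc[row, "F"])
            out["F"][f] = 0.0 if np.isnan(Fv) else Fv
    return out


def classify_cells(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach explore/exploit/none labels from the cycle main effect.

    ``results`` needs columns ``p_cycle``, ``c1_mean``, ``c4_mean``
    (selection-half means).  ``explore`` = significant cycle effect with
    Cycle 1 > Cycle 4; ``exploit`` = the reverse.
    """
    out = results.copy()
    sig = out["p_cycle"] < alpha
    out["label"] = "none"
    out.loc[sig & (out["c1_mean"] > out["c4_mean"]), "label"] = "explore"
    out.loc[sig & (out["c1_mean"] < out["c4_mean"]), "label"] = "exploit"
    return out


def select_cells(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    split: pd.DataFrame,
    alpha: float = 0.05,
    phases: Sequence[str] = PHASES,
) -> pd.DataFrame:
    """Run the full selection ANOVA per cell and phase.

    Returns one row per cell x phase with the cycle main-effect p,
    selection-half Cycle-1/Cycle-4 means, the label, the
    validation-half Cycle 4 - Cycle 1 mean-rate difference
    (``val_diff``, used by :func:`validate_selection`), and a per-cell
    two-sample t-test of the same contrast on validation trials
    (``val_t``/``val_p``) — unbiased because selection never saw that
    half.
    """
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    rows = []
    for phase in phases:
        win = analysis_window(phase)
        rates = rate_table(aligned, trials, cells, win,
                           trial_uids=base["trial_uid"])
        rates = with_factors(rates, trials)
        sel = restrict_to_half(rates, split, "selection")
        val = restrict_to_half(rates, split, "validation")
        val_diff = (val.groupby(["cell_id", "cycle"])["rate"].mean()
                    .unstack("cycle"))
        val_groups = dict(tuple(val.groupby("cell_id")))
        for cell_id, grp in sel.groupby("cell_id"):
            res = selection_anova(grp)
            cyc = grp.groupby("cycle")["rate"].mean()
            c1, c4 = cyc.get(1, np.nan), cyc.get(4, np.nan)
            vd, vt, vp = np.nan, np.nan, np.nan
            if cell_id in val_diff.index:
                v = val_diff.loc[cell_id]
                vd = v.get(4, np.nan) - v.get(1, np.nan)
                vgrp = val_groups[cell_id]
                a = vgrp.loc[vgrp["cycle"] == 4, "rate"]
                b = vgrp.loc[vgrp["cycle"] == 1, "rate"]
                if len(a) >= 2 and len(b) >= 2 and (a.var() + b.var()) > 0:
                    vt, vp = sps.ttest_ind(a, b)
            rows.append({
                "cell_id": cell_id, "phase": phase,
                "p_cycle": res["p"].get("cycle", 1.0),
                "F_cycle": res["F"].get("cycle", 0.0),
                "p_n_targets": res["p"].get("n_targets", np.nan),
                "p_object_set": res["p"].get("object_set", np.nan),
                "p_location": res["p"].get("chosen_location", np.nan),
                "dropped_factors": ";".join(res["dropped"]),
                "c1_mean": c1, "c4_mean": c4,
                "val_diff": vd, "val_t": vt, "val_p": vp,
            })
    return classify_cells(pd.DataFrame(rows), alpha=alpha)


def validate_selection(selection: pd.DataFrame) -> pd.DataFrame:
    """Across-cell t-tests of the validation-half cycle preference.

    For each labeled group (phase x explore/exploit) a one-sample t-test
    on the validation Cycle 4 - Cycle 1 differences checks that the
    preference found on the selection half replicates with the same
    sign on unseen trials.  Reports two-tailed and directed
    (sign-consistent) one-tailed p.  Groups with fewer than two cells
    are skipped with a warning.
    """
    rows = []
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        d = grp["val_diff"].dropna().to_numpy()
        if len(d) < 2:
            logger.warning("validation group %s/%s has %d cell(s); skipped",
                           phase, label, len(d))
            continue
        t, p = sps.ttest_1samp(d, 0.0)
        expected_sign = -1.0 if label == "explore" else 1.0
        p_one = sps.t.sf(expected_sign * t, len(d) - 1)
        rows.append({"phase": phase, "label": label, "n_cells": len(d),
                     "mean_val_diff": float(d.mean()), "t": float(t),
                     "df": len(d) - 1, "p_two_tailed": float(p),
                     "p_one_tailed": float(p_one),
                     "sign_consistent": bool(expected_sign * d.mean() > 0)})
    return pd.DataFrame(rows, columns=[
        "phase", "label", "n_cells", "mean_val_diff", "t", "df",
        "p_two_tailed", "p_one_tailed", "sign_consistent"])


# ---------------------------------------------------------------------------
# normalization and PSTHs


def unweighted_cell_means(rates: pd.DataFrame,
                          by: Sequence[str] = ("n_targets", "object_set",
                                               "chosen_location")) -> pd.Series:
    """Per cell, the unweighted mean rate over condition cells:
    condition means are averaged with equal weight regardless of trial
    counts; empty condition cells are simply absent from the average."""
    by = [b for b in by if b in rates.columns and rates[b].nunique() > 0]
    if not by:
        return rates.groupby("cell_id")["rate"].mean()
    per_cond = rates.groupby(["cell_id", *by], observed=True)["rate"].mean()
    return per_cond.groupby("cell_id").mean()


def cell_norms(trials: pd.DataFrame, aligned: pd.DataFrame, cells: pd.DataFrame,
               split: pd.DataFrame) -> pd.Series:
    """Each cell's mean-activity normalization constant (spikes/s).

    Defined as the unweighted mean over the selection-ANOVA condition
    cells (cycle x n_targets x object set x location, correct trials of
    cycles 1 and 4, selection half), averaged over the CH and FB 400 ms
    windows.
    """
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    per_phase = []
    for phase in PHASES:
        rates = rate_table(aligned, trials, cells, analysis_window(phase),
                           trial_uids=base["trial_uid"])
        rates = with_factors(rates, trials)
        rates = restrict_to_half(rates, split, "selection")
        per_phase.append(unweighted_cell_means(
            rates, by=("cycle", "n_targets", "object_set", "chosen_location")))
    return pd.concat(per_phase, axis=1).mean(axis=1).rename("norm")


def build_psth(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    alignment: str,
    norms: pd.Series,
    trial_uids: Optional[Iterable[int]] = None,
    by: Sequence[str] = ("n_targets", "object_set", "chosen_location"),
) -> pd.DataFrame:
    """Normalized per-cell PSTH: cells x 28 window centers.

    Each window's rate is the unweighted mean over the ``by`` condition
    cells, divided by the cell's mean activity.  Cells whose
    normalization constant falls below ``MIN_NORM_RATE`` (near-silent
    cells, for which the ratio is unstable) are excluded and logged.
    """
    ok = norms[norms >= MIN_NORM_RATE]
    low = norms.index.difference(ok.index)
    if len(low):
        logger.info("excluding %d near-silent cell(s) from normalized PSTHs", len(low))
    use_cells = cells[cells["cell_id"].isin(ok.index)]
    cols = {}
    if trial_uids is not None:
        trial_uids = np.asarray(list(trial_uids))
    for win in psth_windows(alignment):
        center = round(win.start + win.width / 2, 4)
        rates = rate_table(aligned, trials, use_cells, win, trial_uids=trial_uids)
        rates = with_factors(rates, trials)
        cols[center] = unweighted_cell_means(rates, by=by)
    psth = pd.DataFrame(cols)
    return psth.div(ok.reindex(psth.index), axis=0)


def group_psth(psth: pd.DataFrame, selection: pd.DataFrame) -> pd.DataFrame:
    """Average normalized PSTHs within each labeled group."""
    rows = {}
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        members = psth.index.intersection(grp["cell_id"])
        if len(members):
            rows[(phase, label)] = psth.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# statistical helpers


def paired_t(a: pd.Series, b: pd.Series) -> dict:
    """Paired t-test across cells on two aligned per-cell series."""
    joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
    if len(joined) < 2:
        return {"n": len(joined), "t": np.nan, "df": np.nan, "p": np.nan}
    t, p = sps.ttest_rel(joined["a"], joined["b"])
    return {"n": len(joined), "t": float(t), "df": len(joined) - 1, "p": float(p)}


def rm_anova_f(per_cell: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA across cells.

    ``per_cell`` is wide: rows = cells, columns = the repeated
    conditions.  Incomplete cells are dropped (complete-case).  Uses
    pingouin's repeated-measures ANOVA.
    """
    data = per_cell.dropna()
    n, k = data.shape
    if n < 2 or k < 2:
        return {"n": int(n), "F": np.nan, "df1": np.nan,
                "df2": np.nan, "p": np.nan}
    try:
        import pingouin as pg
        long = data.reset_index().melt(id_vars="cell_id", var_name="cond",
                                       value_name="value")
        res = pg.rm_anova(data=long, dv="value", within="cond",
                          subject="cell_id")
        row = res.iloc[0]
        return {"n": int(n), "F": float(row["F"]),
                "df1": float(row["ddof1"]), "df2": float(row["ddof2"]),
                "p": float(row["p_unc"])}
    except ZeroDivisionError:
        # sphericity estimate degenerates for very small samples;
        # fall back to the uncorrected within-subject F
        x = data.to_numpy(dtype=float)
        grand = x.mean()
        ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        df1, df2 = k - 1, (k - 1) * (n - 1)
        if ss_err <= 0 or df2 <= 0:
            return {"n": int(n), "F": np.nan, "df1": float(df1),
                    "df2": float(df2), "p": np.nan}
        F = (ss_cond / df1) / (ss_err / df2)
        return {"n": int(n), "F": float(F), "df1": float(df1),
                "df2": float(df2), "p": float(sps.f.sf(F, df1, df2))}


# ---------------------------------------------------------------------------
# condition helpers shared by the one-shot / expectancy analyses


def regular_cycle_uids(trials: pd.DataFrame) -> np.ndarray:
    """Trial uids belonging to *regular* cycles: cycles 2-4 whose first
    response was correct (the exceptional failed-start cycles are
    excluded from one-shot analyses)."""
    resp = trials[trials["chosen_object"].notna()].sort_values("trial_in_cycle")
    first = resp.groupby(["session_id", "problem_id", "cycle"]).first()
    good = first[first["correct"]].index
    key = trials.set_index(["session_id", "problem_id", "cycle"]).index
    mask = key.isin(good) & (trials["cycle"] >= 2).to_numpy()
    return trials.loc[mask.to_numpy() if hasattr(mask, "to_numpy") else mask,
                      "trial_uid"].to_numpy()


def errors_before(trials: pd.DataFrame) -> pd.Series:
    """Per trial, number of earlier error responses in the same cycle."""
    t = trials.sort_values(["session_id", "problem_id", "cycle", "trial_in_cycle"])
    err = (t["chosen_object"].notna() & ~t["correct"]).astype(int)
    cum = err.groupby([t["session_id"], t["problem_id"], t["cycle"]]).cumsum() - err
    return pd.Series(cum.to_numpy(), index=t["trial_uid"].to_numpy(),
                     name="errors_before").reindex(trials["trial_uid"])


def failed_learning_uids(trials: pd.DataFrame) -> np.ndarray:
    """Correct Cycle-2 trials preceded by >= 1 Cycle-2 error (learning
    did not complete in Cycle 1)."""
    nerr = errors_before(trials)
    mask = ((trials["cycle"] == 2) & trials["correct"]
            & (nerr.to_numpy() >= 1))
    return trials.loc[mask, "trial_uid"].to_numpy()


def favored_location(trials: pd.DataFrame, animal_id: str) -> int:
    """Modal chosen location on the first trial of Cycle 1 for one
    animal; ties resolved to the lowest location index (logged)."""
    first = trials[(trials["animal_id"] == animal_id) & (trials["cycle"] == 1)
                   & (trials["trial_in_cycle"] == 1)
                   & trials["chosen_location"].notna()]
    if first.empty:
        raise ValueError(f"no Cycle-1 first trials for animal {animal_id!r}")
    counts = first["chosen_location"].astype(int).value_counts()
    top = counts[counts == counts.max()].index
    if len(top) > 1:
        logger.warning("favored-location tie for animal %s among %s; taking lowest",
                       animal_id, sorted(top))
    return int(min(top))


def _group_cells(selection: pd.DataFrame, phase: str, label: str) -> pd.Index:
    sub = selection[(selection["phase"] == phase) & (selection["label"] == label)]
    return pd.Index(sub["cell_id"].unique())


def _normalized_cell_means(
    trials: pd.DataFrame, aligned: pd.DataFrame, cells: pd.DataFrame,
    norms: pd.Series, phase: str, trial_uids: np.ndarray,
    by: Sequence[str] = ("object_set", "chosen_location"),
) -> pd.Series:
    """Per-cell normalized unweighted mean rate in the phase's 400 ms
    window over the given trials."""
    if len(trial_uids) == 0:
        return pd.Series(dtype=float)
    rates = rate_table(aligned, trials, cells, analysis_window(phase),
                       trial_uids=trial_uids)
    rates = with_factors(rates, trials)
    means = unweighted_cell_means(rates, by=by)
    ok = norms[norms >= MIN_NORM_RATE]
    return (means / ok.reindex(means.index)).dropna()


# ---------------------------------------------------------------------------
# one-shot and expectancy analyses


def one_shot_cycle_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    norms: pd.Series,
) -> dict:
    """Group activity across cycles 1-4 in 1-target problems.

    Cycles 1 and 4 use the validation half only (their selection-half
    trials chose the cells); cycles 2 and 3 use all trials.  Cycles 2-4
    are restricted to regular cycles (first response correct).  For each
    labeled group the analysis reports mean normalized activity per
    cycle, a paired t-test Cycle 1 vs Cycle 2 (the one-shot switch), and
    a repeated-measures F over Cycles 2-4 (flat under a binary state).
    """
    base = trials[trials["correct"] & (trials["n_targets"] == 1)]
    regular = set(regular_cycle_uids(trials))
    half = _half_lookup(split)
    out: dict = {}
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        members = cells[cells["cell_id"].isin(grp["cell_id"])]
        per_cycle = {}
        for cyc in (1, 2, 3, 4):
            sub = base[base["cycle"] == cyc]
            uids = sub["trial_uid"].to_numpy()
            if cyc >= 2:
                uids = np.array([u for u in uids if u in regular])
            means = {}
            for cell_id in members["cell_id"]:
                cell_uids = uids
                if cyc in (1, 4):
                    keep = half.loc[cell_id].reindex(cell_uids) == "validation"
                    cell_uids = cell_uids[keep.to_numpy(dtype=bool)]
                m = _normalized_cell_means(
                    trials, aligned, members[members["cell_id"] == cell_id],
                    norms, phase, cell_uids)
                if cell_id in m.index:
                    means[cell_id] = m.loc[cell_id]
            per_cycle[cyc] = pd.Series(means, dtype=float)
        wide = pd.DataFrame(per_cycle)
        wide.index.name = "cell_id"
        out[(phase, label)] = {
            "cycle_means": wide.mean(axis=0).to_dict(),
            "n_cells": int(len(wide)),
            "t_c1_vs_c2": paired_t(wide.get(1), wide.get(2)),
            "F_c2_c4": rm_anova_f(wide[[c for c in (2, 3, 4) if c in wide]]),
        }
    return out


def failed_learning_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    norms: pd.Series,
) -> dict:
    """Failed-learning Cycle-2 trials versus regular Cycle 2 and Cycle 1.

    Failed-learning trials (correct Cycle-2 trials after at least one
    Cycle-2 error, 1-target problems) probe whether the explore state is
    maintained when the Cycle-1 reward did not produce learning.
    Skipped (empty dict entries) when too few such trials exist.
    """
    base = trials[trials["correct"] & (trials["n_targets"] == 1)]
    failed = set(failed_learning_uids(trials))
    regular = set(regular_cycle_uids(trials))
    half = _half_lookup(split)
    out: dict = {}
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        members = cells[cells["cell_id"].isin(grp["cell_id"])]
        c2 = base[base["cycle"] == 2]
        uids_failed = np.array([u for u in c2["trial_uid"] if u in failed])
        uids_regular = np.array([u for u in c2["trial_uid"] if u in regular])
        m_failed = _normalized_cell_means(trials, aligned, members, norms,
                                          phase, uids_failed)
        m_regular = _normalized_cell_means(trials, aligned, members, norms,
                                           phase, uids_regular)
        c1 = base[base["cycle"] == 1]
        means_c1 = {}
        for cell_id in members["cell_id"]:
            keep = half.loc[cell_id].reindex(c1["trial_uid"].to_numpy()) == "validation"
            m = _normalized_cell_means(
                trials, aligned, members[members["cell_id"] == cell_id], norms,
                phase, c1["trial_uid"].to_numpy()[keep.to_numpy(dtype=bool)])
            if cell_id in m.index:
                means_c1[cell_id] = m.loc[cell_id]
        m_c1 = pd.Series(means_c1, dtype=float)
        n_cells_with_failed = int(m_failed.notna().sum())
        if n_cells_with_failed < 2:
            out[(phase, label)] = {"skipped": True,
                                   "n_cells_with_failed_trials": n_cells_with_failed}
            continue
        out[(phase, label)] = {
            "skipped": False,
            "means": {"failed_c2": float(m_failed.mean()),
                      "regular_c2": float(m_regular.mean()),
                      "c1": float(m_c1.mean())},
            "t_failed_vs_regular": paired_t(m_failed, m_regular),
            "t_failed_vs_c1": paired_t(m_failed, m_c1),
        }
    return out


def sampling_order_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    norms: pd.Series,
) -> dict:
    """Activity by Cycle-1 sampling position (reward-expectancy probe).

    Correct 1-target Cycle-1 trials in which the target was found at the
    animal's favored location are binned by how many different objects
    had been sampled before (+1 -> position 1-4).  Under a binary
    explore state, group activity is flat across positions; a graded
    expectancy signal would produce a positional ramp.  Selection-half
    trials are removed.
    """
    return _position_groups_analysis(trials, aligned, cells, selection, split,
                                     norms, kind="sampling_order")


def correct_error_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    norms: pd.Series,
) -> dict:
    """Target vs nontarget selections in Cycle 1 (prediction-error probe).

    Uses 1-target Cycle-1 trials at the favored location, revisits
    excluded, errors *included*.  Correct and incorrect means are
    averaged unweighted over serial positions 1-3 (an incorrect fourth
    sample is impossible: three eliminated nontargets leave only the
    target) and compared by paired t-test per group.
    """
    return _position_groups_analysis(trials, aligned, cells, selection, split,
                                     norms, kind="correct_error")


def _position_groups_analysis(trials, aligned, cells, selection, split, norms,
                              kind: str) -> dict:
    half = _half_lookup(split)
    out: dict = {}
    animals = trials["animal_id"].unique()
    fav = {a: favored_location(trials, a) for a in animals}
    fav_loc = trials["animal_id"].map(fav)
    c1 = trials[(trials["cycle"] == 1) & (trials["n_targets"] == 1)
                & trials["chosen_location"].notna()
                & (trials["chosen_location"] == fav_loc)]
    c1 = c1.copy()
    if kind == "sampling_order":
        c1 = c1[c1["correct"]]
        c1["cond"] = c1["n_already_sampled"].astype(int) + 1
    else:
        c1 = c1[c1["response_type"].isin(["T", "NT_novel"])]
        c1 = c1[c1["n_already_sampled"] <= 2]  # serial positions 1-3
        c1["cond"] = np.where(c1["correct"], "correct", "incorrect")
        c1["pos"] = c1["n_already_sampled"].astype(int) + 1
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        members = cells[cells["cell_id"].isin(grp["cell_id"])]
        percell: dict = {}
        for cell_id in members["cell_id"]:
            norm = norms.get(cell_id, np.nan)
            if not np.isfinite(norm) or norm < MIN_NORM_RATE:
                continue
            keep = half.loc[cell_id].reindex(c1["trial_uid"].to_numpy()) == "validation"
            sub = c1[keep.to_numpy(dtype=bool)]
            if sub.empty:
                continue
            rates = rate_table(aligned, trials,
                               members[members["cell_id"] == cell_id],
                               analysis_window(phase),
                               trial_uids=sub["trial_uid"])
            meta_cols = ["trial_uid", "cond"] + (["pos"] if "pos" in sub else [])
            rates = rates.merge(sub[meta_cols], on="trial_uid")
            if kind == "correct_error":
                # unweighted over serial position within each outcome
                per_pos = rates.groupby(["cond", "pos"])["rate"].mean()
                vals = per_pos.groupby("cond").mean()
            else:
                vals = rates.groupby("cond")["rate"].mean()
            percell[cell_id] = vals / norm
        wide = pd.DataFrame(percell).T
        wide.index.name = "cell_id"
        entry: dict = {"n_cells": int(len(wide)),
                       "cond_means": wide.mean(axis=0).to_dict()}
        if kind == "sampling_order":
            entry["F_positions"] = rm_anova_f(wide)
        else:
            if {"correct", "incorrect"} <= set(wide.columns):
                entry["t_correct_vs_incorrect"] = paired_t(wide["correct"],
                                                           wide["incorrect"])
            else:
                entry["t_correct_vs_incorrect"] = {"n": 0, "t": np.nan,
                                                   "df": np.nan, "p": np.nan}
        out[(phase, label)] = entry
    return out


def discovery_type_analysis(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    norms: pd.Series,
) -> dict:
    """Target-discovery trials: 1-target vs first-of-2 vs second-of-2.

    These three Cycle-1 discovery types carry different reward
    expectancies (0.25 vs 0.5 at the first sample), so a flat
    repeated-measures F across them indicates binary state coding rather
    than expectancy scaling.  Selection-half trials removed.
    """
    half = _half_lookup(split)
    disc = trials[(trials["cycle"] == 1) & trials["correct"]].copy()
    ttype = np.where(disc["n_targets"] == 1, "discovery_1t",
                     np.where(disc["n_found_before"] == 0, "first_of_2",
                              "second_of_2"))
    disc["cond"] = ttype
    out: dict = {}
    for (phase, label), grp in selection.groupby(["phase", "label"]):
        if label == "none":
            continue
        members = cells[cells["cell_id"].isin(grp["cell_id"])]
        percell: dict = {}
        for cell_id in members["cell_id"]:
            keep = half.loc[cell_id].reindex(disc["trial_uid"].to_numpy()) == "validation"
            sub = disc[keep.to_numpy(dtype=bool)]
            norm = norms.get(cell_id, np.nan)
            if sub.empty or not np.isfinite(norm) or norm < MIN_NORM_RATE:
                continue
            rates = rate_table(aligned, trials,
                               members[members["cell_id"] == cell_id],
                               analysis_window(phase),
                               trial_uids=sub["trial_uid"])
            rates = rates.merge(sub[["trial_uid", "cond"]], on="trial_uid")
            percell[cell_id] = rates.groupby("cond")["rate"].mean() / norm
        wide = pd.DataFrame(percell).T
        wide.index.name = "cell_id"
        out[(phase, label)] = {
            "n_cells": int(len(wide)),
            "cond_means": wide.mean(axis=0).to_dict(),
            "F_types": rm_anova_f(wide),
        }
    return out


def object_interaction_screen(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    split: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Fraction of labeled cells whose cycle preference depends on object.

    Selection-half ANOVAs are repeated separately per object set with an
    added object factor; the reported fraction of explore/exploit cells
    with a significant cycle x object interaction is averaged over the
    two sets.  A stable explore/exploit state predicts a fraction near
    the false-positive rate.
    """
    base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
    out: dict = {}
    for phase in PHASES:
        labeled = selection[(selection["phase"] == phase)
                            & (selection["label"] != "none")]
        members = cells[cells["cell_id"].isin(labeled["cell_id"])]
        if members.empty:
            out[phase] = {"fraction": np.nan, "n_cells": 0}
            continue
        rates_all = rate_table(aligned, trials, members, analysis_window(phase),
                               trial_uids=base["trial_uid"])
        rates_all = with_factors(rates_all, trials)
        rates_all = restrict_to_half(rates_all, split, "selection")
        fracs = []
        for oset, sub in rates_all.groupby("object_set"):
            flags = []
            for _, grp in sub.groupby("cell_id"):
                res = selection_anova(
                    grp, factors=("cycle", "chosen_object", "n_targets",
                                  "chosen_location"),
                    interaction=("cycle", "chosen_object"))
                p = res["p"].get("cycle:chosen_object", np.nan)
                if np.isfinite(p):
                    flags.append(p < alpha)
            if flags:
                fracs.append(np.mean(flags))
        out[phase] = {"fraction": float(np.mean(fracs)) if fracs else np.nan,
                      "n_cells": int(members.shape[0])}
    return out


def outcome_coding_anova(
    trials: pd.DataFrame,
    aligned: pd.DataFrame,
    cells: pd.DataFrame,
    selection: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Correct/error coding at feedback across the whole sample.

    ANOVA of the FB-window rate on correct/error x object set x
    location over *all* response trials (selection and validation halves
    combined).  Counts cells with a significant outcome main effect,
    split by preferred direction, and reports the overlap with the
    FB-phase explore/exploit cells.
    """
    resp = trials[trials["chosen_object"].notna() & trials["t_fb_on"].notna()]
    rates = rate_table(aligned, trials, cells, analysis_window("FB"),
                       trial_uids=resp["trial_uid"])
    rates = with_factors(rates, trials)
    rows = []
    for cell_id, grp in rates.groupby("cell_id"):
        res = selection_anova(grp, factors=("correct", "object_set",
                                            "chosen_location"))
        p = res["p"].get("correct", 1.0)
        means = grp.groupby("correct")["rate"].mean()
        direction = "correct" if means.get(True, np.nan) > means.get(False, np.nan) \
            else "error"
        rows.append({"cell_id": cell_id, "p_outcome": p,
                     "direction": direction, "significant": p < alpha})
    table = pd.DataFrame(rows)
    fb_labeled = set(selection[(selection["phase"] == "FB")
                               & (selection["label"] != "none")]["cell_id"])
    sig = table[table["significant"]]
    overlap = len(set(sig["cell_id"]) & fb_labeled)
    return {
        "table": table,
        "n_cells": int(len(table)),
        "n_outcome_cells": int(len(sig)),
        "fraction_outcome_cells": float(len(sig) / len(table)) if len(table) else np.nan,
        "n_prefer_correct": int((sig["direction"] == "correct").sum()),
        "n_prefer_error": int((sig["direction"] == "error").sum()),
        "n_fb_explore_exploit": len(fb_labeled),
        "overlap_with_fb_cells": overlap,
        "overlap_fraction": float(overlap / len(fb_labeled)) if fb_labeled else np.nan,
    }
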