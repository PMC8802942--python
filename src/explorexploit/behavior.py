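"""Behavioral summaries for the four-cycle search task.

Covers the standard descriptive and inferential battery: trials per
cycle and response-type breakdowns (per animal and problem type), the
Cycle-1 revisit rate against the memoryless chance expectation
(0/25/50/75% with 0-3 objects already sampled), and the decline of
nontarget selections across cycles tested by repeated-measures ANOVA
over session means with Tukey HSD follow-ups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps

from .task import N_OBJECTS, chance_revisit_probability

REVISIT_TYPES = ("NT_revisit", "T_revisit")
NONTARGET_TYPES = ("NT_novel", "NT_revisit")


def _response_trials(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["chosen_object"].notna()]


def summarize_cycles(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean trials per cycle and response-type counts.

    One row per animal x problem type (1-/2-target) x cycle, with the
    mean number of response trials per problem-cycle and mean counts of
    each response type.  Input should already have passed problem
    exclusion.
    """
    resp = _response_trials(trials)
    per_cycle = (resp.groupby(["animal_id", "n_targets", "session_id",
                               "problem_id", "cycle"])
                 .agg(n_trials=("trial_uid", "size"))
                 .reset_index())
    counts = (resp.groupby(["animal_id", "n_targets", "session_id", "problem_id",
                            "cycle"])["response_type"]
              .value_counts().unstack(fill_value=0).reset_index())
    merged = per_cycle.merge(counts, on=["animal_id", "n_targets", "session_id",
                                         "problem_id", "cycle"])
    type_cols = [c for c in ("T", "NT_novel", "NT_revisit", "T_revisit")
                 if c in merged.columns]
    out = (merged.groupby(["animal_id", "n_targets", "cycle"])
           [["n_trials", *type_cols]].mean().reset_index())
    return out.rename(columns={"n_trials": "mean_trials_per_cycle"})


def revisit_vs_chance(trials: pd.DataFrame) -> pd.DataFrame:
    """Cycle-1 revisit rates versus the memoryless chance expectation.

    Trials are binned by the number of different objects already
    sampled this cycle (0-3); within each bin the observed proportion of
    reselections is compared to ``n_already_sampled / 4`` by a
    chi-squared goodness-of-fit test.  Split by animal and problem
    type.  Empty bins are reported with NaN statistics rather than
    raising.
    """
    c1 = _response_trials(trials)
    c1 = c1[c1["cycle"] == 1]
    rows = []
    for (animal, ntg), grp in c1.groupby(["animal_id", "n_targets"]):
        for k in range(N_OBJECTS):
            sub = grp[grp["n_already_sampled"] == k]
            expected_p = chance_revisit_probability(k)
            n = len(sub)
            if n == 0:
                rows.append({"animal_id": animal, "n_targets": ntg,
                             "n_already_sampled": k, "n_trials": 0,
                             "observed_pct": np.nan,
                             "expected_pct": 100 * expected_p,
                             "chi2": np.nan, "p": np.nan})
                continue
            obs_rev = int(sub["response_type"].isin(REVISIT_TYPES).sum())
            if expected_p in (0.0, 1.0):
                # degenerate null: chance puts all mass on one category
                chi2 = np.nan if obs_rev == n * expected_p else np.inf
                p = np.nan if not np.isfinite(chi2) else 0.0
                if obs_rev == n * expected_p:
                    chi2, p = 0.0, 1.0
            else:
                f_obs = [obs_rev, n - obs_rev]
                f_exp = [n * expected_p, n * (1 - expected_p)]
                chi2, p = sps.chisquare(f_obs, f_exp)
            rows.append({"animal_id": animal, "n_targets": ntg,
                         "n_already_sampled": k, "n_trials": n,
                         "observed_pct": 100 * obs_rev / n,
                         "expected_pct": 100 * expected_p,
                         "chi2": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)


def nontarget_decline_test(trials: pd.DataFrame) -> dict:
    """Decline of nontarget selections across cycles.

    The unit of analysis is the session mean: for each session and
    cycle, the mean number of nontarget selections (novel + revisit)
    per problem.  A one-way repeated-measures ANOVA over cycles (session
    as subject) is run per animal and problem type, followed by Tukey
    HSD on all cycle pairs.  Raises when fewer than two sessions are
    available.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    resp = _response_trials(trials)
    nt = resp.assign(is_nt=resp["response_type"].isin(NONTARGET_TYPES))
    per_problem = (nt.groupby(["animal_id", "n_targets", "session_id",
                               "problem_id", "cycle"])["is_nt"].sum()
                   .reset_index(name="n_nontarget"))
    session_means = (per_problem
                     .groupby(["animal_id", "n_targets", "session_id", "cycle"])
                     ["n_nontarget"].mean().reset_index())
    out: dict = {}
    for (animal, ntg), grp in session_means.groupby(["animal_id", "n_targets"]):
        n_sessions = grp["session_id"].nunique()
        if n_sessions < 2:
            raise ValueError(
                f"nontarget decline test needs >=2 sessions for animal {animal}"
                f" ({ntg}-target); got {n_sessions}")
        wide = grp.pivot(index="session_id", columns="cycle",
                         values="n_nontarget").dropna()
        if wide.to_numpy().std() == 0:
            res = {"F": 0.0, "p": 1.0, "df1": np.nan, "df2": np.nan}
            tukey = None
        else:
            aov = pg.rm_anova(data=grp, dv="n_nontarget", within="cycle",
                              subject="session_id")
            row = aov.iloc[0]
            res = {"F": float(row["F"]), "p": float(row["p_unc"]),
                   "df1": float(row["ddof1"]), "df2": float(row["ddof2"])}
            hsd = pairwise_tukeyhsd(grp["n_nontarget"], grp["cycle"])
            tukey = pd.DataFrame(hsd.summary().data[1:],
                                 columns=hsd.summary().data[0])
        out[(animal, int(ntg))] = {"anova": res, "tukey": tukey,
                                   "session_means": wide}
    return out
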