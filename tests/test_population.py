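"""Population analyses: preference vectors, cross-generalization, discriminant."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from explorexploit import io as eio
from explorexploit import population as popm
from explorexploit import selection as sel
from explorexploit import simulate as sim


def _deterministic_dataset():
    """Two cells with constant rates: one prefers Cycle 4 (10 vs 20 Hz),
    the other the reverse.  Spikes are laid on a regular grid so every
    100 ms window holds exactly rate/10 spikes."""
    problems = sim.simulate_behavior(16, sim.optimal_agent(seed=1), seed=1)
    trials = eio.problems_to_frame(problems)
    cells = pd.DataFrame({"cell_id": ["D1", "D2"],
                          "session_id": ["S001", "S001"],
                          "animal_id": ["A", "A"], "region": ["PFC", "PFC"]})
    rows = []
    for t in trials.itertuples():
        if np.isnan(t.t_fb_on):
            continue
        for cell, (r1, r4) in (("D1", (10, 20)), ("D2", (20, 10))):
            rate = r1 if t.cycle == 1 else r4
            for ev in (t.t_ch_on, t.t_fb_on):
                # regular grid over [ev, ev + 0.4); offset avoids spikes
                # landing on window edges up to float rounding
                for k in range(int(rate * 0.4)):
                    rows.append({"cell_id": cell, "session_id": t.session_id,
                                 "problem_id": t.problem_id, "cycle": t.cycle,
                                 "trial_in_cycle": t.trial_in_cycle,
                                 "spike_time_s": ev + k / rate + 1e-3})
    spikes = pd.DataFrame(rows)
    return trials, spikes, cells


class TestCyclePreferenceVectors:
    def test_constant_rate_cells_give_signed_difference(self):
        trials, spikes, cells = _deterministic_dataset()
        aligned = sel.align_spikes(spikes, trials)
        split = sel.split_trials(trials, cells, seed=3, halves=("A", "B"))
        vecs = popm.cycle_preference_vectors(trials, aligned, cells, split, "A")
        assert vecs.shape == (2, 8)
        assert np.allclose(vecs.loc["D1"], 10.0)
        assert np.allclose(vecs.loc["D2"], -10.0)

    def test_unweighted_mean_matches_hand_oracle(self, dataset, aligned):
        """On an unbalanced design the unweighted mean weights each
        location x n_targets cell equally, not each trial."""
        trials, cells = dataset["trials"], dataset["cells"]
        split = sel.split_trials(trials, cells, seed=9, halves=("A", "B"))
        win = popm.crossgen_windows()[0]
        vecs = popm.cycle_preference_vectors(trials, aligned, cells, split,
                                             "A", windows=[win])
        cell_id = vecs.dropna().index[0]
        base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
        rates = sel.rate_table(aligned, trials,
                               cells[cells["cell_id"] == cell_id], win,
                               trial_uids=base["trial_uid"])
        rates = sel.with_factors(rates, trials)
        rates = sel.restrict_to_half(rates, split, "A")
        per = {}
        for cyc, grp in rates.groupby("cycle"):
            conds = grp.groupby(["n_targets", "chosen_location"])["rate"].mean()
            per[cyc] = conds.mean()
        assert vecs.loc[cell_id].iloc[0] == pytest.approx(per[4] - per[1])


class TestCrossGeneralization:
    def test_conjunctive_population_shows_block_structure(self, dataset,
                                                          aligned):
        trials, cells = dataset["trials"], dataset["cells"]
        mat = popm.cross_generalization_matrix(trials, aligned, cells, seed=17)
        assert mat.shape == (8, 8)
        assert (mat.to_numpy() <= 1.0 + 1e-9).all()
        assert popm.phase_block_contrast(mat) > 0.15

    def test_requires_three_cells(self, dataset, aligned):
        with pytest.raises(ValueError, match="3 cells"):
            popm.cross_generalization_matrix(dataset["trials"], aligned,
                                             dataset["cells"].head(2), seed=1)


@pytest.fixture(scope="module")
def fitted(dataset, aligned):
    trials, cells = dataset["trials"], dataset["cells"]
    split = sel.split_trials(trials, cells, seed=23, halves=("train", "test"))
    model = popm.fit_discriminant(trials, aligned, cells, split, "CH")
    return trials, cells, split, model


class TestDiscriminant:
    def test_weights_match_brute_force_oracle(self, dataset, aligned, fitted):
        trials, cells, split, model = fitted
        base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
        rates = sel.rate_table(aligned, trials, cells, model.window,
                               trial_uids=base["trial_uid"])
        rates = sel.with_factors(rates, trials)
        rates = sel.restrict_to_half(rates, split, "train")
        for cell_id in model.cell_ids[:5]:
            grp = rates[rates["cell_id"] == cell_id]
            m1 = grp.loc[grp["cycle"] == 1, "rate"].mean()
            m4 = grp.loc[grp["cycle"] == 4, "rate"].mean()
            s1 = grp.loc[grp["cycle"] == 1, "rate"].std(ddof=1)
            s4 = grp.loc[grp["cycle"] == 4, "rate"].std(ddof=1)
            c, s = (m1 + m4) / 2, (s1 + s4) / 2
            expect = 0.0 if s == 0 else ((m4 - c) / s - (m1 - c) / s)
            assert model.weights[cell_id] == pytest.approx(expect)

    def test_train_projections_symmetric(self, dataset, aligned, fitted):
        trials, cells, split, model = fitted
        base = trials[trials["correct"] & trials["cycle"].isin([1, 4])]
        rates = sel.rate_table(aligned, trials, cells, model.window,
                               trial_uids=base["trial_uid"])
        rates = sel.with_factors(rates, trials)
        rates = sel.restrict_to_half(rates, split, "train")
        m1 = rates[rates["cycle"] == 1].groupby("cell_id")["rate"].mean()
        m4 = rates[rates["cycle"] == 4].groupby("cell_id")["rate"].mean()
        p1, p4 = popm.project(model, m1), popm.project(model, m4)
        assert p4 > 0
        assert p1 == pytest.approx(-p4, rel=1e-9)

    def test_antisymmetric_in_cycle_labels(self, dataset, aligned, fitted):
        trials, cells, split, model = fitted
        swapped = trials.copy()
        swapped["cycle"] = swapped["cycle"].map({1: 4, 4: 1, 2: 2, 3: 3})
        model2 = popm.fit_discriminant(swapped, aligned, cells, split, "CH")
        pd.testing.assert_series_equal(model2.weights, -model.weights)

    def test_projection_mixture_linearity(self, fitted):
        _, _, _, model = fitted
        rng = np.random.default_rng(5)
        a = pd.Series(rng.normal(10, 2, len(model.cell_ids)),
                      index=model.cell_ids)
        b = pd.Series(rng.normal(6, 2, len(model.cell_ids)),
                      index=model.cell_ids)
        mid = (a + b) / 2
        assert popm.project(model, mid) == pytest.approx(
            (popm.project(model, a) + popm.project(model, b)) / 2)


class TestPermutationTest:
    def _rates(self, cells, rng, mean, n=30):
        rows = []
        for c in cells:
            for i in range(n):
                rows.append({"cell_id": c, "trial_uid": i,
                             "rate": rng.poisson(mean) / 0.4})
        return pd.DataFrame(rows)

    def _model(self, cells):
        idx = pd.Index(cells, name="cell_id")
        return popm.DiscriminantModel(
            phase="CH", window=sel.analysis_window("CH"),
            center=pd.Series(20.0, index=idx), scale=pd.Series(5.0, index=idx),
            weights=pd.Series(1.0, index=idx))

    def test_identical_conditions_give_p_one(self):
        rng = np.random.default_rng(1)
        cells = [f"C{i}" for i in range(5)]
        a = self._rates(cells, rng, 8)
        model = self._model(cells)
        res = popm.permutation_test(a, a.copy(), model, n=200, seed=2)
        assert res["p"] == 1.0

    def test_strong_separation_hits_floor(self):
        rng = np.random.default_rng(2)
        cells = [f"C{i}" for i in range(5)]
        a = self._rates(cells, rng, 30)
        b = self._rates(cells, rng, 2)
        model = self._model(cells)
        res = popm.permutation_test(a, b, model, n=200, seed=3)
        assert res["p"] == pytest.approx(1 / 201)

    def test_p_never_zero_and_empty_condition_errors(self):
        rng = np.random.default_rng(3)
        cells = [f"C{i}" for i in range(3)]
        a = self._rates(cells, rng, 5)
        model = self._model(cells)
        with pytest.raises(ValueError):
            popm.permutation_test(a, a.iloc[:0], model, n=100, seed=1)
        res = popm.permutation_test(a, self._rates(cells, rng, 5), model,
                                    n=100, seed=1)
        assert res["p"] > 0


class TestDiscriminantAnalysis:
    def test_binary_switch_projection_ordering(self):
        """C2/C3 cluster with C4; failed-learning trials fall between
        C1 and regular C2."""
        agent = sim.AgentConfig(p_learn_one_shot=0.7, p_revisit_lapse=0.1,
                                p_exploit_error_by_cycle={2: 0.0, 3: 0.0, 4: 0.0},
                                p_no_response=0.0, p_abort=0.0)
        pop = sim.PopulationConfig(n_cells=48, state_gain=2.0)
        trials, spikes, cells, _ = sim.simulate_dataset(
            n_sessions=2, n_problems=60, agent=agent, pop=pop, seed=71)
        aligned = sel.align_spikes(spikes, trials)
        res = popm.discriminant_analysis(trials, aligned, cells, "CH",
                                         seed=5, n_permutations=199)
        pr = res.projections
        assert pr["C1_test"] < 0 < pr["C4_test"]
        assert abs(pr["C2"] - pr["C4_test"]) < abs(pr["C2"] - pr["C1_test"])
        assert abs(pr["C3"] - pr["C4_test"]) < abs(pr["C3"] - pr["C1_test"])
        assert pr["C1_test"] < pr["C2_failed"] < pr["C2"]
        assert res.permutation_p[("C1_test", "C4_test")]["p"] == \
            pytest.approx(1 / 200)
        assert res.permutation_p[("C1_test", "C2")]["p"] < 0.05
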