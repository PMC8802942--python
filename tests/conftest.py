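"""Shared fixtures: one mid-sized simulated dataset reused across tests."""

from __future__ import annotations

import pytest

from explorexploit import selection as sel
from explorexploit import simulate as sim


@pytest.fixture(scope="session")
def dataset():
    """Two sessions, 40 problems each, 48 cells with clear state gain."""
    pop = sim.PopulationConfig(n_cells=48, state_gain=2.0,
                               fraction_outcome_cells=0.15)
    trials, spikes, cells, truth = sim.simulate_dataset(
        n_sessions=2, n_problems=40, pop=pop, seed=1234)
    return {"trials": trials, "spikes": spikes, "cells": cells, "truth": truth}


@pytest.fixture(scope="session")
def aligned(dataset):
    return sel.align_spikes(dataset["spikes"], dataset["trials"])


@pytest.fixture(scope="session")
def split(dataset):
    return sel.split_trials(dataset["trials"], dataset["cells"], seed=7)


@pytest.fixture(scope="session")
def selection_results(dataset, aligned, split):
    return sel.select_cells(dataset["trials"], aligned, dataset["cells"], split)


@pytest.fixture(scope="session")
def norms(dataset, aligned, split):
    return sel.cell_norms(dataset["trials"], aligned, dataset["cells"], split)
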