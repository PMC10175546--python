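"""Shared fixtures: ground-truth models and replicate fit ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from palspheroid import (
    SimulationConfig,
    fit_spectrum,
    melanoma_condition_model,
    simulate_histogram,
)


@pytest.fixture(scope="session")
def wm266_day4_model():
    return melanoma_condition_model("WM266-4", 4)


@pytest.fixture(scope="session")
def wm266_day4_replicate_fits(wm266_day4_model):
    """Twenty independent million-event simulate-and-fit replicates of the
    WM266-4 day-4 condition; shared by the recovery, coverage and
    uncertainty-scale checks."""
    results = []
    for seed in range(1, 21):
        hist = simulate_histogram(SimulationConfig(model=wm266_day4_model, seed=seed))
        results.append(fit_spectrum(hist))
    return results


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
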