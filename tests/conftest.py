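"""Shared fixtures: ground-truth tables and session-scoped simulated datasets."""

from __future__ import annotations

import pytest
from hypothesis import settings

import pamkin as pk
from pamkin.kinetics import efficiency_table, normalize_activity
from pamkin.rates import extract_rates
from pamkin.simulate import (
    NoiseModel,
    custom_chip_design,
    custom_chip_layout,
    screen_efficiencies,
    screening_design,
    screening_layout,
    simulate_experiment,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: Low noise level used for perfect-recovery screening checks.
LOW_NOISE = NoiseModel(sigma_add=1.0, sigma_prop=0.01, bg_mean=50.0, bg_sd=10.0)


@pytest.fixture(scope="session")
def profiles():
    return pk.load_constructs()


@pytest.fixture(scope="session")
def table2():
    return pk.load_table2()


@pytest.fixture(scope="session")
def screen_truth():
    return pk.load_table1()


@pytest.fixture(scope="session")
def chip_noiseless(profiles):
    """Zero-noise 24-peptide efficiency experiment for all four constructs."""
    design = custom_chip_design(profiles, pk.CONSTRUCTS)
    data, config = simulate_experiment(
        design, custom_chip_layout(), profiles, NoiseModel.noiseless(), master_seed=1
    )
    return data, config


@pytest.fixture(scope="session")
def chip_rates_noiseless(chip_noiseless):
    data, config = chip_noiseless
    return extract_rates(data), config


@pytest.fixture(scope="session")
def chip_efficiencies_noiseless(chip_rates_noiseless):
    """End-to-end recovered efficiencies, calibrated to the reference spot."""
    rates, config = chip_rates_noiseless
    normalized = normalize_activity(rates, reference_value=config["reference_values"])
    return efficiency_table(normalized)


@pytest.fixture(scope="session")
def screen_dataset(profiles, screen_truth):
    """Low-noise 144-spot screen for the three JAK2 constructs, seed 42."""
    effs = screen_efficiencies(screen_truth)
    design = []
    for cid in ("JAK2_JH1", "JAK2_JH1JH2_WT", "JAK2_JH1JH2_V617F"):
        design += screening_design(cid, profiles[cid].pmol_per_reaction)
    data, config = simulate_experiment(
        design, screening_layout(), profiles, LOW_NOISE, master_seed=42, efficiencies=effs
    )
    return data, config
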