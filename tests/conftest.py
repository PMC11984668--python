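"""Shared fixtures: small synthetic cohorts with known ground truth."""

from __future__ import annotations

import warnings

import pytest

from epiconcord.synthetic import SimConfig, generate_clock_definitions, generate_cohort

warnings.filterwarnings("ignore", message="reference-free fit")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale noisy cohort with batches and both probe types."""
    return SimConfig(
        n_children=6,
        n_adults=8,
        n_probes=800,
        n_age_probes=100,
        n_control_probes=60,
        noise_sd=0.05,
        n_batches=2,
        batch_sd=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    return SimConfig(
        n_children=6,
        n_adults=8,
        n_probes=600,
        n_age_probes=80,
        n_control_probes=40,
        noise_sd=0.0,
        batch_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_clocks(noiseless_config, noiseless_cohort):
    _, _, _, truth = noiseless_cohort
    return generate_clock_definitions(noiseless_config, truth)
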