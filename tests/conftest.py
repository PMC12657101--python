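"""Shared fixtures: one synthetic study fit and one reference simulation."""

import warnings

import numpy as np
import pytest

from lipidstore import bayes_model, reference_body, synthetic_data
from lipidstore.densitometry import Constants


@pytest.fixture(scope="session")
def constants():
    return Constants()


@pytest.fixture(scope="session")
def study_obs():
    """Default-condition synthetic study: truths plus observation tables."""
    cfg = synthetic_data.SimulationConfig(seed=42)
    truths = synthetic_data.simulate_truths(cfg)
    obs = synthetic_data.simulate_observations(truths, cfg)
    return cfg, truths, obs


@pytest.fixture(scope="session")
def study_fit(study_obs):
    """Scaled-down MCMC fit of the default synthetic study (shared)."""
    _, truths, obs = study_obs
    mcfg = bayes_model.ModelConfig(iterations=4000, thin=2, seed=43)
    model = bayes_model.build_model(obs, mcfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples, diag = bayes_model.fit(model)
    return truths, obs, model, samples, diag


@pytest.fixture(scope="session")
def ref_draws(constants):
    """Packaged-default reference-body simulation at acceptance scale."""
    params = reference_body.default_compartment_table()
    return reference_body.draw_reference_bodies(
        params, constants, n=100_000, length_range=(8.0, 17.0), seed=7
    )
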