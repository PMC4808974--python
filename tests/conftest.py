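"""Shared fixtures: one medium synthetic study region reused across tests."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from greenbirth import inference
from greenbirth.covariates import build_covariate_panel
from greenbirth.exposure import RasterStack, assign_exposure
from greenbirth.outcomes import (apply_exclusions, build_growth_reference,
                                 classify_outcomes)
from greenbirth.synthetic_data import (SimConfig, simulate_cohort,
                                       simulate_point_layers, simulate_raster)


@pytest.fixture(scope="session")
def medium_config() -> SimConfig:
    return SimConfig(
        seed=42,
        n_births={"city": 2000, "borough": 2000, "township": 3000},
        n_communities={"city": 10, "borough": 10, "township": 12},
    )


@pytest.fixture(scope="session")
def medium_raster(medium_config):
    return simulate_raster(medium_config)


@pytest.fixture(scope="session")
def medium_cohort(medium_config, medium_raster):
    return simulate_cohort(medium_config, medium_raster)


@pytest.fixture(scope="session")
def medium_frame(medium_config, medium_raster, medium_cohort):
    cohort, _truth = medium_cohort
    included, _ = apply_exclusions(cohort)
    expo = assign_exposure(included, medium_raster, 250.0, "mean")
    layers = simulate_point_layers(medium_config)
    panel = build_covariate_panel(included, layers["layout"], layers)
    reference = build_growth_reference(included)
    out = classify_outcomes(included, reference)
    return inference.build_model_frame(included, panel, expo, out)


@pytest.fixture()
def constant_raster():
    """Flat NDVI = 0.5, 10x10 grid at 250 m, six composites."""
    dates = [date(2008, m, 1) for m in range(1, 7)]
    values = np.full((6, 10, 10), 0.5)
    return RasterStack(values, 0.0, 0.0, 250.0, dates)
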