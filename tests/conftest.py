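"""Shared fixtures: deterministic parameter sets and small PSA bundles."""

from __future__ import annotations

import copy

import numpy as np
import pytest
from hypothesis import settings

from quitcost.params import DISEASE_IDS, STRATUM_KEYS, ParameterSet
from quitcost.synthetic import generate_default_parameters

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_ps() -> ParameterSet:
    return generate_default_parameters()


def make_toy_ps(
    *,
    zero_disease: bool = True,
    zero_mortality: bool = True,
    unit_utility: bool = True,
    zero_discount: bool = True,
    zero_relapse: bool = True,
    zero_adverse_events: bool = True,
    zero_course_costs: bool = True,
    single_stratum: str | None = "male_35_64",
) -> ParameterSet:
    """A stripped-down parameter set for analytic limit checks."""
    ps = copy.deepcopy(generate_default_parameters())
    if zero_disease:
        for d in ps.diseases.values():
            for k in STRATUM_KEYS:
                d.incidence[k] = 0.0
                d.prevalence[k] = 0.0
                d.excess_mortality[k] = 0.0
    if zero_mortality:
        for s in ps.strata:
            s.all_cause_mortality = 0.0
    if unit_utility:
        ps.economics.baseline_utility = {k: 1.0 for k in STRATUM_KEYS}
        for d in ps.diseases.values():
            d.utility_value = 1.0
    if zero_discount:
        ps.economics.discount_rate = 0.0
    if zero_relapse:
        ps.relapse.p_relapse_short = 0.0
        ps.relapse.p_relapse_long = 0.0
        ps.relapse.p_relapse_10plus = 0.0
    if zero_adverse_events:
        ae = ps.adverse_events
        ae.disutility_depression = ae.disutility_selfharm = 0.0
        ae.cost_depression = ae.cost_selfharm = 0.0
        ae.fatal_fraction_selfharm = 0.0
    if zero_course_costs:
        ps.course_costs = {k: 0.0 for k in ps.course_costs}
    if single_stratum is not None:
        for s in ps.strata:
            s.cohort_share = 1.0 if s.key == single_stratum else 0.0
    return ps


@pytest.fixture()
def toy_ps() -> ParameterSet:
    return make_toy_ps()


@pytest.fixture(scope="session")
def small_bundle():
    """A 200-draw licensed-only pipeline run shared across analysis tests."""
    from quitcost.pipeline import RunConfig, run_pipeline

    return run_pipeline(RunConfig(scenario="base", seed=11, psa_draws=200))
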