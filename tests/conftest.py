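import numpy as np
import pytest

import routetrend as rt


@pytest.fixture(scope="session")
def small_design():
    return rt.SurveyDesign(n_pairs=2, n_points=5, years=tuple(range(2010, 2015)))


@pytest.fixture(scope="session")
def small_survey(small_design):
    """A small zip survey with realized truth, shared across tests."""
    truth = rt.TruthRecord(family="zip", seed=42, missing_before=2012)
    counts, cov, truth = rt.generate_survey(small_design, truth)
    return counts, cov, truth


@pytest.fixture(scope="session")
def small_table(small_survey, small_design):
    counts, cov, _ = small_survey
    cov = rt.extrapolate_grass(cov, list(small_design.years))
    return rt.build_design_table(counts, cov)


@pytest.fixture(scope="session")
def small_fit(small_table):
    """A quick zip fit reused by trend/summary tests (mixing quality not asserted)."""
    spec = rt.ModelSpec(family="zip")
    cfg = rt.SamplerConfig(n_chains=2, burn_in=400, thin=2, saved_total=300, seed=7)
    draws, report = rt.run_sampler(small_table, spec, cfg)
    return draws, report
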