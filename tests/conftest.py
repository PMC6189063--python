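"""Shared fixtures: seeded synthetic datasets and fitted models.

Session-scoped so the expensive simulate-and-fit steps run once per test
session; individual tests must not mutate them.
"""

import numpy as np
import pytest

from fdamort.basis import Interval, make_basis
from fdamort.fflm import default_mortality_basis, fit_fflm, log_rate_curves
from fdamort.sflm import fit_sflm
from fdamort.synthetic import Scenario, make_fflm_dataset, make_sflm_dataset


@pytest.fixture(scope="session")
def summer_data():
    """Five synthetic summers (2007-2011 layout) with the reference intraday effect."""
    return make_sflm_dataset(Scenario(seed=1, mode="sflm", n_years=5))


@pytest.fixture(scope="session")
def summer_fit(summer_data):
    return fit_sflm(summer_data.counts, summer_data.exposures)


@pytest.fixture(scope="session")
def annual_data():
    """31 synthetic years with the reference season-varying cold surface."""
    return make_fflm_dataset(Scenario(seed=1, mode="fflm", n_years=31))


@pytest.fixture(scope="session")
def annual_fit(annual_data):
    mort = log_rate_curves(annual_data.counts_by_year, default_mortality_basis())
    return fit_fflm(mort, annual_data.temperature_sample)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(
    params=[(0.0, 1.0, 0, 1), (0.0, 24.0, 8, 4), (0.0, 365.0, 5, 4),
            (-3.0, 7.0, 3, 2), (0.0, 10.0, 12, 3)],
    ids=["const", "daily-cubic", "annual-cubic", "quadratic", "dense-linear"],
)
def any_basis(request):
    lo, hi, n_knots, order = request.param
    return make_basis(Interval(lo, hi), n_knots, order)
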