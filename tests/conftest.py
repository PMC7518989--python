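import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from heatsd import (
    AdaptationParameters,
    CityProfile,
    DailyClimateRecord,
    ExposureParameters,
    FixtureSpec,
    ModelParameters,
    TableFunction,
    TemperatureSeries,
    default_parameters,
    gen_city_profile,
    gen_heatwave_series,
)


def make_series(tmaxes, start=dt.date(2013, 7, 1)):
    """Series with the given daily maxima, consecutive dates."""
    return TemperatureSeries(
        DailyClimateRecord(date=start + dt.timedelta(days=i), tmax=float(t))
        for i, t in enumerate(tmaxes)
    )


@pytest.fixture(scope="session")
def profile_2013():
    return gen_city_profile("y2013")


@pytest.fixture(scope="session")
def hw2013_series():
    return gen_heatwave_series(FixtureSpec.hw2013())


@pytest.fixture(scope="session")
def hw2003_series():
    return gen_heatwave_series(FixtureSpec.hw2003())


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture
def neutral_params(profile_2013):
    """All amplification off: neutral tables, unit factors at reference."""
    return ModelParameters(
        exposure=ExposureParameters(beta_morb=5.0, r_base=10.0, mu=0.05),
        adaptation=AdaptationParameters(reference_profile=profile_2013, af0=0.3),
        ma_table=TableFunction([(0.0, 1.0), (50.0, 1.0)]),
        hdaf_table=TableFunction([(0.0, 1.0), (50.0, 1.0)]),
        background_rate=114.0,
    )


def random_params(rng, profile):
    """A random admissible parameter draw for property tests."""
    ma = TableFunction(
        [(35.0, 1.0), (37.6, 1.0)]
        + [(37.6 + 1.5 * (i + 1), 1.0 + float(rng.uniform(0, 0.5)) * (i + 1))
           for i in range(3)]
    )
    hdaf = TableFunction(
        [(0.0, 1.0), (1.0, 1.0), (5.0, 1.0 + float(rng.uniform(0, 0.5))),
         (15.0, 1.5 + float(rng.uniform(0, 1.0)))]
    )
    return ModelParameters(
        exposure=ExposureParameters(
            beta_morb=float(rng.uniform(0, 40)),
            r_base=float(rng.uniform(0, 40)),
            mu=float(rng.uniform(0.01, 0.3)),
        ),
        adaptation=AdaptationParameters(
            reference_profile=profile,
            af0=float(rng.uniform(0.05, 0.7)),
        ),
        ma_table=ma,
        hdaf_table=hdaf,
        background_rate=float(rng.uniform(50, 150)),
        bed_capacity=float(rng.uniform(1e-3, 1e-2)),
        allowance_elasticity=float(rng.uniform(0.0, 4.0)),
    )
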