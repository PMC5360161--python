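import math

import numpy as np
import pytest

from adctrack import (
    CompartmentSpec,
    HistogramSummary,
    LongitudinalSeries,
    PhantomSpec,
    TimePoint,
    TrajectorySpec,
    generate_phantom,
)

VIABLE_MEDIAN = 1.19e-3


@pytest.fixture(scope="session")
def constant_noiseless_spec():
    """Single constant-ADC viable compartment, no noise, no cystic part."""
    return PhantomSpec(
        grid_shape=(24, 24, 10),
        noise_sigma=0.0,
        compartments=(
            CompartmentSpec(
                "viable",
                center=(12.0, 12.0, 5.0),
                semi_axes=(7.0, 7.0, 3.0),
                family="constant",
                median_adc=VIABLE_MEDIAN,
            ),
        ),
        trajectory=TrajectorySpec(
            weeks=(0, 1),
            adc_median_multipliers=(1.0, 1.14),
            volume_multipliers=(1.0, 0.92),
            cystic_schedule=(0.0, 0.0),
        ),
        seed=0,
    )


@pytest.fixture(scope="session")
def constant_noiseless_output(constant_noiseless_spec):
    return generate_phantom(constant_noiseless_spec)


@pytest.fixture(scope="session")
def default_output():
    """Default two-compartment phantom with mild noise (shared, read-only)."""
    return generate_phantom(PhantomSpec(noise_sigma=10.0, seed=7))


def summary_with_median(median, **overrides):
    """Minimal HistogramSummary for longitudinal tests driven by medians."""
    fields = dict(
        n_voxels=100,
        mean=median,
        median=median,
        sd=0.1 * median,
        p10=0.8 * median,
        p25=0.9 * median,
        p75=1.1 * median,
        p90=1.2 * median,
        skewness=0.3,
        kurtosis=0.1,
        volume_cm3=math.nan,
    )
    fields.update(overrides)
    return HistogramSummary(**fields)


def make_series(medians, volumes=None, gtv_id="g1"):
    """Series from {week: median_adc}; volumes optional {week: cm3}."""
    volumes = volumes or {}
    tps = [
        TimePoint(
            week=w,
            adc_summary=summary_with_median(m),
            gtv_volume_cm3=volumes.get(w, 10.0),
        )
        for w, m in sorted(medians.items())
    ]
    return LongitudinalSeries(gtv_id=gtv_id, timepoints=tps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
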