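import numpy as np
import pytest

from deukin import EnrichmentSchedule, ESFractionParams

# the eight reference parameter sets: (d1, d2, p2, k) with the analytic
# gain/loss approximations and, where the constant-rate model describes
# the curve, the fitted (p*, d*); None marks a lack-of-fit case
REFERENCE_CASES = [
    dict(d1=0.5, d2=0.2, p2=0.1, k=1, p0=0.10, p1=0.13, dpost=-0.20, fit=(0.12, 0.04)),
    dict(d1=0.5, d2=0.2, p2=0.1, k=2, p0=0.15, p1=0.15, dpost=0.03, fit=(0.16, 0.13)),
    dict(d1=0.5, d2=0.2, p2=0.0, k=1, p0=0.00, p1=0.08, dpost=-1.00, fit=None),
    dict(d1=0.5, d2=0.2, p2=0.0, k=2, p0=0.10, p1=0.13, dpost=-0.20, fit=(0.12, 0.04)),
    dict(d1=0.2, d2=0.5, p2=0.25, k=1, p0=0.25, p1=0.20, dpost=0.25, fit=(0.24, 0.27)),
    dict(d1=0.2, d2=0.5, p2=0.25, k=2, p0=0.38, p1=0.27, dpost=0.41, fit=(0.37, 0.40)),
    dict(d1=0.2, d2=0.5, p2=0.0, k=1, p0=0.00, p1=0.07, dpost=-1.00, fit=None),
    dict(d1=0.2, d2=0.5, p2=0.0, k=2, p0=0.25, p1=0.20, dpost=0.25, fit=(0.24, 0.27)),
]


@pytest.fixture(scope="session")
def step_schedule():
    return EnrichmentSchedule(shape="step", tau=1.0)


@pytest.fixture(scope="session")
def body_water_schedule():
    # body-water curve of the worked case study: plateau 3.1% enrichment,
    # 0.032/day water turnover, 0.23% baseline
    return EnrichmentSchedule(
        shape="body_water", tau=1.0, f=0.031, delta=0.032, beta0=0.0023,
        normalize=False,
    )


def random_es_params(rng, k=None, lo=0.05, hi=0.95):
    """One random ES parameter set in the slow-turnover regime."""
    return ESFractionParams(
        d1=rng.uniform(lo, hi),
        p2=rng.uniform(0.0, 0.95) * (d2 := rng.uniform(lo, hi)),
        d2=d2,
        k=int(rng.integers(1, 3)) if k is None else k,
    )
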