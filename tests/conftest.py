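import numpy as np
import pytest

from ctcflow import EventSeries, SimConfig, simulate_homogeneous_poisson
from ctcflow.simulate import BurstParams, CircadianParams


@pytest.fixture
def poisson_series() -> EventSeries:
    """One seeded homogeneous Poisson session at the reference intensity."""
    return simulate_homogeneous_poisson(SimConfig(rate_per_s=0.05, session_length_s=3000, seed=11))


@pytest.fixture
def burst_params() -> BurstParams:
    return BurstParams(cluster_rate_per_s=0.005, mean_events_per_cluster=5.0,
                       intra_cluster_scale_s=2.0)


@pytest.fixture
def circadian_params() -> CircadianParams:
    """Reference circadian generator: mesor 0.04/s, amplitude 0.03/s, peak ZT13."""
    return CircadianParams(mesor_rate=0.04, amplitude_rate=0.03, acrophase_h=13.0)
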