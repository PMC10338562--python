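import numpy as np
import pytest

from smo.kinetics import KineticsParams, simulate
from smo.preprocessing import PhysioSeries, moving_average
from smo.protocol import validation_protocol
from smo.synthetic import CohortRanges, generate_test, sample_cohort


@pytest.fixture(scope="session")
def hr_params():
    return KineticsParams(K=0.4, tau=40.0, X0=70.0, variable="HR")


@pytest.fixture(scope="session")
def vo2_params():
    return KineticsParams(K=0.010, tau=35.0, X0=0.35, variable="VO2")


@pytest.fixture(scope="session")
def submax_protocol():
    """Validation-style protocol with the ramp cut after 7 minutes."""
    return validation_protocol().truncate_ramp(t_cut=900.0,
                                               recovery_duration_s=300.0)


@pytest.fixture(scope="session")
def clean_hr_series(hr_params, submax_protocol):
    """Noise-free 1 Hz HR trajectory of the first-order model."""
    t = np.arange(0.0, submax_protocol.end_s)
    sim = simulate(hr_params, submax_protocol, None, t)
    return PhysioSeries(t, sim.values, "HR").label_phases(submax_protocol)


@pytest.fixture(scope="session")
def clean_vo2_series(vo2_params, submax_protocol):
    t = np.arange(0.0, submax_protocol.end_s)
    sim = simulate(vo2_params, submax_protocol, None, t)
    return PhysioSeries(t, sim.values, "VO2").label_phases(submax_protocol)


@pytest.fixture(scope="session")
def noisefree_truth():
    """A synthetic subject whose true HRmax equals the Whyte estimate."""
    ranges = CohortRanges(noise_sd_hr=0.0, noise_sd_vo2=0.0,
                          hrmax_offset_sd=0.0)
    return sample_cohort(1, seed=42, ranges=ranges)[0]


@pytest.fixture(scope="session")
def noisefree_submax_test(noisefree_truth):
    hr, vo2, prot = generate_test(noisefree_truth, mode="submaximal_80",
                                  seed=1)
    return moving_average(hr, 15), moving_average(vo2, 15), prot
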