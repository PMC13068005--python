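import numpy as np
import pytest

from sddetwin import build_cohort, default_parameters
from sddetwin.inflammation_models import CascadeParameters, StressorSpec
from sddetwin.sdde_core import TimeGrid


@pytest.fixture(scope="session")
def reference_params():
    return default_parameters("reference")


@pytest.fixture(scope="session")
def default_cohort(reference_params):
    """The shipped default experiment: 100 subjects, 20% prevalence, seed 0."""
    return build_cohort(reference_params, 100, 0.20, master_seed=0,
                        preset_name="reference")


@pytest.fixture
def small_grid():
    return TimeGrid(t0=0.0, t_end=2.0, dt=0.01)


@pytest.fixture
def quiet_params(reference_params):
    """Reference cascade with all noise off (deterministic runs)."""
    return reference_params.with_updates(sigma1=0.0, sigma2=0.0,
                                         sigma3=0.0, sigma4=0.0)


@pytest.fixture
def tiny_cascade():
    """A small, fast cascade on a short grid for structural tests."""
    return CascadeParameters(
        alpha1=1.0, alpha2=0.5, gamma1=0.5, gamma2=0.3,
        theta1=0.5, theta2=0.05, theta3=0.1,
        beta1=0.5, beta2=0.05, beta3=0.1,
        sigma1=0.1, sigma2=0.1, sigma3=0.05, sigma4=0.1,
        tau1=0.5, tau2=0.5, tau3=1.0, tau4=1.0, tau5=2.0, tau6=2.0,
        tau7=1.0, tau8=1.0, tau9=1.0,
        baseline_b1=0.1, baseline_b2=0.1, baseline_b3=5.0, baseline_y=0.1,
        stressor=StressorSpec(amplitude=1.0, onset=2.0, duration=5.0),
        grid=TimeGrid(t0=0.0, t_end=30.0, dt=0.01),
    )


def metrics_arrays(cohort):
    tpk = np.array([m.time_to_peak_y for m in cohort.metrics])
    my = np.array([m.max_y for m in cohort.metrics])
    ev = np.array([m.event_cv for m in cohort.metrics])
    return my, tpk, ev
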