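import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gdnca.simulate import ConcentrationTimeProfile


def make_profile(times, concs, dose=30.0, blq=None, subject_id="s1", group="control"):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = np.zeros(len(times), dtype=bool)
    return ConcentrationTimeProfile(
        subject_id=subject_id,
        group=group,
        dose=dose,
        body_weight=300.0,
        times=times,
        concentrations=concs,
        blq_flags=np.asarray(blq, dtype=bool),
    )


def mono_profile(c0, lam, times, dose=30.0):
    """Exact mono-exponential profile C(t) = c0·exp(-lam·t)."""
    times = np.asarray(times, dtype=float)
    return make_profile(times, c0 * np.exp(-lam * times), dose=dose)


def dense_log_times(lam_fast, lam_slow, n=6000, n_halves=25.0):
    """Geometric grid from deep inside the fast phase to n_halves/λ_slow."""
    return np.geomspace(1e-4 / lam_fast, n_halves / lam_slow, n)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def mono_factory():
    return mono_profile
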