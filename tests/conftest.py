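import numpy as np
import pytest

import quantpk as q

PAPER_TIMES = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 5.0, 12.0, 24.0, 48.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paper_times():
    return PAPER_TIMES.copy()


@pytest.fixture
def dsv_params():
    return q.PKParams(ka=0.6, ke=0.0385, V_F=290_000.0, dose=50e6)


@pytest.fixture
def tam_params():
    return q.PKParams(ka=2.0, ke=0.0433, V_F=30_000.0, dose=10e6,
                      fm=0.3, kem=0.5, Vm_F=640.0)


def profile_from_arrays(times, concs, blq=None, analyte="TAM", dose=10e6,
                        subject="s1", group="II"):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = np.zeros_like(times, dtype=bool)
    return q.ConcentrationTimeProfile(
        subject_id=subject, group=group, analyte=analyte,
        times=times, concs=concs, blq=np.asarray(blq, dtype=bool), dose=dose)


@pytest.fixture
def make_profile():
    return profile_from_arrays


def noise_free_profile(params, times, analyte="TAM", metabolite=False, **kw):
    f = q.simulate_metabolite if metabolite else q.simulate_parent
    concs = f(params, times)
    blq = concs <= 0
    return profile_from_arrays(times, np.where(blq, 0.0, concs), blq,
                               analyte=analyte, dose=params.dose, **kw)


@pytest.fixture
def make_noise_free_profile():
    return noise_free_profile
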