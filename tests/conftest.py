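import numpy as np
import pytest

from lymphoslope.cohort import ALCMeasurement, ALCSeries


def make_series(days, values, patient_id="p"):
    return ALCSeries(
        patient_id=patient_id,
        measurements=tuple(
            ALCMeasurement(day=int(d), value=float(v)) for d, v in zip(days, values)
        ),
    )


def decay_series(alpha, a1, e1, days, patient_id="p"):
    days = np.asarray(days)
    return make_series(days, a1 * np.exp(-alpha * days) + e1, patient_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    from lymphoslope.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(n_patients=30, seed=11, n_genes=0))
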