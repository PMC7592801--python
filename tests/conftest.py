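import numpy as np
import pytest
from hypothesis import settings

from gaitmet import musclemodel, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Desk-scale sampling rate used throughout the suite; the generator default
#: is 2000 Hz but every operation is rate-agnostic.
FS = 200.0


@pytest.fixture(scope="session")
def model():
    params, geometry, curves = musclemodel.load_default_model()
    return {"params": params, "geometry": geometry, "curves": curves}


@pytest.fixture(scope="session")
def participant():
    return synthetic.ParticipantSpec(id="T1")


@pytest.fixture(scope="session")
def level_trial(participant):
    """Noise-free baseline trial at desk scale."""
    return synthetic.generate_trial(participant, synthetic.ConditionSpec(),
                                    n_strides=4, noise_sd=0.0, seed=11,
                                    sampling_rate=FS)


@pytest.fixture(scope="session")
def truth_setup(model, participant):
    """Truth-known trial plus its reference moments (known calibration optimum)."""
    trial, reference = synthetic.generate_truth_trial(
        model["params"], participant, seed=3, geometry=model["geometry"],
        n_strides=2, sampling_rate=FS)
    return {"trial": trial, "reference": reference, **model}


@pytest.fixture(scope="session")
def simulated_states(model, level_trial):
    states, moments, per_kg = musclemodel.simulate_trial(
        level_trial, model["params"], model["geometry"], curves=model["curves"])
    return {"states": states, "moments": moments, "per_kg": per_kg}
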