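import numpy as np
import pytest

from reachfield.synthetic_data import EPOCHS, GroundTruthNeuron
from reachfield.task_geometry import make_task1, make_task2


@pytest.fixture(scope="session")
def task1_config():
    return make_task1(2.5, 7.0)


@pytest.fixture(scope="session")
def task2_config():
    return make_task2()


@pytest.fixture(scope="session")
def task2_radial():
    # unstaggered variant: directions repeat exactly across rings
    return make_task2(radial_offset=0.0)


def neuron(neuron_id=0, model_id="untuned", params=(), baseline=5.0, gain=20.0):
    """Shorthand ground-truth neuron with equal epoch gains."""
    g = 0.0 if model_id == "untuned" else float(gain)
    return GroundTruthNeuron(
        neuron_id=neuron_id,
        model_id=model_id,
        true_params=np.asarray(params, dtype=float),
        baseline_rate=baseline,
        epoch_gains={e: g for e in EPOCHS},
        task_related=model_id != "untuned",
    )


@pytest.fixture
def make_neuron():
    return neuron
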