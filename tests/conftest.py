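import numpy as np
import pytest

from cstkit import ShieldingTensor
from cstkit.synthetic import (
    ObservationSpec,
    TensorGeneratorSpec,
    generate_rcsa_observations,
    generate_reference_tensors,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_tensor(rng):
    return ShieldingTensor("mol", "C1", rng.normal(scale=50.0, size=(3, 3)))


@pytest.fixture
def reference_set():
    return generate_reference_tensors(TensorGeneratorSpec(n_nuclei=10, seed=7))


@pytest.fixture
def noiseless_problem(reference_set):
    """(tensors, dataset, true Saupe matrix) with zero observation noise."""
    dataset, truth = generate_rcsa_observations(
        reference_set, ObservationSpec(noise_sd=0.0), seed=11
    )
    return reference_set, dataset, truth
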