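import numpy as np
import pytest

from kincal import (
    ObjectiveSpec,
    OdeModel,
    Species,
    build_toy_cascade,
    generate_dataset,
    parse_reaction,
    toy_parameter_space,
)
from kincal.synthetic import ToyCascadeSpec


@pytest.fixture(scope="session")
def cascade():
    """The certified toy snap-action cascade at ground truth."""
    return build_toy_cascade()


@pytest.fixture(scope="session")
def cascade_spec():
    return ToyCascadeSpec()


@pytest.fixture(scope="session")
def cascade_space(cascade):
    return toy_parameter_space(cascade)


@pytest.fixture(scope="session")
def reporter_grid(cascade_spec):
    """3-minute reporter sampling grid over the full horizon."""
    return cascade_spec.grid()


@pytest.fixture(scope="session")
def clean_synth(cascade):
    """Noise-free three-dose dataset generated at ground truth."""
    return generate_dataset(cascade, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_synth(cascade):
    return generate_dataset(cascade, noise_sd=0.02, seed=7)


@pytest.fixture(scope="session")
def decay_model():
    """Pure first-order decay A -> 0, k = 0.1/min, [A]0 = 1."""
    return OdeModel(
        species=(Species("A", 1.0),),
        reactions=(parse_reaction("A -> 0 @ k"),),
        parameters={"k": 0.1},
        observables={"amount": "A"},
    )


@pytest.fixture(scope="session")
def conversion_model():
    """Reversible A <-> B for closed-form comparisons."""
    return OdeModel(
        species=(Species("A", 2.0), Species("B", 0.0)),
        reactions=(parse_reaction("A -> B @ kf"), parse_reaction("B -> A @ kr")),
        parameters={"kf": 0.3, "kr": 0.1},
        pools={"total": ("A", "B")},
    )
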