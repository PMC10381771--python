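import numpy as np
import pandas as pd
import pytest

from emometrics import (
    GradedMatrix,
    ItemBank,
    ItemKey,
    StimulusRecord,
    default_label_set,
)
from emometrics.grm import FitControls, GRMItemParams, default_quadrature
from emometrics import simulate as sim


@pytest.fixture(scope="session")
def labels():
    return default_label_set()


@pytest.fixture()
def nonverbal_key():
    return ItemKey(
        item_id="NV001",
        correct=("fear",),
        partial=frozenset({"anxiety"}),
        incorrect=frozenset({"joy", "boredom", "pride", "awe"}),
        n_options=6,
    )


@pytest.fixture()
def concealed_key():
    return ItemKey(
        item_id="C001",
        correct=("anger", "content"),  # displayed anger, concealed content
        partial=frozenset(),
        incorrect=frozenset({"joy", "sadness", "fear", "awe"}),
        n_options=6,
    )


@pytest.fixture()
def small_bank(nonverbal_key, concealed_key):
    stimuli = {
        "NV001": StimulusRecord(
            stimulus_id="NV001", modality="nonverbal", target_emotion="fear",
            actor_race="asian", actor_gender="women",
        ),
        "C001": StimulusRecord(
            stimulus_id="C001", modality="concealed",
            displayed_emotion="anger", concealed_emotion="content",
            actor_race="black", actor_gender="men",
        ),
    }
    return ItemBank(stimuli=stimuli, keys={"NV001": nonverbal_key, "C001": concealed_key})


@pytest.fixture(scope="session")
def quad():
    return default_quadrature()


@pytest.fixture(scope="session")
def item3():
    """Symmetric 3-category item used in worked examples."""
    return GRMItemParams(item_id="x", a=2.0, b=np.array([-1.0, 1.0]), m=3)


@pytest.fixture(scope="session")
def small_controls():
    return FitControls(min_n=10)


@pytest.fixture(scope="session")
def fitted_toy(quad, small_controls):
    """A seeded 10-item / n=500 simulation plus its calibrated fit."""
    items = sim.simulate_item_params(10, 3, seed=3)
    rng = np.random.default_rng(1)
    theta = rng.normal(size=500)
    matrix = sim.simulate_graded_responses(
        theta, items, np.ones((500, 10), bool), 7
    )
    from emometrics.grm import fit_grm

    return items, matrix, fit_grm(matrix, quad, small_controls)
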