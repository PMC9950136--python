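import numpy as np
import pytest

from poptensor.bases import BasisSet
from poptensor.gmlm import GmlmModel
from poptensor.synthetic import TaskSchedule, sample_ground_truth, simulate_trials


@pytest.fixture(scope="session")
def default_bases():
    return BasisSet.default()


@pytest.fixture(scope="session")
def compact_schedule():
    return TaskSchedule().compact()


@pytest.fixture(scope="session")
def compact_bases(compact_schedule):
    return compact_schedule.default_bases()


@pytest.fixture(scope="session")
def small_population(compact_schedule):
    """Small mixed-tuning population with history, for likelihood tests."""
    truth = sample_ground_truth(
        "mixed", 4, 2, seed=7, schedule=compact_schedule, include_history=True
    )
    data = simulate_trials(truth, 6, seed=8)
    return truth, data


@pytest.fixture(scope="session")
def small_population_tbar():
    """Population with touch-bar releases (uniform reaction times)."""
    sched = TaskSchedule().compact()
    sched.touchbar_policy = "uniform"
    truth = sample_ground_truth(
        "mixed", 3, 1, seed=11, schedule=sched,
        include_history=True, include_tbar=True,
    )
    data = simulate_trials(truth, 4, seed=12)
    return truth, data


@pytest.fixture(scope="session")
def fitted_small_model(small_population):
    truth, data = small_population
    model = GmlmModel(
        truth.model.spec,
        truth.model.bases,
        n_neurons=4,
        rank=2,
        include_history=True,
        include_tbar=False,
        bin_width=data.bin_width,
    )
    design = model.build_design(data)
    rng = np.random.default_rng(0)
    params = model.init_params(rng, design)
    return model, design, params
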