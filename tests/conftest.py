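import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from thaali.nutrients import NUTRIENTS, FoodComposition
from thaali.records import PortionRecord, RecallVisit
from thaali.simulate import SimulationConfig, generate_fct, simulate_study


def make_food(code, group="grains_roots_tubers", **values):
    per = {n: 0.0 for n in NUTRIENTS}
    per["energy_kcal"] = 100.0
    per.update(values)
    return FoodComposition(code, code, group, per)


def make_visit(member_id, visit_index, *portions):
    return RecallVisit(
        member_id=member_id,
        visit_index=visit_index,
        portions=[PortionRecord(code, grams) for code, grams in portions],
    )


@pytest.fixture(scope="session")
def fct():
    return generate_fct(seed=1)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_clusters=4, households_per_cluster=3, seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
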