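import numpy as np
import pytest

from cavegrowth import io_model
from cavegrowth.io_model import ReadingSet, Structure
from cavegrowth.simulate import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """102 fish lying exactly on the generating VBGF and power law."""
    return simulate_cohort(
        CohortSimConfig(length_noise_sd=0.0, weight_lognoise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """102 fish at the default (study-condition) noise levels."""
    return simulate_cohort(CohortSimConfig(seed=2))


@pytest.fixture(scope="session")
def six_species():
    from cavegrowth.reference import triplophysa_species

    return triplophysa_species()


def star_newick(names, branch=1.0):
    return "(" + ",".join(f"{n}:{branch}" for n in names) + ");"


@pytest.fixture()
def star_tree_factory():
    def make(names, branch=1.0):
        return io_model.read_newick(star_newick(names, branch))

    return make


def reading_set(fish_id, values, structure=Structure.OTOLITH):
    return ReadingSet(
        fish_id=fish_id, structure=structure, readings=tuple(float(v) for v in values)
    )
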