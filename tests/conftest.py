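import numpy as np
import pytest

from isletradius.simulate import generate_cohort

# seeds for the simulated study conditions; fixed once, shared across tests
COHORT_SEEDS = {"mantle": 101, "core": 202, "diffuse": 303, "if_mantle": 404}


@pytest.fixture
def unit_square():
    """Axis-aligned square centered at the origin, counterclockwise."""
    return np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort_dirs(tmp_path_factory):
    """Simulated IHC cohorts of the three placement phenotypes + one IF cohort.

    Session-scoped: the same folders back the batch, simulation and
    acceptance tests.
    """
    base = tmp_path_factory.mktemp("cohorts")
    dirs = {}
    for phenotype, n in (("mantle", 20), ("core", 20), ("diffuse", 50)):
        d = base / phenotype
        generate_cohort(d, n, phenotype, stain_mode="ihc", seed=COHORT_SEEDS[phenotype])
        dirs[phenotype] = d
    d = base / "if_mantle"
    generate_cohort(d, 20, "mantle", stain_mode="if", seed=COHORT_SEEDS["if_mantle"])
    dirs["if_mantle"] = d
    return dirs
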