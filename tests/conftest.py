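import numpy as np
import pytest

import grassid as g


@pytest.fixture(scope="session")
def toy():
    """The hand-coded 3-species x 4-obs x 2-perspective fixture."""
    return g.make_toy_fixture()


@pytest.fixture(scope="session")
def small_synth():
    """A small but non-trivial synthetic dataset (3 species, 2 perspectives)."""
    cfg = g.SyntheticConfig(
        n_species=3,
        n_per_species=10,
        perspectives=("A", "B"),
        dim=4,
        discriminability={"A": 3.0, "B": 0.5},
        noise_sd=1.0,
        view_correlation=0.2,
        seed=7,
    )
    return g.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_score_matrix(rng, perspective, obs_ids, species, concentration=1.0):
    """Random row-normalized score matrix (Dirichlet rows)."""
    scores = rng.dirichlet([concentration] * len(species), size=len(obs_ids))
    return g.ScoreMatrix(
        perspective=perspective,
        obs_ids=tuple(obs_ids),
        species_order=tuple(species),
        scores=scores,
    )
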