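"""Synthetic multi-perspective feature data.

The generator emulates the statistical structure that makes multi-view grass
identification work: each photographic perspective carries a perspective-
specific amount of species signal, and the several views of one plant are
correlated because they depict the same individual.

Generative model (documented here verbatim; tests rely on it):

* species-perspective centroid ``mu[k, p] = delta_p * z[k, p]`` with
  ``z[k, p]`` drawn standard-normal per coordinate;
* observation ``i`` of species ``k`` has a shared latent vector ``u_i``
  (standard normal);
* feature ``x[i, p] = mu[k, p] + sigma * (sqrt(rho) * u_i
  + sqrt(1 - rho) * eps[i, p])`` with ``eps`` standard normal.

``delta_p`` (discriminability) scales between-species centroid separation for
perspective ``p`` — the synthetic analogue of a perspective's information
content.  ``rho`` is the fraction of within-observation noise variance shared
across perspectives.  A single seeded generator draws, in this fixed order:
all centroids, then all shared latents, then all private noise, species-major
throughout — so the same seed gives bit-identical datasets on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import CANONICAL_PERSPECTIVES, Observation, ObservationSet
from .errors import ConfigError

#: Study-scale defaults: 31 grass species, 80 observations each, six
#: perspectives whose informativeness decreases F > LiF > LiS > N > LeB > LeT.
DEFAULT_DISCRIMINABILITY: dict[str, float] = {
    "F": 2.0,
    "LiF": 1.5,
    "LiS": 1.2,
    "N": 1.0,
    "LeB": 0.9,
    "LeT": 0.8,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the class-conditional Gaussian multi-view simulator."""

    n_species: int = 31
    n_per_species: int = 80
    perspectives: tuple[str, ...] = CANONICAL_PERSPECTIVES
    dim: int = 64
    discriminability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCRIMINABILITY)
    )
    noise_sd: float = 1.0
    view_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be a positive integer")
        if self.n_per_species < 1:
            raise ConfigError("n_per_species must be a positive integer")
        if self.dim < 1:
            raise ConfigError("dim must be >= 1")
        if not self.perspectives:
            raise ConfigError("perspectives must be a non-empty list")
        object.__setattr__(self, "perspectives", tuple(self.perspectives))
        if set(self.discriminability) != set(self.perspectives):
            raise ConfigError(
                "discriminability must have exactly one entry per perspective; "
                f"got {sorted(self.discriminability)} for perspectives {list(self.perspectives)}"
            )
        if any(d < 0 for d in self.discriminability.values()):
            raise ConfigError("discriminability values must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.view_correlation <= 1.0:
            raise ConfigError("view_correlation must lie in [0, 1]")


def _species_labels(n: int) -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"sp{i:0{width}d}" for i in range(n)]


def generate_dataset(config: SyntheticConfig) -> ObservationSet:
    """Draw a complete multi-perspective dataset from the generative model.

    Returns ``n_species * n_per_species`` observations with ids
    ``obs_<species_index>_<replicate_index>`` (zero-padded, hence sortable).
    Identical configs (including seed) yield bit-identical datasets.
    """
    K, n, d = config.n_species, config.n_per_species, config.dim
    P = list(config.perspectives)
    delta = np.array([config.discriminability[p] for p in P])
    sigma = config.noise_sd
    rho = config.view_correlation

    rng = np.random.default_rng(config.seed)
    # fixed draw order: centroids, then shared latents, then private noise
    z = rng.standard_normal((K, len(P), d))
    u = rng.standard_normal((K, n, d))
    eps = rng.standard_normal((K, n, len(P), d))

    mu = delta[None, :, None] * z  # (K, P, d)
    shared = np.sqrt(rho) * u[:, :, None, :]  # (K, n, 1, d)
    private = np.sqrt(1.0 - rho) * eps  # (K, n, P, d)
    x = mu[:, None, :, :] + sigma * (shared + private)  # (K, n, P, d)

    labels = _species_labels(K)
    kw = max(2, len(str(K - 1)))
    nw = max(2, len(str(n - 1)))
    observations = []
    for k in range(K):
        for i in range(n):
            features = {p: x[k, i, j] for j, p in enumerate(P)}
            observations.append(
                Observation(id=f"obs_{k:0{kw}d}_{i:0{nw}d}", species=labels[k], features=features)
            )
    return ObservationSet(
        observations, species_list=tuple(labels), perspective_list=tuple(P)
    )


# ---------------------------------------------------------------------------
# deterministic toy fixture
# ---------------------------------------------------------------------------

# Hand-coded coordinates: perspective P1 is linearly separable by species
# (three well-separated clusters); perspective P2 repeats the same four
# points for every species, so it carries no species signal at all.
_TOY_P1 = {
    "sp_a": [(10.0, 0.0), (11.0, 0.0), (10.0, 1.0), (11.0, 1.0)],
    "sp_b": [(0.0, 10.0), (0.0, 11.0), (1.0, 10.0), (1.0, 11.0)],
    "sp_c": [(-10.0, -10.0), (-11.0, -10.0), (-10.0, -11.0), (-11.0, -11.0)],
}
_TOY_P2 = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]


def make_toy_fixture() -> ObservationSet:
    """Deterministic hand-coded set: 3 species x 4 observations x 2 perspectives, dim 2.

    Species are linearly separable on perspective ``P1`` and exactly
    chance-level on ``P2`` (every species shares the same four points).
    Used by exact-value tests across modules.
    """
    observations = []
    for k, (species, pts) in enumerate(sorted(_TOY_P1.items())):
        for i, pt in enumerate(pts):
            observations.append(
                Observation(
                    id=f"obs_{k:02d}_{i:02d}",
                    species=species,
                    features={"P1": np.array(pt), "P2": np.array(_TOY_P2[i])},
                )
            )
    return ObservationSet(
        observations,
        species_list=("sp_a", "sp_b", "sp_c"),
        perspective_list=("P1", "P2"),
    )
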