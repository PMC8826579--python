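"""Core data model for multi-perspective observation sets.

An *observation* is one plant encounter recorded from several standardized
photographic perspectives; here each perspective is represented by a fixed
length feature vector (e.g. a CNN embedding of the image).  The canonical
perspective codes follow field practice for grasses: culm node (N),
inflorescence (F), leaf adaxial/top (LeT), leaf abaxial/back (LeB), ligule in
side view (LiS) and ligule in frontal view (LiF).

Datasets are exchanged as long-format (tidy) CSV tables with one row per
(observation, perspective) pair and columns ``obs_id, species, perspective,
f0..f{d-1}``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    DimensionError,
    DuplicateError,
    StratificationError,
)

#: Canonical perspective order used for display and subset ids.
CANONICAL_PERSPECTIVES: tuple[str, ...] = ("N", "F", "LeT", "LeB", "LiS", "LiF")

_FORBIDDEN_IN_CODE = set(",_ \t\n")


def _check_perspective_code(code: str) -> str:
    if not code or any(c in _FORBIDDEN_IN_CODE for c in code):
        raise DuplicateError(
            f"invalid perspective code {code!r}: must be non-empty and free of "
            "delimiter characters (comma, underscore, whitespace)"
        )
    return code


@dataclass(frozen=True)
class Observation:
    """One plant encounter: an id, a species label and per-perspective features."""

    id: str
    species: str
    features: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "features",
            {p: np.asarray(v, dtype=float) for p, v in self.features.items()},
        )


@dataclass
class ObservationSet:
    """A validated collection of observations with a fixed perspective list.

    Parameters
    ----------
    observations
        The observations, in any order; stored sorted by (species, id).
    species_list
        Ordered unique species labels; defaults to sorted labels found.
    perspective_list
        Ordered unique perspective codes; defaults to the codes of the first
        observation.
    allow_incomplete
        If False (default) every observation must carry every perspective in
        ``perspective_list``.
    """

    observations: list[Observation]
    species_list: tuple[str, ...] = field(default=())
    perspective_list: tuple[str, ...] = field(default=())
    allow_incomplete: bool = False
    dim: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.species_list:
            self.species_list = tuple(sorted({o.species for o in self.observations}))
        else:
            self.species_list = tuple(self.species_list)
        if not self.perspective_list:
            seen: dict[str, None] = {}
            for o in self.observations:
                for p in o.features:
                    seen.setdefault(p, None)
            self.perspective_list = tuple(seen)
        else:
            self.perspective_list = tuple(self.perspective_list)
        for p in self.perspective_list:
            _check_perspective_code(p)
        if len(set(self.perspective_list)) != len(self.perspective_list):
            raise DuplicateError("perspective_list contains duplicates")

        ids = [o.id for o in self.observations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateError(f"duplicate observation ids: {dupes}")

        species_set = set(self.species_list)
        dims: set[int] = set()
        incomplete: list[str] = []
        pset = set(self.perspective_list)
        for o in self.observations:
            if o.species not in species_set:
                raise StratificationError(
                    f"observation {o.id!r} has species {o.species!r} not in species_list"
                )
            missing = pset - set(o.features)
            unknown = set(o.features) - pset
            if unknown:
                raise CompletenessError(
                    f"observation {o.id!r} carries unknown perspectives {sorted(unknown)}"
                )
            if missing and not self.allow_incomplete:
                incomplete.append(o.id)
            for v in o.features.values():
                if v.ndim != 1:
                    raise DimensionError(f"observation {o.id!r}: feature vector must be 1-D")
                dims.add(v.shape[0])
        if incomplete:
            raise CompletenessError(
                "incomplete observations (missing perspectives): " + ", ".join(sorted(incomplete))
            )
        if len(dims) > 1:
            raise DimensionError(f"inconsistent feature dimensions: {sorted(dims)}")
        self.dim = dims.pop() if dims else 0
        # stable canonical storage order: species-major, then id
        order = {s: i for i, s in enumerate(self.species_list)}
        self.observations = sorted(self.observations, key=lambda o: (order[o.species], o.id))

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.observations)

    def labels(self) -> dict[str, str]:
        """Map observation id -> species label."""
        return {o.id: o.species for o in self.observations}

    def subset(self, ids: Iterable[str]) -> "ObservationSet":
        """Restrict to the given ids, preserving species/perspective lists."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise AlignmentErrorIds(sorted(unknown))
        obs = [o for o in self.observations if o.id in wanted]
        return ObservationSet(
            obs,
            species_list=self.species_list,
            perspective_list=self.perspective_list,
            allow_incomplete=self.allow_incomplete,
        )

    def feature_matrix(self, perspective: str) -> tuple[list[str], np.ndarray, list[str]]:
        """Return (ids, X, y) for one perspective, rows sorted by id.

        Observations lacking the perspective are skipped (only possible when
        ``allow_incomplete``).
        """
        rows = [o for o in self.observations if perspective in o.features]
        rows.sort(key=lambda o: o.id)
        ids = [o.id for o in rows]
        X = np.vstack([o.features[perspective] for o in rows]) if rows else np.empty((0, self.dim))
        y = [o.species for o in rows]
        return ids, X, y

    # -- tabular form ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, deterministic row order (species-major, id, perspective)."""
        cols = [f"f{i}" for i in range(self.dim)]
        records = []
        for o in self.observations:  # already species-major, id-sorted
            for p in self.perspective_list:
                if p not in o.features:
                    continue
                records.append((o.id, o.species, p, *o.features[p]))
        return pd.DataFrame(records, columns=["obs_id", "species", "perspective", *cols])


class AlignmentErrorIds(KeyError):
    def __init__(self, ids: list[str]):
        super().__init__(f"unknown observation ids: {ids}")


@dataclass(frozen=True)
class DataSplit:
    """A stratified train/test partition of an ObservationSet's ids."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int
    per_species_train: int
    per_species_test: int

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise StratificationError("train and test ids overlap")

    def role_frame(self) -> pd.DataFrame:
        rows = [(i, "train") for i in sorted(self.train_ids)]
        rows += [(i, "test") for i in sorted(self.test_ids)]
        rows.sort()
        return pd.DataFrame(rows, columns=["obs_id", "role"])


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path, allow_incomplete: bool = False) -> ObservationSet:
    """Read a long-format feature CSV into an ObservationSet.

    The file must have header ``obs_id, species, perspective, f0..f{d-1}``.
    Rows may appear in any order; observations are assembled by grouping on
    ``obs_id``.  Raises :class:`DuplicateError` for repeated
    (obs_id, perspective) pairs, :class:`DimensionError` for ragged feature
    columns and :class:`CompletenessError` (unless ``allow_incomplete``) when
    an observation lacks a perspective present elsewhere in the file.
    """
    df = pd.read_csv(path, dtype={"obs_id": str, "species": str, "perspective": str})
    required = ["obs_id", "species", "perspective"]
    if list(df.columns[:3]) != required:
        raise DimensionError(
            f"feature table must start with columns {required}, got {list(df.columns[:3])}"
        )
    fcols = list(df.columns[3:])
    if not fcols:
        raise DimensionError("feature table has no feature columns (f0..)")
    if df[fcols].isna().any().any():
        bad = df.loc[df[fcols].isna().any(axis=1), "obs_id"].tolist()
        raise DimensionError(f"ragged/missing feature cells for obs_ids {sorted(set(bad))}")

    dup = df.duplicated(subset=["obs_id", "perspective"], keep=False)
    if dup.any():
        pairs = sorted(set(map(tuple, df.loc[dup, ["obs_id", "perspective"]].values)))
        raise DuplicateError(f"duplicate (obs_id, perspective) rows: {pairs}")

    # perspective order: first appearance in file
    perspective_list = tuple(dict.fromkeys(df["perspective"]))
    feats = df[fcols].to_numpy(dtype=float)
    observations: list[Observation] = []
    species_of: dict[str, str] = {}
    by_obs: dict[str, dict[str, np.ndarray]] = {}
    for i, (oid, sp, p) in enumerate(zip(df["obs_id"], df["species"], df["perspective"])):
        if species_of.setdefault(oid, sp) != sp:
            raise DuplicateError(f"observation {oid!r} appears with conflicting species labels")
        by_obs.setdefault(oid, {})[p] = feats[i]
    for oid, fmap in by_obs.items():
        observations.append(Observation(id=oid, species=species_of[oid], features=fmap))
    return ObservationSet(
        observations, perspective_list=perspective_list, allow_incomplete=allow_incomplete
    )


def _format_float(x: float) -> str:
    return repr(float(x))


def write_feature_table(dataset: ObservationSet, path: str | Path) -> None:
    """Write the long-format CSV with deterministic row order and full precision.

    Floats are serialized with ``repr`` so a read/write round trip is
    bit-exact.  Writing the same set twice yields byte-identical files.
    """
    df = dataset.to_frame()
    buf = io.StringIO()
    fcols = [c for c in df.columns if c.startswith("f")]
    df[fcols] = df[fcols].map(_format_float)
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_split(path: str | Path, seed: int = -1) -> DataSplit:
    df = pd.read_csv(path, dtype=str)
    train = frozenset(df.loc[df["role"] == "train", "obs_id"])
    test = frozenset(df.loc[df["role"] == "test", "obs_id"])
    return DataSplit(train, test, seed=seed, per_species_train=-1, per_species_test=-1)


def write_split(split: DataSplit, path: str | Path) -> None:
    buf = io.StringIO()
    split.role_frame().to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------


def stratified_split(
    dataset: ObservationSet,
    train_per_species: int = 65,
    test_per_species: int = 15,
    seed: int = 0,
) -> DataSplit:
    """Species-stratified train/test split with exact per-species counts.

    Every species must contribute exactly ``train_per_species +
    test_per_species`` observations (the balanced design the accuracy
    denominators rely on).  Ids are sorted within species before the seeded
    shuffle, so the split is invariant to observation order in the input.
    """
    if train_per_species < 1 or test_per_species < 1:
        raise StratificationError("train_per_species and test_per_species must be >= 1")
    need = train_per_species + test_per_species
    by_species: dict[str, list[str]] = {s: [] for s in dataset.species_list}
    for o in dataset.observations:
        by_species[o.species].append(o.id)
    bad = {s: len(v) for s, v in by_species.items() if len(v) != need}
    if bad:
        raise StratificationError(
            f"species with observation count != {need}: "
            + ", ".join(f"{s} ({n})" for s, n in sorted(bad.items()))
        )
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    test: set[str] = set()
    for s in dataset.species_list:
        ids = sorted(by_species[s])
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        train.update(shuffled[:train_per_species])
        test.update(shuffled[train_per_species:])
    return DataSplit(
        frozenset(train),
        frozenset(test),
        seed=seed,
        per_species_train=train_per_species,
        per_species_test=test_per_species,
    )
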