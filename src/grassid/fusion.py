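"""Score-level fusion by the normalized sum rule, over perspective subsets.

The fused score of an observation over a perspective subset ``P`` is the
arithmetic mean of the per-perspective score rows:

    S(i, k) = (1 / |P|) * sum_{p in P} s_p(i, k)

Because every member row sums to one, so does every fused row; the predicted
species is the argmax of the fused row.  The module also enumerates all
non-empty perspective subsets (optionally requiring or excluding one
perspective, e.g. the inflorescence) for combination studies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import ScoreMatrix
from .errors import AlignmentError, ConfigError, MissingPerspectiveError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerspectiveSubset:
    """A non-empty ordered set of perspective codes."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ConfigError("a perspective subset must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"duplicate members in subset {self.members}")

    @property
    def id(self) -> str:
        """Underscore-joined subset name, e.g. ``N_F_LeB_LiF``."""
        return "_".join(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, p: str) -> bool:
        return p in self.members


@dataclass
class FusedScoreMatrix(ScoreMatrix):
    """Sum-rule fused scores over a perspective subset; same row contract as ScoreMatrix."""

    subset: PerspectiveSubset = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.subset is None:
            raise ConfigError("FusedScoreMatrix requires a subset")
        super().__post_init__()


def fuse_scores(
    matrices: Mapping[str, ScoreMatrix],
    subset: PerspectiveSubset,
    allow_incomplete: bool = False,
) -> FusedScoreMatrix:
    """Average the member score matrices cell-wise (unweighted sum rule).

    All member matrices must share ``species_order``; with complete data they
    also share ``obs_ids``.  With ``allow_incomplete`` the mean is taken over
    the perspectives available for each observation (observations with no
    member perspective at all are an error).
    """
    missing = [p for p in subset.members if p not in matrices]
    if missing:
        raise MissingPerspectiveError(
            f"subset {subset.id}: no score matrix for perspectives {missing}"
        )
    member = [matrices[p] for p in subset.members]
    species_order = member[0].species_order
    if any(m.species_order != species_order for m in member):
        raise AlignmentError("member matrices disagree on species_order")

    if not allow_incomplete:
        obs_ids = member[0].obs_ids
        if any(m.obs_ids != obs_ids for m in member):
            raise AlignmentError("member matrices disagree on obs_ids")
        fused = np.mean([m.scores for m in member], axis=0)
    else:
        obs_ids = tuple(sorted(set().union(*(m.obs_ids for m in member))))
        idx = {o: i for i, o in enumerate(obs_ids)}
        total = np.zeros((len(obs_ids), len(species_order)))
        count = np.zeros(len(obs_ids))
        for m in member:
            rows = [idx[o] for o in m.obs_ids]
            total[rows] += m.scores
            count[rows] += 1
        if (count == 0).any():
            bad = [o for o, c in zip(obs_ids, count) if c == 0]
            raise MissingPerspectiveError(
                f"subset {subset.id}: observations with no member perspective: {bad}"
            )
        fused = total / count[:, None]

    return FusedScoreMatrix(
        perspective=subset.id,
        obs_ids=obs_ids,
        species_order=species_order,
        scores=fused,
        subset=subset,
    )


def predict_labels(fused: ScoreMatrix) -> dict[str, str]:
    """Top-1 decision per row; float ties go to the smallest species index (logged)."""
    out: dict[str, str] = {}
    for oid, row in zip(fused.obs_ids, fused.scores):
        best = int(np.argmax(row))  # argmax returns the first maximal index
        if np.count_nonzero(row == row[best]) > 1:
            logger.debug("tie in fused scores for %s; choosing %s", oid, fused.species_order[best])
        out[oid] = fused.species_order[best]
    return out


def enumerate_subsets(
    perspectives: Sequence[str],
    require: str | None = None,
    exclude: str | None = None,
) -> list[PerspectiveSubset]:
    """All non-empty subsets, ordered by size then lexicographically over the input order.

    ``require`` keeps only subsets containing that perspective; ``exclude``
    drops them.  For six perspectives this yields 63 subsets, of which 32
    contain any given perspective and 31 do not.
    """
    perspectives = list(perspectives)
    if len(set(perspectives)) != len(perspectives):
        raise ConfigError("perspective list contains duplicates")
    for p in (require, exclude):
        if p is not None and p not in perspectives:
            raise ConfigError(f"unknown perspective {p!r}")
    if require is not None and require == exclude:
        raise ConfigError("require and exclude cannot name the same perspective")
    out = []
    for size in range(1, len(perspectives) + 1):
        for combo in itertools.combinations(perspectives, size):
            if require is not None and require not in combo:
                continue
            if exclude is not None and exclude in combo:
                continue
            out.append(PerspectiveSubset(combo))
    return out
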