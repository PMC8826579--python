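"""Accuracy statistics: confusion matrices, per-species accuracy, macro recall,
relative accuracy, and the perspective-combination study.

Accuracy is the percentage of correctly identified observations per species;
the headline number is its unweighted mean across species (macro recall) —
with the balanced test design (equal test observations per species) macro and
micro accuracy coincide.  Relative accuracy divides each species' accuracy by
the maximum across species, giving a difficulty profile comparable across
feature sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classify import ScoreMatrix
from .errors import AlignmentError, ConfigError, DegenerateInputError
from .fusion import PerspectiveSubset, fuse_scores, predict_labels


@dataclass
class EvaluationResult:
    """Confusion matrix and accuracy summaries for one perspective subset."""

    subset: PerspectiveSubset | None
    species_order: tuple[str, ...]
    confusion: np.ndarray  # rows = reference species, columns = predicted
    per_species_accuracy: dict[str, float]  # percent, [0, 100]
    macro_accuracy: float  # percent: mean of per-species accuracies

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion, index=list(self.species_order), columns=list(self.species_order)
        )


def evaluate(
    predictions: Mapping[str, str],
    truth: Mapping[str, str],
    species_order: Sequence[str],
    subset: PerspectiveSubset | None = None,
) -> EvaluationResult:
    """Confusion matrix plus per-species and macro accuracy (percent).

    ``predictions`` and ``truth`` must share exactly the same observation ids
    and use labels from ``species_order``.  Species without reference
    observations are excluded from the per-species map and the macro mean.
    """
    if set(predictions) != set(truth):
        only_p = sorted(set(predictions) - set(truth))[:5]
        only_t = sorted(set(truth) - set(predictions))[:5]
        raise AlignmentError(
            f"prediction/truth id mismatch (extra predictions {only_p}, missing {only_t})"
        )
    species_order = tuple(species_order)
    known = set(species_order)
    ids = sorted(truth)
    y_true = [truth[i] for i in ids]
    y_pred = [predictions[i] for i in ids]
    bad = {l for l in (*y_true, *y_pred) if l not in known}
    if bad:
        raise AlignmentError(f"labels outside species_order: {sorted(bad)}")

    cm = _sk_confusion(y_true, y_pred, labels=list(species_order))
    rowsum = cm.sum(axis=1)
    per_species = {
        s: 100.0 * cm[k, k] / rowsum[k]
        for k, s in enumerate(species_order)
        if rowsum[k] > 0
    }
    macro = float(np.mean(list(per_species.values())))
    return EvaluationResult(
        subset=subset,
        species_order=species_order,
        confusion=cm,
        per_species_accuracy=per_species,
        macro_accuracy=macro,
    )


def relative_accuracy(per_species_accuracy: Mapping[str, float]) -> dict[str, float]:
    """Each species' accuracy divided by the maximum across species (in [0, 1]).

    At least one value equals exactly 1.  All-zero accuracies are degenerate.
    """
    if not per_species_accuracy:
        raise DegenerateInputError("empty accuracy map")
    mx = max(per_species_accuracy.values())
    if mx <= 0:
        raise DegenerateInputError("all species accuracies are zero; relative accuracy undefined")
    return {s: a / mx for s, a in per_species_accuracy.items()}


@dataclass
class CombinationReport:
    """Evaluation of every perspective subset, partitioned by inflorescence presence."""

    results: dict[str, EvaluationResult]
    has_inflorescence: dict[str, bool]
    best_by_size: dict[tuple[bool, int], str]  # (with_F, size) -> subset id
    inflorescence: str

    def to_frame(self) -> pd.DataFrame:
        """One row per subset: id, size, has_F, macro accuracy, per-species accuracies."""
        rows = []
        for sid, res in self.results.items():
            row = {
                "subset_id": sid,
                "size": len(res.subset),
                "has_F": self.has_inflorescence[sid],
                "macro_accuracy": res.macro_accuracy,
            }
            row.update({f"acc_{s}": a for s, a in res.per_species_accuracy.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        """Best subset per size for each partition (with / without inflorescence)."""
        rows = []
        for (with_f, size), sid in sorted(self.best_by_size.items()):
            rows.append(
                {
                    "partition": "flowers_present" if with_f else "vegetative",
                    "size": size,
                    "best_combination": sid,
                    "macro_accuracy": round(self.results[sid].macro_accuracy, 1),
                }
            )
        return pd.DataFrame(rows)


def combination_study(
    matrices: Mapping[str, ScoreMatrix],
    subsets: Sequence[PerspectiveSubset],
    truth: Mapping[str, str],
    inflorescence: str = "F",
) -> CombinationReport:
    """Fuse, predict and evaluate every subset; pick the best per size and partition.

    Subsets are partitioned by whether they contain the inflorescence
    perspective; within each (partition, size) cell the subset with maximal
    macro accuracy wins, ties broken by lexicographically smaller subset id.
    """
    if not subsets:
        raise ConfigError("no subsets to evaluate")
    results: dict[str, EvaluationResult] = {}
    has_f: dict[str, bool] = {}
    for subset in subsets:
        if subset.id in results:
            raise ConfigError(f"subset {subset.id} listed twice")
        try:
            fused = fuse_scores(matrices, subset)
            species_order = fused.species_order
            preds = predict_labels(fused)
            results[subset.id] = evaluate(preds, truth, species_order, subset=subset)
        except Exception as exc:
            raise type(exc)(f"subset {subset.id}: {exc}") from exc
        has_f[subset.id] = inflorescence in subset

    best: dict[tuple[bool, int], str] = {}
    for sid, res in results.items():
        key = (has_f[sid], len(res.subset))
        cur = best.get(key)
        if (
            cur is None
            or res.macro_accuracy > results[cur].macro_accuracy
            or (res.macro_accuracy == results[cur].macro_accuracy and sid < cur)
        ):
            best[key] = sid
    return CombinationReport(
        results=results, has_inflorescence=has_f, best_by_size=best, inflorescence=inflorescence
    )
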