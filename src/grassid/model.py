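"""High-level model/results interface for the multi-perspective fusion pipeline.

``PerspectiveFusionModel`` bundles a dataset, a split policy and a classifier
specification; ``fit()`` trains one classifier per perspective, scores the
test split, runs the sum-rule combination study over all perspective subsets
and returns a ``PerspectiveFusionResults`` carrying the score matrices, the
per-subset accuracies and a printable summary.

Example
-------
>>> from grassid import PerspectiveFusionModel, SyntheticConfig, ClassifierSpec
>>> cfg = SyntheticConfig(n_species=5, n_per_species=20, dim=8, seed=0)
>>> model = PerspectiveFusionModel.from_synthetic(
...     cfg, classifier=ClassifierSpec("svm_linear", grid=[{"C": 1.0}]),
...     train_per_species=15, test_per_species=5)
>>> res = model.fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import (
    ClassifierSpec,
    ScoreMatrix,
    TrainedPerspectiveModel,
    predict_scores,
    train_all,
)
from .datamodel import DataSplit, ObservationSet, read_feature_table, stratified_split
from .evaluate import CombinationReport, combination_study, evaluate
from .fusion import PerspectiveSubset, enumerate_subsets, fuse_scores, predict_labels
from .simulate import SyntheticConfig, generate_dataset


@dataclass
class PerspectiveFusionModel:
    """Multi-perspective classifier with score-level sum-rule fusion.

    Parameters
    ----------
    dataset
        A complete multi-perspective observation set.
    classifier
        Classifier family, tuning grid and seed; one instance is tuned and
        trained per perspective.
    train_per_species, test_per_species
        Per-species split counts (defaults 65/15, the balanced design).
    split_seed
        Seed of the stratified shuffle.
    inflorescence
        Perspective code treated as the flowering organ when partitioning
        subsets ("F" by default; ignored if absent from the dataset).
    """

    dataset: ObservationSet
    classifier: ClassifierSpec
    train_per_species: int = 65
    test_per_species: int = 15
    split_seed: int = 0
    inflorescence: str = "F"

    @classmethod
    def from_csv(cls, path: str | Path, classifier: ClassifierSpec, **kwargs):
        return cls(read_feature_table(path), classifier, **kwargs)

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig, classifier: ClassifierSpec, **kwargs):
        return cls(generate_dataset(config), classifier, **kwargs)

    def split(self) -> DataSplit:
        return stratified_split(
            self.dataset, self.train_per_species, self.test_per_species, self.split_seed
        )

    def fit(self, subsets: list[PerspectiveSubset] | None = None) -> "PerspectiveFusionResults":
        """Train per-perspective classifiers and evaluate all perspective subsets."""
        split = self.split()
        models = train_all(self.dataset, split, self.classifier)
        test = self.dataset.subset(split.test_ids)
        scores = {p: predict_scores(m, test) for p, m in models.items()}
        truth = {o.id: o.species for o in test.observations}
        if subsets is None:
            subsets = enumerate_subsets(self.dataset.perspective_list)
        report = combination_study(scores, subsets, truth, inflorescence=self.inflorescence)
        return PerspectiveFusionResults(
            model=self, split=split, trained=models, scores=scores, truth=truth, report=report
        )


@dataclass
class PerspectiveFusionResults:
    """Fitted pipeline: score matrices, combination report and summaries."""

    model: PerspectiveFusionModel
    split: DataSplit
    trained: dict[str, TrainedPerspectiveModel]
    scores: dict[str, ScoreMatrix]
    truth: dict[str, str]
    report: CombinationReport

    # -- convenience accessors --------------------------------------------

    def single_view_accuracies(self) -> dict[str, float]:
        """Macro accuracy (percent) of each perspective used alone."""
        out = {}
        for p in self.scores:
            sid = PerspectiveSubset((p,)).id
            if sid in self.report.results:
                out[p] = self.report.results[sid].macro_accuracy
            else:
                preds = predict_labels(self.scores[p])
                out[p] = evaluate(preds, self.truth, self.scores[p].species_order).macro_accuracy
        return out

    def macro_accuracy(self, members: tuple[str, ...] | str) -> float:
        """Macro accuracy (percent) of one fused subset, by members or subset id."""
        sid = members if isinstance(members, str) else PerspectiveSubset(tuple(members)).id
        if sid in self.report.results:
            return self.report.results[sid].macro_accuracy
        subset = PerspectiveSubset(tuple(sid.split("_")))
        fused = fuse_scores(self.scores, subset)
        return evaluate(predict_labels(fused), self.truth, fused.species_order).macro_accuracy

    def chosen_hyperparameters(self) -> dict[str, dict]:
        return {p: m.chosen_setting for p, m in self.trained.items()}

    def summary(self) -> str:
        """Printable report: design, single-view ranking, best combinations."""
        ds = self.model.dataset
        lines = [
            "Multi-perspective fusion results",
            "=" * 48,
            f"species: {len(ds.species_list)}   observations: {len(ds)}   "
            f"perspectives: {', '.join(ds.perspective_list)}   dim: {ds.dim}",
            f"split: {self.split.per_species_train} train / "
            f"{self.split.per_species_test} test per species (seed {self.split.seed})",
            f"classifier: {self.model.classifier.family}",
            "",
            "Single-perspective macro accuracy (%):",
        ]
        singles = self.single_view_accuracies()
        for p, a in sorted(singles.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {p:>5s}  {a:5.1f}")
        lines.append("")
        lines.append("Best combination per size (macro accuracy, %):")
        tbl = self.report.summary_table()
        for _, r in tbl.iterrows():
            lines.append(
                f"  {r['partition']:<16s} size {r['size']}: "
                f"{r['best_combination']:<24s} {r['macro_accuracy']:5.1f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()
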