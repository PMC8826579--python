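"""Per-perspective classifiers producing normalized species score matrices.

One classifier is trained per perspective on the training-set feature vectors
of that perspective only.  Hyperparameters are tuned by bootstrap resampling:
for each candidate setting the training set is resampled with replacement a
fixed number of times, the model is fitted on each resample and scored on the
out-of-bag observations, and the setting with the best mean accuracy wins.

Score production: families that natively emit class probabilities (random
forest, naive Bayes posteriors, k-NN neighbor-vote fractions) use them
directly; linear-SVM multiclass decision values are mapped through a softmax
(temperature 1).  Every score row is non-negative and sums to one, which is
what the downstream sum-rule fusion requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import DataSplit, ObservationSet
from .errors import ConfigError, DimensionError, TrainingError

logger = logging.getLogger(__name__)

FAMILIES = ("svm_linear", "random_forest", "knn", "naive_bayes")

_GRID_PARAM = {
    "svm_linear": "C",
    "random_forest": "max_features",
    "knn": "n_neighbors",
    "naive_bayes": "var_smoothing",
}


def default_grid(family: str, dim: int | None = None) -> list[dict]:
    """Ten standard candidate settings per family.

    svm_linear: C log-spaced over [1e-3, 1e2]; random_forest: features-per-
    split integers spanning [1, dim]; knn: odd neighbor counts 1..19;
    naive_bayes: variance smoothing log-spaced over [1e-12, 1e-3].
    """
    if family == "svm_linear":
        return [{"C": float(c)} for c in np.logspace(-3, 2, 10)]
    if family == "random_forest":
        if dim is None:
            raise ConfigError("random_forest grid requires the feature dimension")
        vals = np.unique(np.round(np.linspace(1, dim, 10)).astype(int))
        return [{"max_features": int(v)} for v in vals]
    if family == "knn":
        return [{"n_neighbors": k} for k in range(1, 20, 2)]
    if family == "naive_bayes":
        return [{"var_smoothing": float(v)} for v in np.logspace(-12, -3, 10)]
    raise ConfigError(f"unknown classifier family {family!r}; choose from {FAMILIES}")


@dataclass
class ClassifierSpec:
    """A classifier family plus its tuning grid and resampling budget."""

    family: str
    grid: list[dict] = field(default_factory=list)
    tuning_resamples: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}; choose from {FAMILIES}")
        if self.tuning_resamples < 1:
            raise ConfigError("tuning_resamples must be a positive integer")
        if self.grid and len(self.grid) == 0:
            raise ConfigError("grid must be non-empty")

    def resolved_grid(self, dim: int) -> list[dict]:
        grid = self.grid or default_grid(self.family, dim)
        if not grid:
            raise ConfigError("grid must be non-empty")
        return grid


def _build_estimator(family: str, setting: Mapping[str, object], seed: int):
    if family == "svm_linear":
        est = SVC(kernel="linear", decision_function_shape="ovr", **setting)
        return make_pipeline(StandardScaler(), est)
    if family == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed, **setting)
        return est
    if family == "knn":
        est = KNeighborsClassifier(weights="uniform", **setting)
        return make_pipeline(StandardScaler(), est)
    if family == "naive_bayes":
        return GaussianNB(**setting)
    raise ConfigError(f"unknown classifier family {family!r}")


@dataclass
class ScoreMatrix:
    """Per-perspective classifier scores: rows = test observations, columns = species.

    Each row is the score vector ``s_p`` of one observation under perspective
    ``p``: non-negative and summing to one (tolerance 1e-9).
    """

    perspective: str
    obs_ids: tuple[str, ...]
    species_order: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.obs_ids = tuple(self.obs_ids)
        self.species_order = tuple(self.species_order)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.obs_ids), len(self.species_order)):
            raise DimensionError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.obs_ids)} observations x {len(self.species_order)} species"
            )
        if self.scores.size and (self.scores < -1e-12).any():
            raise DimensionError("score matrix has negative entries")
        if self.scores.size and not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-9):
            raise DimensionError("score matrix rows must sum to 1 within 1e-9")


@dataclass
class TrainedPerspectiveModel:
    """A fitted single-perspective classifier plus the tuning outcome."""

    perspective: str
    spec: ClassifierSpec
    chosen_setting: dict
    estimator: object
    species_order: tuple[str, ...]
    dim: int
    tuning_accuracy: dict[str, float] = field(default_factory=dict)


def _scores_from(estimator, family: str, X: np.ndarray, n_classes: int) -> np.ndarray:
    if family == "svm_linear":
        d = estimator.decision_function(X)
        if d.ndim == 1:  # binary: one signed margin per sample
            d = np.column_stack([-d, d])
        return softmax(d, axis=1)
    proba = estimator.predict_proba(X)
    # GaussianNB/KNN drop classes absent from a resample; caller aligns columns
    return proba


def _aligned_proba(estimator, family, X, species_order):
    """Probability rows aligned to species_order (unseen classes get 0)."""
    raw = _scores_from(estimator, family, X, len(species_order))
    fitted = list(_fitted_classes(estimator))
    out = np.zeros((X.shape[0], len(species_order)))
    col = {s: j for j, s in enumerate(species_order)}
    for i, s in enumerate(fitted):
        out[:, col[s]] = raw[:, i]
    rs = out.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return out / rs


def _fitted_classes(estimator):
    if hasattr(estimator, "classes_"):
        return estimator.classes_
    return estimator[-1].classes_


def tune_and_train(
    train_set: ObservationSet,
    perspective: str,
    spec: ClassifierSpec,
) -> TrainedPerspectiveModel:
    """Bootstrap-tune the hyperparameter grid and refit on the full training set.

    For each grid setting, ``tuning_resamples`` bootstrap resamples are drawn
    (with replacement); the model is fitted on each resample and its accuracy
    measured on the out-of-bag observations; settings are ranked by mean
    accuracy, ties broken by grid order.  A single-element grid short-circuits
    the resampling.  A setting that cannot be fitted (e.g. more neighbors
    than resample points) scores 0 with a logged warning.
    """
    ids, X, y = train_set.feature_matrix(perspective)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    missing = set(train_set.species_list) - set(classes)
    if missing:
        raise TrainingError(
            f"perspective {perspective!r}: species absent from training data: {sorted(missing)}"
        )
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 species")
    if counts.min() < 2:
        raise TrainingError("training requires at least 2 observations per species")

    grid = spec.resolved_grid(train_set.dim)
    rng = np.random.default_rng(spec.seed)
    n = len(ids)
    tuning_accuracy: dict[str, float] = {}

    if len(grid) == 1:
        chosen = grid[0]
    else:
        # shared resamples across settings (paired comparison); redraw when OOB empty
        resamples = []
        while len(resamples) < spec.tuning_resamples:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0:
                continue
            resamples.append((idx, oob))
        mean_acc = []
        for setting in grid:
            accs = []
            for idx, oob in resamples:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = _build_estimator(spec.family, setting, spec.seed)
                        est.fit(X[idx], y[idx])
                        pred = est.predict(X[oob])
                    accs.append(float(np.mean(pred == y[oob])))
                except Exception as exc:  # unfittable setting scores 0
                    logger.warning(
                        "perspective %s: setting %s failed to fit (%s); scored 0",
                        perspective, setting, exc,
                    )
                    accs.append(0.0)
            mean_acc.append(float(np.mean(accs)))
        best = int(np.argmax(mean_acc))  # argmax takes the earliest on ties
        chosen = grid[best]
        tuning_accuracy = {repr(s): a for s, a in zip(grid, mean_acc)}

    estimator = _build_estimator(spec.family, chosen, spec.seed)
    estimator.fit(X, y)
    return TrainedPerspectiveModel(
        perspective=perspective,
        spec=spec,
        chosen_setting=dict(chosen),
        estimator=estimator,
        species_order=tuple(train_set.species_list),
        dim=train_set.dim,
        tuning_accuracy=tuning_accuracy,
    )


def predict_scores(model: TrainedPerspectiveModel, test_set: ObservationSet) -> ScoreMatrix:
    """Score test observations; rows sorted by obs_id, columns by species_order."""
    if test_set.dim != model.dim:
        raise DimensionError(
            f"test feature dimension {test_set.dim} != training dimension {model.dim}"
        )
    ids, X, _ = test_set.feature_matrix(model.perspective)
    scores = _aligned_proba(model.estimator, model.spec.family, X, model.species_order)
    return ScoreMatrix(
        perspective=model.perspective,
        obs_ids=tuple(ids),
        species_order=model.species_order,
        scores=scores,
    )


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """CSV with columns obs_id, perspective, then one column per species label."""
    import io as _io
    from pathlib import Path as _Path

    df = pd.DataFrame(matrix.scores, columns=list(matrix.species_order))
    df.insert(0, "perspective", matrix.perspective)
    df.insert(0, "obs_id", list(matrix.obs_ids))
    buf = _io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    _Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_score_matrix(path) -> ScoreMatrix:
    df = pd.read_csv(path, dtype={"obs_id": str, "perspective": str})
    species = [c for c in df.columns if c not in ("obs_id", "perspective")]
    return ScoreMatrix(
        perspective=str(df["perspective"].iloc[0]),
        obs_ids=tuple(df["obs_id"]),
        species_order=tuple(species),
        scores=df[species].to_numpy(dtype=float),
    )


def train_all(
    dataset: ObservationSet,
    split: DataSplit,
    spec: ClassifierSpec,
    perspectives: Sequence[str] | None = None,
) -> dict[str, TrainedPerspectiveModel]:
    """Tune and train one model per perspective on the training split.

    Per-perspective seeds are derived as ``spec.seed + index in the dataset's
    perspective list``, so each perspective's model is unchanged by the order
    in which perspectives are requested.
    """
    perspectives = list(perspectives or dataset.perspective_list)
    train = dataset.subset(split.train_ids)
    out: dict[str, TrainedPerspectiveModel] = {}
    for p in perspectives:
        if p not in dataset.perspective_list:
            raise ConfigError(f"unknown perspective {p!r}")
        pseed = spec.seed + dataset.perspective_list.index(p)
        pspec = ClassifierSpec(
            family=spec.family,
            grid=spec.grid,
            tuning_resamples=spec.tuning_resamples,
            seed=pseed,
        )
        try:
            out[p] = tune_and_train(train, p, pspec)
        except Exception as exc:
            raise type(exc)(f"perspective {p!r}: {exc}") from exc
    return out


def run_all(
    dataset: ObservationSet,
    split: DataSplit,
    spec: ClassifierSpec,
    perspectives: Sequence[str] | None = None,
) -> dict[str, ScoreMatrix]:
    """Tune, train and score every perspective; returns perspective -> ScoreMatrix."""
    test = dataset.subset(split.test_ids)
    models = train_all(dataset, split, spec, perspectives)
    return {p: predict_scores(m, test) for p, m in models.items()}
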