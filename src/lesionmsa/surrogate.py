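"""Random-forest surrogate predictor serving as the characteristic function.

A contribution analysis over multi-lesion configurations needs the system's
performance for arbitrary binary lesion configurations, but a clinical
cohort only samples the configurations its patients happen to present.  A
random forest trained on the graded lesion loads (percent damage per
region) against the binarised behavioural outcome stands in for the
missing configurations: any binary intact/lesioned pattern is embedded as
a graded feature vector and the trained model predicts its performance.

The module covers hyperparameter selection by exhaustive grid search on
F1, leave-one-out evaluation, the shuffled-label chance level, and the
configuration-evaluation contract used by the Shapley engine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .data_model import LesionDataset, RegionSet
from .utils import spawn_seeds

__all__ = [
    "DEFAULT_GRID",
    "PredictorSpec",
    "PredictorEvaluation",
    "SurrogateModel",
    "f1_score",
    "optimize_hyperparameters",
    "train",
    "loo_accuracy",
    "chance_level",
]

logger = logging.getLogger(__name__)

#: Default hyperparameter grid.  The search dimensions are the forest
#: size, tree depth, feature subsampling, bagging, and the minimum leaf
#: and split sizes; the candidate values are package defaults chosen to
#: span shallow/deep and full/subsampled regimes at desk scale.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [50, 150],
    "max_depth": [None, 4],
    "max_features": ["sqrt", 0.5],
    "bootstrap": [True],
    "min_samples_leaf": [2, 5],
    "min_samples_split": [2],
}

#: Class treated as "positive" when computing precision/recall/F1.  The
#: deficit class (0) is the minority, clinically relevant outcome.
DEFAULT_POSITIVE_LABEL = 0


@dataclass
class PredictorSpec:
    """A hyperparameter grid plus the point selected from it."""

    grid: dict[str, list]
    chosen: dict
    selection_metric: str = "f1"
    seed: int = 0
    cv_score: float = float("nan")

    def __post_init__(self) -> None:
        for key, value in self.chosen.items():
            if key not in self.grid:
                raise ValueError(f"chosen key {key!r} not a grid dimension")
            if value not in self.grid[key]:
                raise ValueError(f"chosen[{key!r}] = {value!r} not in grid")


@dataclass
class PredictorEvaluation:
    """Leave-one-out performance of the surrogate on a cohort."""

    loo_accuracy: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: int = DEFAULT_POSITIVE_LABEL
    chance_accuracy: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SurrogateModel:
    """Trained predictor realising the characteristic-function contract.

    ``evaluate_configurations`` maps binary intact/lesioned configurations
    (1 = intact) to performance values.  Feature order is bound to the
    region set at training time and immutable afterwards.
    """

    model: RandomForestClassifier
    region_set: RegionSet
    output_mode: str = "class"  # "class" (hard 0/1) or "proba" (P[intact])
    #: "ablation": lesioned -> 100% load (complete ablation);
    #: "max_load": lesioned -> the region's maximum observed load, keeping
    #:   queries inside the training support (matters for the RoB, whose
    #:   observed loads are tiny);
    #: "mean_load": lesioned -> the region's mean observed load.
    embedding: str = "ablation"
    mean_loads: Optional[np.ndarray] = field(default=None, repr=False)
    max_loads: Optional[np.ndarray] = field(default=None, repr=False)

    def _embed(self, configs: np.ndarray) -> np.ndarray:
        """Binary configs (1 = intact) to graded percent-load features."""
        configs = np.atleast_2d(np.asarray(configs))
        if configs.shape[1] != len(self.region_set):
            raise ValueError(
                f"configuration length {configs.shape[1]} != "
                f"{len(self.region_set)} regions"
            )
        if not np.all(np.isin(configs, [0, 1])):
            raise ValueError("configuration entries must be 0 or 1")
        lesioned = 1.0 - configs.astype(float)
        if self.embedding == "ablation":
            return lesioned * 100.0
        if self.embedding == "max_load":
            if self.max_loads is None:
                raise ValueError("max_load embedding requires stored max loads")
            return lesioned * self.max_loads[None, :]
        if self.embedding == "mean_load":
            if self.mean_loads is None:
                raise ValueError("mean_load embedding requires stored mean loads")
            return lesioned * self.mean_loads[None, :]
        raise ValueError(f"unknown embedding {self.embedding!r}")

    def evaluate_configurations(self, configs: np.ndarray) -> np.ndarray:
        """Performance for each row of a (k, n_regions) binary matrix."""
        x = self._embed(configs)
        if self.output_mode == "class":
            return self.model.predict(x).astype(float)
        if self.output_mode == "proba":
            proba = self.model.predict_proba(x)
            classes = list(self.model.classes_)
            if 1 in classes:
                return proba[:, classes.index(1)]
            return np.zeros(len(x))  # model never saw the intact class
        raise ValueError(f"unknown output_mode {self.output_mode!r}")

    def evaluate_configuration(self, config: np.ndarray) -> float:
        """Performance of a single binary configuration (1 = intact)."""
        return float(self.evaluate_configurations(np.atleast_2d(config))[0])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = harmonic mean of precision TP/(TP+FP) and recall TP/(TP+FN).

    Algebraically equal to ``tp / (tp + (fp + fn) / 2)``.  When TP = 0 and
    either denominator vanishes, F1 is 0 by convention.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = tp + (fp + fn) / 2.0
    if denom == 0:
        return 0.0
    return tp / denom


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive_label: int) -> tuple[int, int, int, int]:
    pos = y_true == positive_label
    pred_pos = y_pred == positive_label
    tp = int(np.sum(pos & pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    return tp, fp, tn, fn


def _make_forest(params: dict, random_state: int) -> RandomForestClassifier:
    return RandomForestClassifier(**params, random_state=random_state, n_jobs=1)


# ---------------------------------------------------------------------------
# Hyperparameter optimisation
# ---------------------------------------------------------------------------

def optimize_hyperparameters(
    dataset: LesionDataset,
    grid: Optional[dict[str, list]] = None,
    seed: int = 0,
    n_splits: int = 5,
    positive_label: int = DEFAULT_POSITIVE_LABEL,
) -> PredictorSpec:
    """Exhaustive grid search maximising cross-validated F1.

    Every combination of the grid's candidate values is evaluated by
    stratified k-fold cross-validation (default k = 5) on loads →
    performance, scoring F1 on the deficit class.  Ties are broken by
    grid order, so the result is deterministic given the seed.
    """
    grid = dict(grid) if grid is not None else {k: list(v) for k, v in DEFAULT_GRID.items()}
    y = dataset.performance
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both outcome classes")

    fold_seed, fit_seed = spawn_seeds(seed, 2)
    n_splits = min(n_splits, int(np.min(np.bincount(y))))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(dataset.loads, y))

    keys = list(grid)
    best_score, best_params = -np.inf, None
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        tp = fp = fn = 0
        for train_idx, test_idx in folds:
            clf = _make_forest(params, fit_seed)
            clf.fit(dataset.loads[train_idx], y[train_idx])
            pred = clf.predict(dataset.loads[test_idx])
            dtp, dfp, _, dfn = _confusion(y[test_idx], pred, positive_label)
            tp, fp, fn = tp + dtp, fp + dfp, fn + dfn
        score = f1_score(tp, fp, fn)
        if score > best_score:  # strict: ties keep the earlier grid point
            best_score, best_params = score, params

    return PredictorSpec(grid=grid, chosen=best_params, seed=seed, cv_score=best_score)


def train(
    dataset: LesionDataset,
    spec: PredictorSpec,
    output_mode: str = "class",
    embedding: str = "ablation",
    random_state: Optional[int] = None,
) -> SurrogateModel:
    """Fit the forest on graded loads (percent) against binary performance.

    The feature order is the region-set order; the RoB column is an
    ordinary feature.  ``random_state`` defaults to the spec's seed.
    """
    y = dataset.performance
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both outcome classes")
    rs = spec.seed if random_state is None else random_state
    clf = _make_forest(spec.chosen, rs)
    clf.fit(dataset.loads, y)
    return SurrogateModel(
        model=clf,
        region_set=dataset.region_set,
        output_mode=output_mode,
        embedding=embedding,
        mean_loads=dataset.loads.mean(axis=0),
        max_loads=dataset.loads.max(axis=0),
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def loo_accuracy(
    dataset: LesionDataset,
    spec: PredictorSpec,
    seed: int = 0,
    positive_label: int = DEFAULT_POSITIVE_LABEL,
    _labels: Optional[np.ndarray] = None,
) -> PredictorEvaluation:
    """Leave-one-out cross-validated accuracy, confusion counts and F1.

    Each patient is predicted by a forest trained on the other n−1.  A
    fold whose training labels collapse to one class is still trained and
    predicts that sole class (logged).
    """
    y = dataset.performance if _labels is None else np.asarray(_labels)
    n = dataset.n_patients
    if n < 3:
        raise ValueError("leave-one-out evaluation needs at least 3 patients")
    fit_seed = spawn_seeds(seed, 1)[0]

    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            logger.info("LOO fold %d has a single training class", i)
        clf = _make_forest(spec.chosen, fit_seed)
        clf.fit(dataset.loads[mask], y_train)
        preds[i] = int(clf.predict(dataset.loads[i : i + 1])[0])
        mask[i] = True

    tp, fp, tn, fn = _confusion(y, preds, positive_label)
    return PredictorEvaluation(
        loo_accuracy=(tp + tn) / n,
        f1=f1_score(tp, fp, fn),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        positive_label=positive_label,
    )


def chance_level(
    dataset: LesionDataset,
    spec: PredictorSpec,
    n_shuffles: int = 20,
    seed: int = 0,
) -> float:
    """Shuffled-label chance accuracy of the surrogate.

    The true binary scores are permuted across patients and the LOO
    accuracy recomputed; the mean over ``n_shuffles`` permutations is the
    accuracy of an arbitrary classifier on this cohort, which concentrates
    near the majority-class proportion.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng_seed, *loo_seeds = spawn_seeds(seed, n_shuffles + 1)
    rng = np.random.default_rng(rng_seed)
    accs = []
    for k in range(n_shuffles):
        shuffled = rng.permutation(dataset.performance)
        ev = loo_accuracy(dataset, spec, seed=loo_seeds[k], _labels=shuffled)
        accs.append(ev.loo_accuracy)
    return float(np.mean(accs))
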