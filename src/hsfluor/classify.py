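"""Balanced feature tables and the model-selection/evaluation protocol.

Four tasks are supported: tissue type, tumor margin (solid tumor /
infiltrating zone / reactively altered brain tissue), WHO grade, and IDH
mutation status.  The protocol:

* features are fluorophore abundance vectors of 1-3 spatially nearby blocks
  of one biopsy, concatenated (``pixels_per_sample``);
* classes are balanced to exactly ``samples_per_class`` rows; a class with
  fewer available blocks than that is excluded from the task;
* the table is split 80/20 (stratified; optionally grouped by biopsy), models
  and hyperparameters are ranked by 5-fold cross-validated accuracy on the
  training set, and the best model is evaluated once on the test set with
  accuracy, per-class one-vs-rest ROC/AUC (macro-averaged) and a confusion
  matrix;
* under the WHO-2021 revision, IDH-wildtype anaplastic astrocytomas are
  relabeled as glioblastoma before tissue-type training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .exceptions import TaskInfeasibleError
from .simulate import SimulatedDataset
from .spectral import FLUOROPHORES

__all__ = [
    "SAMPLES_PER_CLASS_PRESETS",
    "PIXELS_PER_SAMPLE_CHOICES",
    "ModelSpec",
    "GridEntry",
    "FeatureTable",
    "EvaluationReport",
    "relabel_who2021",
    "build_feature_table",
    "split_train_test",
    "table1_grids",
    "compact_grids",
    "make_estimator",
    "cross_validate_grid",
    "select_and_fit",
    "evaluate",
]

#: Published dataset-variant grids: samples-per-class choices per task
#: (IDH uses all available samples per class) and pixels-per-sample choices.
SAMPLES_PER_CLASS_PRESETS: dict[str, list[int] | str] = {
    "tissue_type": [300, 500, 800],
    "margin": [1000, 3000, 5000],
    "who_grade": [500, 1500, 3000],
    "idh": "all",
}
PIXELS_PER_SAMPLE_CHOICES = (1, 2, 3)


def relabel_who2021(
    records: pd.DataFrame,
    type_col: str = "tissue_type",
    idh_col: str = "idh",
) -> tuple[pd.DataFrame, int]:
    """Apply the WHO-2021 rule: (AA, IDH-wildtype) becomes GB.

    Returns the relabeled copy and the number of records changed; all other
    records (including AA with mutant or unknown IDH status) are untouched.
    """
    out = records.copy()
    hit = (out[type_col] == "AA") & (out[idh_col] == "wildtype")
    out.loc[hit, type_col] = "GB"
    return out, int(hit.sum())


@dataclass
class FeatureTable:
    """Balanced (m, 5 * pixels_per_sample) feature matrix with labels."""

    features: np.ndarray
    labels: np.ndarray
    biopsy_ids: np.ndarray
    pixels_per_sample: int
    samples_per_class: int
    included_classes: tuple[str, ...]
    excluded_classes: tuple[str, ...]
    seed: int
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.biopsy_ids = np.asarray(self.biopsy_ids)
        if not self.feature_names:
            self.feature_names = tuple(
                f"{name}_px{p + 1}"
                for p in range(self.pixels_per_sample)
                for name in FLUOROPHORES
            )

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.feature_names))
        frame.insert(0, "sample_id", [f"S{i:06d}" for i in range(len(self))])
        frame.insert(1, "biopsy_id", self.biopsy_ids)
        frame.insert(2, "label", self.labels)
        return frame


def _neighbor_features(
    coords: np.ndarray, abundances: np.ndarray, anchor: int, k: int
) -> np.ndarray:
    """Concatenate the anchor block with its k-1 nearest blocks (tile distance,
    ties broken row-major)."""
    if k == 1:
        return abundances[anchor]
    d = np.hypot(*(coords - coords[anchor]).T)
    order = np.lexsort((coords[:, 1], coords[:, 0], d))
    order = order[order != anchor][: k - 1]
    return np.concatenate([abundances[anchor]] + [abundances[o] for o in order])


def build_feature_table(
    dataset: SimulatedDataset | pd.DataFrame,
    pixels_per_sample: int = 1,
    samples_per_class: int | str = 300,
    seed: int = 0,
    exclude: Sequence[str] = (),
    label_col: str = "label",
) -> FeatureTable:
    """Draw a balanced feature table from block-level abundances.

    Anchor blocks are sampled uniformly without replacement within each class;
    for ``pixels_per_sample > 1`` the anchor's nearest blocks from the same
    biopsy are appended.  A class with fewer available blocks than
    ``samples_per_class`` is excluded; ``samples_per_class="all"`` uses the
    size of the smallest surviving class.
    """
    blocks = dataset.blocks if isinstance(dataset, SimulatedDataset) else dataset
    blocks = blocks[~blocks[label_col].isin(exclude)]
    counts = blocks[label_col].value_counts()
    if samples_per_class == "all":
        spc = int(counts.min())
    else:
        spc = int(samples_per_class)
    included = tuple(sorted(c for c in counts.index if counts[c] >= spc))
    excluded = tuple(sorted(c for c in counts.index if counts[c] < spc))
    if len(included) < 2:
        raise TaskInfeasibleError(
            f"only {len(included)} class(es) have >= {spc} blocks; task infeasible"
        )
    rng = np.random.default_rng(seed)
    ab_cols = [f"c_{n}" for n in FLUOROPHORES]
    feats, labs, bids = [], [], []
    # per-biopsy coordinate/abundance caches for neighbor lookup
    by_biopsy: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in included:
        sub = blocks[blocks[label_col] == cls]
        idx = rng.choice(len(sub), size=spc, replace=False)
        chosen = sub.iloc[np.sort(idx)]
        if pixels_per_sample == 1:
            feats.extend(chosen[ab_cols].to_numpy(dtype=float))
        else:
            for row_idx, bid in zip(chosen.index, chosen["biopsy_id"]):
                if bid not in by_biopsy:
                    bb = blocks[blocks["biopsy_id"] == bid]
                    by_biopsy[bid] = (
                        bb[["tile_row", "tile_col"]].to_numpy(dtype=float),
                        bb[ab_cols].to_numpy(dtype=float),
                        bb.index.to_numpy(),
                    )
                coords, ab, index = by_biopsy[bid]
                anchor = int(np.flatnonzero(index == row_idx)[0])
                feats.append(_neighbor_features(coords, ab, anchor, pixels_per_sample))
        labs.extend([cls] * spc)
        bids.extend(chosen["biopsy_id"].tolist())
    return FeatureTable(
        features=np.array(feats),
        labels=np.array(labs),
        biopsy_ids=np.array(bids),
        pixels_per_sample=pixels_per_sample,
        samples_per_class=spc,
        included_classes=included,
        excluded_classes=excluded,
        seed=seed,
    )


def split_train_test(
    table: FeatureTable,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_by_biopsy: bool = False,
) -> tuple[FeatureTable, FeatureTable]:
    """80/20 split, stratified by class; optionally grouped so that no biopsy
    spans the train/test boundary (grouping makes stratification approximate)."""
    if len(table) == 0:
        raise ValueError("empty feature table")
    idx = np.arange(len(table))
    if group_by_biopsy:
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        train_idx, test_idx = next(splitter.split(idx, table.labels, groups=table.biopsy_ids))
    else:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed, stratify=table.labels
        )

    def _subset(sel: np.ndarray) -> FeatureTable:
        return replace(
            table,
            features=table.features[sel],
            labels=table.labels[sel],
            biopsy_ids=table.biopsy_ids[sel],
        )

    return _subset(train_idx), _subset(test_idx)


@dataclass(frozen=True)
class ModelSpec:
    """One (algorithm, hyperparameter) combination."""

    algorithm: str
    params: tuple[tuple[str, object], ...]

    @classmethod
    def of(cls, algorithm: str, **params) -> "ModelSpec":
        return cls(algorithm, tuple(sorted(params.items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.algorithm}({inner})"


def table1_grids() -> list[ModelSpec]:
    """The full published hyperparameter grid for the five algorithm families."""
    specs: list[ModelSpec] = []
    for n_trees in (50, 75, 100, 125, 150):
        for crit in ("gini", "entropy", "log_loss"):
            for mss in (2, 3, 4):
                for mf in ("sqrt", "log2", None):
                    specs.append(ModelSpec.of(
                        "random_forest", n_estimators=n_trees, criterion=crit,
                        min_samples_split=mss, max_features=mf,
                    ))
    for k in (3, 5, 7, 9):
        for w in ("uniform", "distance"):
            for p in (1, 2):
                specs.append(ModelSpec.of("knn", n_neighbors=k, weights=w, p=p))
    for kernel in ("rbf", "linear", "poly", "sigmoid"):
        specs.append(ModelSpec.of("svm", kernel=kernel))
    for layers in (1, 2, 3):
        for neurons in (25, 50, 100, 150):
            for solver in ("adam", "lbfgs"):
                specs.append(ModelSpec.of(
                    "mlp", hidden_layers=layers, neurons=neurons, solver=solver,
                ))
    specs.append(ModelSpec.of("adaboost", n_estimators=50, learning_rate=1.0))
    return specs


def compact_grids() -> list[ModelSpec]:
    """A small representative grid for demos and smoke-scale runs."""
    return [
        ModelSpec.of("random_forest", n_estimators=100, criterion="gini",
                     min_samples_split=2, max_features="sqrt"),
        ModelSpec.of("random_forest", n_estimators=50, criterion="entropy",
                     min_samples_split=2, max_features="sqrt"),
        ModelSpec.of("knn", n_neighbors=5, weights="uniform", p=2),
        ModelSpec.of("mlp", hidden_layers=1, neurons=50, solver="adam"),
    ]


def make_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for one grid entry."""
    p = spec.param_dict
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], criterion=p["criterion"],
            min_samples_split=p["min_samples_split"], max_features=p["max_features"],
            random_state=seed, n_jobs=1,
        )
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"], weights=p["weights"],
                                    p=p["p"])
    if spec.algorithm == "svm":
        return SVC(kernel=p["kernel"], probability=False, random_state=seed)
    if spec.algorithm == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(p["neurons"],) * p["hidden_layers"],
            activation="relu", solver=p["solver"], momentum=0.9, nesterovs_momentum=True,
            max_iter=400, random_state=seed,
        )
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(
            n_estimators=p["n_estimators"], learning_rate=p["learning_rate"],
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")


@dataclass(frozen=True)
class GridEntry:
    spec: ModelSpec
    mean_cv_accuracy: float
    std_cv_accuracy: float
    order: int  # registration order within the grid


def cross_validate_grid(
    train: FeatureTable,
    grids: Iterable[ModelSpec],
    k: int = 5,
    seed: int = 0,
) -> list[GridEntry]:
    """Rank every grid entry by mean k-fold cross-validated accuracy.

    Folds are stratified and seeded; if a degenerate (single-class) fold ever
    arises the split is redrawn with a new seed and a warning.  Ties are
    broken by fewer hyperparameters, then registration order.
    """
    counts = pd.Series(train.labels).value_counts()
    if counts.min() < k:
        raise ValueError(f"need at least {k} samples per class for {k}-fold CV")
    entries: list[GridEntry] = []
    for order, spec in enumerate(grids):
        fold_seed = seed
        for attempt in range(3):
            cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # MLP convergence chatter
                    scores = cross_val_score(
                        make_estimator(spec, seed), train.features, train.labels, cv=cv
                    )
                break
            except ValueError:
                warnings.warn(f"degenerate fold for {spec.describe()}; refolding")
                fold_seed += 1000003
        else:  # pragma: no cover - three failed refolds
            raise RuntimeError(f"could not fold data for {spec.describe()}")
        entries.append(GridEntry(spec, float(scores.mean()), float(scores.std()), order))
    entries.sort(key=lambda e: (-e.mean_cv_accuracy, len(e.spec.params), e.order))
    return entries


def select_and_fit(train: FeatureTable, ranked: Sequence[GridEntry], seed: int = 0):
    """Refit the top-ranked model on the full training set."""
    best = ranked[0]
    model = make_estimator(best.spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(train.features, train.labels)
    return model


@dataclass
class EvaluationReport:
    """Held-out test metrics for one trained model."""

    accuracy: float
    classes: tuple[str, ...]
    auc_per_class: dict[str, float]
    macro_auc: float
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    confusion: np.ndarray  # rows = true class, cols = predicted
    model_desc: str = ""
    split_seed: int = 0
    missing_test_classes: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "classes": list(self.classes),
            "auc_per_class": {k: (None if np.isnan(v) else v)
                              for k, v in self.auc_per_class.items()},
            "macro_auc": self.macro_auc,
            "confusion_matrix": self.confusion.tolist(),
            "model": self.model_desc,
            "split_seed": self.split_seed,
            "missing_test_classes": list(self.missing_test_classes),
        }


def _class_scores(model, features: np.ndarray) -> np.ndarray:
    """(n, K) per-class scores from probabilities or decision values."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(features)
    scores = model.decision_function(features)
    if scores.ndim == 1:  # binary decision function
        return np.column_stack([-scores, scores])
    return scores


def evaluate(model, test: FeatureTable, model_desc: str = "", split_seed: int = 0
             ) -> EvaluationReport:
    """Test-set accuracy, one-vs-rest ROC/AUC per class, macro AUC, confusion."""
    classes = tuple(model.classes_)
    y_pred = model.predict(test.features)
    scores = _class_scores(model, test.features)
    acc = float(np.mean(y_pred == test.labels))
    cm = confusion_matrix(test.labels, y_pred, labels=list(classes))
    aucs, curves, missing = {}, {}, []
    for i, cls in enumerate(classes):
        pos = test.labels == cls
        if pos.all() or not pos.any():
            missing.append(cls)
            aucs[cls] = float("nan")
            curves[cls] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, i])
        aucs[cls] = float(auc(fpr, tpr))
        curves[cls] = (fpr, tpr)
    finite = [v for v in aucs.values() if np.isfinite(v)]
    macro = float(np.mean(finite)) if finite else float("nan")
    if missing:
        warnings.warn(f"classes absent from the test set, ROC undefined: {missing}")
    return EvaluationReport(
        accuracy=acc, classes=tuple(str(c) for c in classes),
        auc_per_class={str(k): v for k, v in aucs.items()}, macro_auc=macro,
        roc_curves={str(k): v for k, v in curves.items()}, confusion=cm,
        model_desc=model_desc, split_seed=split_seed,
        missing_test_classes=tuple(str(m) for m in missing),
    )
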