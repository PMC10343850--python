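"""Modified cascade forest with out-of-fold class-vector augmentation.

Each cascade level holds four diverse tree ensembles: a random forest, a
completely random tree forest (extra-trees), XGBoost and LightGBM, 100 trees
each (400 trees per level).  Every estimator is fitted as five stratified
fold-models; a training sample's class vector is produced by the fold-model
that did not see it (out-of-fold stacking), giving an 8-dimensional augmented
block per level (4 estimators x 2 class probabilities, class order [0, 1]).

Level t consumes [original features | level t-1's 8 augmented columns].
Growth is validation-driven: a stratified validation split is carved from the
training data, each level is scored by AUC on it, and growth stops when no
level improves the best score by more than ``tol`` for ``patience``
consecutive levels; the model then rolls back to the best level count.

The final predictor depends on the mode:

- ``cfsaemda``: a polynomial-kernel SVM fitted on [features | augmented
  block] of the best level, with cross-validated sigmoid probability
  calibration;
- ``model2``: mean of the four estimators' positive-class probabilities
  (same diverse bank, averaging predictor);
- ``model1``: averaging predictor over the classic bank of two random
  forests and two completely random tree forests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "LevelSpec",
    "FittedLevel",
    "CascadeConfig",
    "CascadeModel",
    "fit_level",
    "transform_level",
    "fit_cascade",
    "predict_proba",
]

DIVERSE_BANK = ("random_forest", "extra_trees", "xgboost", "lightgbm")
CLASSIC_BANK = ("random_forest", "random_forest", "extra_trees", "extra_trees")


@dataclass
class LevelSpec:
    """Estimator bank of one cascade level: names, tree count, inner folds."""

    estimators: tuple[str, ...] = DIVERSE_BANK
    trees_per_estimator: int = 100
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if len(self.estimators) != 4:
            raise ValueError("a cascade level holds exactly 4 estimators")

    @property
    def trees_per_level(self) -> int:
        return len(self.estimators) * self.trees_per_estimator


def _make_estimator(name: str, trees: int, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=trees, n_jobs=1, random_state=seed)
    if name == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=trees, max_features=1, n_jobs=1, random_state=seed
        )
    if name == "xgboost":
        return XGBClassifier(
            n_estimators=trees,
            n_jobs=1,
            random_state=seed,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
    if name == "lightgbm":
        return LGBMClassifier(
            n_estimators=trees,
            n_jobs=1,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
    raise ValueError(f"unknown estimator {name!r}")


@dataclass
class FittedLevel:
    """One fitted level: per-estimator lists of fold-models plus bookkeeping."""

    spec: LevelSpec
    fold_models: list[list]  # [estimator][fold]
    fold_assignment: np.ndarray  # training-sample -> fold index
    n_features_in: int

    @property
    def n_trees(self) -> int:
        return self.spec.trees_per_level


def fit_level(
    X: np.ndarray, y: np.ndarray, spec: LevelSpec | None = None, seed: int = 0
) -> tuple[FittedLevel, np.ndarray]:
    """Fit the four estimators with inner stratified CV; return OOF class vectors.

    The returned matrix has one 2-column probability block per estimator
    (8 columns total); each row comes from the fold-model whose training fold
    excluded that sample.
    """
    spec = spec or LevelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    if n < spec.inner_folds:
        raise ValueError("fewer samples than inner folds")
    skf = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    assignment = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(folds):
        assignment[test_idx] = f

    oof = np.zeros((n, 2 * len(spec.estimators)))
    fold_models: list[list] = []
    for e, name in enumerate(spec.estimators):
        models = []
        for f, (train_idx, test_idx) in enumerate(folds):
            est = _make_estimator(name, spec.trees_per_estimator, seed + 1000 * e + f)
            ytr = y[train_idx]
            if len(np.unique(ytr)) < 2:
                raise ValueError("a stratified fold lost a class")
            est.fit(X[train_idx], ytr)
            proba = _proba_2col(est, X[test_idx])
            oof[test_idx, 2 * e : 2 * e + 2] = proba
            models.append(est)
        fold_models.append(models)
    level = FittedLevel(
        spec=spec, fold_models=fold_models, fold_assignment=assignment, n_features_in=X.shape[1]
    )
    return level, oof


def _proba_2col(est, X: np.ndarray) -> np.ndarray:
    """Class probabilities in fixed column order [P(y=0), P(y=1)]."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*feature names.*")
        proba = est.predict_proba(X)
    classes = np.asarray(est.classes_)
    out = np.zeros((X.shape[0], 2))
    for k, cls in enumerate(classes):
        out[:, int(cls)] = proba[:, k]
    return out


def transform_level(level: FittedLevel, X_new: np.ndarray) -> np.ndarray:
    """Class vectors on new data: each estimator averages its 5 fold-models."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != level.n_features_in:
        raise ValueError(
            f"expected {level.n_features_in} feature columns, got {X_new.shape[1]}"
        )
    blocks = []
    for models in level.fold_models:
        acc = np.zeros((X_new.shape[0], 2))
        for est in models:
            acc += _proba_2col(est, X_new)
        blocks.append(acc / len(models))
    return np.hstack(blocks)


@dataclass
class CascadeConfig:
    """Cascade hyperparameters; every source of randomness derives from ``seed``."""

    mode: str = "cfsaemda"  # cfsaemda | model1 | model2
    max_levels: int = 10
    patience: int = 1
    val_fraction: float = 0.2
    tol: float = 1e-3
    trees_per_estimator: int = 100
    inner_folds: int = 5
    svm_input: str = "concat"  # concat | augmented_only
    svm_degree: int = 3
    svm_C: float = 1.0
    svm_coef0: float = 1.0  # inhomogeneous polynomial kernel (gamma<x,x'> + 1)^d
    seed: int = 0

    def level_spec(self) -> LevelSpec:
        bank = CLASSIC_BANK if self.mode == "model1" else DIVERSE_BANK
        return LevelSpec(
            estimators=bank,
            trees_per_estimator=self.trees_per_estimator,
            inner_folds=self.inner_folds,
        )


@dataclass
class CascadeModel:
    """Fitted cascade: retained levels, growth log, and the final predictor."""

    levels: list[FittedLevel]
    config: CascadeConfig
    growth_log: list[dict] = field(default_factory=list)
    svm: SVC | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _positive_mean(aug: np.ndarray) -> np.ndarray:
    """Averaging predictor: mean of the four positive-class entries."""
    return aug[:, 1::2].mean(axis=1)


def fit_cascade(X: np.ndarray, y: np.ndarray, config: CascadeConfig | None = None) -> CascadeModel:
    """Grow the cascade with validation-driven stopping and roll back to the best depth."""
    config = config or CascadeConfig()
    if config.mode not in {"cfsaemda", "model1", "model2"}:
        raise ValueError(f"unknown mode {config.mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    spec = config.level_spec()

    idx = np.arange(X.shape[0])
    grow_idx, val_idx = train_test_split(
        idx,
        test_size=config.val_fraction,
        stratify=y,
        random_state=config.seed,
        shuffle=True,
    )
    Xg, yg = X[grow_idx], y[grow_idx]
    Xv, yv = X[val_idx], y[val_idx]

    levels: list[FittedLevel] = []
    growth_log: list[dict] = []
    oof_augments: list[np.ndarray] = []
    val_augments: list[np.ndarray] = []
    best_score, best_depth, stall = -np.inf, 0, 0
    aug_g = aug_v = None
    for t in range(1, config.max_levels + 1):
        Xg_in = Xg if aug_g is None else np.hstack([Xg, aug_g])
        Xv_in = Xv if aug_v is None else np.hstack([Xv, aug_v])
        level, oof = fit_level(Xg_in, yg, spec, seed=config.seed + 7919 * t)
        aug_v_new = transform_level(level, Xv_in)
        score = float(roc_auc_score(yv, _positive_mean(aug_v_new)))
        if not np.isfinite(score):
            raise FloatingPointError("non-finite validation metric")
        levels.append(level)
        oof_augments.append(oof)
        val_augments.append(aug_v_new)
        improved = score > best_score + config.tol
        growth_log.append({"level": t, "val_auc": score, "improved": improved})
        if improved:
            best_score, best_depth, stall = score, t, 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        aug_g, aug_v = oof, aug_v_new

    # roll back to the best depth; its validation score is the max observed
    levels = levels[:best_depth]
    for entry in growth_log:
        entry["retained"] = entry["level"] <= best_depth

    model = CascadeModel(levels=levels, config=config, growth_log=growth_log)
    if config.mode == "cfsaemda":
        # unbiased augmented block at the best depth: OOF vectors for the
        # growth rows, fold-averaged transforms for the validation rows
        aug_all = np.empty((X.shape[0], 8))
        aug_all[grow_idx] = oof_augments[best_depth - 1]
        aug_all[val_idx] = val_augments[best_depth - 1]
        rep = np.hstack([X, aug_all]) if config.svm_input == "concat" else aug_all
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            svm = SVC(
                kernel="poly",
                degree=config.svm_degree,
                C=config.svm_C,
                coef0=config.svm_coef0,
                probability=True,
                random_state=config.seed,
            )
            svm.fit(rep, y)
        model.svm = svm
    return model


def _cascade_augment(model: CascadeModel, X_new: np.ndarray) -> np.ndarray:
    aug = None
    for level in model.levels:
        X_in = X_new if aug is None else np.hstack([X_new, aug])
        aug = transform_level(level, X_in)
    if aug is None:
        raise ValueError("cascade has no levels")
    return aug


def predict_proba(model: CascadeModel, X_new: np.ndarray) -> np.ndarray:
    """Positive-class scores in [0,1] for new samples."""
    X_new = np.asarray(X_new, dtype=float)
    aug = _cascade_augment(model, X_new)
    if model.config.mode == "cfsaemda":
        rep = np.hstack([X_new, aug]) if model.config.svm_input == "concat" else aug
        return model.svm.predict_proba(rep)[:, 1]
    return _positive_mean(aug)
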