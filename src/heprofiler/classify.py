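"""Random-forest classification with leave-one-out cross-validation.

The classifier is a bagged ensemble of 50 decision trees (bootstrap
resampling with replacement, sqrt(n_features) candidate features per
split, unlimited depth).  Performance is estimated by LOOCV: n models,
each trained without one sample and asked for that sample's class
probabilities, so every prediction is out-of-training.  Feature
importances (mean impurity decrease, normalized to sum 1) are collected
from every fold and summarized by mean and standard deviation.

AUC is computed by the rank (Mann-Whitney concordance) formulation with
ties counted 1/2 — identical to the area under the empirical ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ForestConfig",
    "LoocvResult",
    "RocSummary",
    "train_forest",
    "loocv",
    "roc_auc",
    "multiclass_eval",
]


@dataclass
class ForestConfig:
    """Ensemble configuration (defaults follow the study setup: 50 trees,
    bootstrap aggregation)."""

    n_trees: int = 50
    bootstrap: bool = True
    features_per_split: str | int | float = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class LoocvResult:
    """Held-out class probabilities and per-fold importances."""

    sample_ids: list[str]
    classes: list[str]
    probabilities: np.ndarray  # (n, n_classes) held-out probabilities
    true_labels: np.ndarray
    importances: np.ndarray  # (n_models, n_features)
    feature_names: list[str]

    @property
    def n_models(self) -> int:
        return self.importances.shape[0]

    @property
    def mean_importance(self) -> np.ndarray:
        return self.importances.mean(axis=0)

    @property
    def sd_importance(self) -> np.ndarray:
        return self.importances.std(axis=0)

    def importance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                feature=self.feature_names,
                mean_importance=self.mean_importance,
                sd_importance=self.sd_importance,
            )
        ).sort_values("mean_importance", ascending=False, ignore_index=True)

    def predictions_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=[f"p_{c}" for c in self.classes])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "true", self.true_labels)
        return df


@dataclass
class RocSummary:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _impute_medians(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    bad = ~np.isfinite(X)
    if bad.any():
        X[bad] = np.take(medians, np.nonzero(bad)[1])
    return X


def _fit(X: np.ndarray, y: np.ndarray, cfg: ForestConfig, seed: int) -> RandomForestClassifier:
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        bootstrap=cfg.bootstrap,
        max_features=cfg.features_per_split,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def train_forest(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: ForestConfig | None = None,
) -> RandomForestClassifier:
    """Fit the bagged tree ensemble on the full data.

    Non-finite feature values are imputed with column medians before the
    fit.  Raises on single-class label vectors.
    """
    cfg = config or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need >= 2 classes")
    med = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    return _fit(_impute_medians(X, med), y, cfg, cfg.seed)


def _fold_seed(root_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(entropy=root_seed, spawn_key=(fold,)).generate_state(1)[0])


def loocv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: ForestConfig | None = None,
    sample_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation: n folds, n trained models.

    Each fold imputes missing values from its own training medians and
    derives its RNG seed from (root seed, fold index), so folds are
    reproducible and independent.  A fold whose training labels collapse
    to one class emits a warning and predicts that class.
    """
    cfg = config or ForestConfig()
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        feature_names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs >= 3 samples")
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    classes = sorted(np.unique(y).tolist())
    class_idx = {c: j for j, c in enumerate(classes)}

    probs = np.zeros((n, len(classes)))
    imps = np.zeros((n, X.shape[1]))
    for f in range(n):
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        Xtr, ytr = X[mask], y[mask]
        med = np.nanmedian(np.where(np.isfinite(Xtr), Xtr, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xtr = _impute_medians(Xtr, med)
        Xte = _impute_medians(X[f : f + 1], med)
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"fold {f}: single-class training set")
            probs[f, class_idx[ytr[0]]] = 1.0
            continue
        model = _fit(Xtr, ytr, cfg, _fold_seed(cfg.seed, f))
        p = model.predict_proba(Xte)[0]
        for c, pc in zip(model.classes_, p):
            probs[f, class_idx[c]] = pc
        imps[f] = model.feature_importances_
    return LoocvResult(
        sample_ids=sample_ids,
        classes=[str(c) for c in classes],
        probabilities=probs,
        true_labels=y,
        importances=imps,
        feature_names=feature_names,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocSummary:
    """ROC curve and AUC for binary labels (positive = 1 / True).

    AUC uses the Mann-Whitney rank formulation; tied scores count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined AUC: need both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = np.cumsum(~sorted_pos)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocSummary(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc))


def multiclass_eval(
    probs: np.ndarray,
    labels: np.ndarray,
    classes: list[str],
) -> tuple[pd.DataFrame, dict[str, RocSummary]]:
    """Confusion matrix (rows = true) and one-vs-rest ROC per class.

    Hard labels are the maximum-probability class; exact ties resolve to
    the lowest class index.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pred_idx = np.argmax(probs, axis=1)  # argmax takes the first (lowest) on ties
    pred = np.asarray(classes)[pred_idx]
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, pred):
        cm.loc[t, p] += 1
    rocs = {
        c: roc_auc(probs[:, j], labels == c)
        for j, c in enumerate(classes)
        if 0 < (labels == c).sum() < len(labels)
    }
    return cm, rocs
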