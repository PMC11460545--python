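"""Infection/ischemia classification on handcrafted features.

Two independent binary scorers — one for infection, one for ischemia — are
trained on the feature vectors of cropped wounds.  Each scorer is a pipeline
of standardization, PCA (component count selected by stratified 5-fold
cross-validation over a small grid, 128 by default when the search is
skipped) and a probabilistic estimator: an RBF-kernel SVM (default),
gradient boosting (100 trees of depth 3) or a three-hidden-layer MLP.

The two marginal probabilities are combined into a four-way posterior under
an independence assumption:

    P(none)      = (1 - P(inf)) * (1 - P(isch))
    P(inf only)  = P(inf) * (1 - P(isch))
    P(isch only) = (1 - P(inf)) * P(isch)
    P(both)      = P(inf) * P(isch)

which always sums to 1.  Hard binary labels use a 0.5 threshold, with ties
(p = 0.5 exactly) classified positive.

Because positive ischemia cases are rare, the training set (never the
validation set) can be rebalanced by minority upsampling: each minority
image is kept and supplemented with factor - 1 randomly augmented copies
(rotation, flips, brightness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "FourWayProbabilities",
    "ClassifierConfig",
    "ClassifierModel",
    "ClassificationReport",
    "FOUR_WAY_CLASSES",
    "four_way_combine",
    "label_from_probability",
    "upsample_minority",
    "augment_image",
    "fit_classifier",
    "predict_proba",
    "classification_metrics",
    "four_way_metrics",
    "save_model",
    "load_model",
]

FOUR_WAY_CLASSES = ("none", "infection_only", "ischemia_only", "both")


# ---------------------------------------------------------------------------
# four-way combiner

@dataclass(frozen=True)
class FourWayProbabilities:
    p_none: float
    p_inf_only: float
    p_isch_only: float
    p_both: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_none, self.p_inf_only, self.p_isch_only, self.p_both)

    @property
    def predicted_class(self) -> str:
        return FOUR_WAY_CLASSES[int(np.argmax(self.as_tuple()))]

    def to_dict(self) -> dict:
        return {
            "p_none": self.p_none,
            "p_inf_only": self.p_inf_only,
            "p_isch_only": self.p_isch_only,
            "p_both": self.p_both,
            "label": self.predicted_class,
        }


def four_way_combine(p_inf: float, p_isch: float) -> FourWayProbabilities:
    """Combine independent infection/ischemia probabilities into the
    four-way posterior {none, infection only, ischemia only, both}."""
    for name, p in (("p_inf", p_inf), ("p_isch", p_isch)):
        if not (np.isfinite(p) and 0.0 <= p <= 1.0):
            raise InvalidInputError(f"{name}={p} outside [0, 1]")
    return FourWayProbabilities(
        p_none=(1.0 - p_inf) * (1.0 - p_isch),
        p_inf_only=p_inf * (1.0 - p_isch),
        p_isch_only=(1.0 - p_inf) * p_isch,
        p_both=p_inf * p_isch,
    )


def label_from_probability(p: float, threshold: float = 0.5) -> int:
    """Hard binary label; p == threshold classifies positive."""
    return int(p >= threshold)


# ---------------------------------------------------------------------------
# minority upsampling

def augment_image(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random augmentation: rotation (+-25 deg), flips, brightness scale."""
    from scipy.ndimage import rotate

    out = np.asarray(img, dtype=np.float64)
    angle = float(rng.uniform(-25.0, 25.0))
    out = rotate(out, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    scale = float(rng.uniform(0.8, 1.2))
    hi = 255.0 if np.asarray(img).max() > 1.0 else 1.0
    out = np.clip(out * scale, 0.0, hi)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        out = np.rint(out).astype(np.asarray(img).dtype)
    return out


def upsample_minority(
    samples: list[np.ndarray],
    labels: np.ndarray,
    factor: int = 6,
    seed: int = 0,
    minority_label: int = 1,
    augmenter=augment_image,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rebalance a labeled image set by augmenting the minority class.

    Every sample with ``minority_label`` appears ``factor`` times in the
    output: the original plus ``factor - 1`` augmented copies sharing its
    label.  Majority samples pass through untouched.  Apply to training data
    only — never to validation or test folds.
    """
    if factor < 1:
        raise InvalidInputError(f"factor must be >= 1, got {factor}")
    labels = np.asarray(labels)
    if len(samples) != len(labels):
        raise InvalidInputError("samples and labels differ in length")
    rng = np.random.default_rng(seed)
    out_samples: list[np.ndarray] = []
    out_labels: list[int] = []
    for img, lab in zip(samples, labels):
        out_samples.append(img)
        out_labels.append(int(lab))
        if lab == minority_label:
            for _ in range(factor - 1):
                out_samples.append(augmenter(img, rng))
                out_labels.append(int(lab))
    return out_samples, np.asarray(out_labels)


# ---------------------------------------------------------------------------
# classical pipeline

@dataclass(frozen=True)
class ClassifierConfig:
    estimator: str = "svm-rbf"  # svm-rbf | gradient-boosting | mlp
    pc_grid: tuple[int, ...] = (32, 64, 128, 256)
    n_components: int = 128  # used when select_by_cv is False
    select_by_cv: bool = True
    n_folds: int = 5
    seed: int = 0


@dataclass
class ClassifierModel:
    pipeline: object  # sklearn Pipeline: scaler -> PCA -> estimator
    config: ClassifierConfig
    n_components: int
    cv_scores: dict[int, float]
    n_features: int
    config_hash: str | None = None


def _make_estimator(cfg: ClassifierConfig):
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if cfg.estimator == "svm-rbf":
        return SVC(kernel="rbf", probability=True, random_state=cfg.seed)
    if cfg.estimator == "gradient-boosting":
        return GradientBoostingClassifier(n_estimators=100, max_depth=3, random_state=cfg.seed)
    if cfg.estimator == "mlp":
        return MLPClassifier(hidden_layer_sizes=(128, 64, 32), max_iter=1000,
                             random_state=cfg.seed)
    raise InvalidInputError(f"unknown estimator {cfg.estimator!r}")


def _make_pipeline(cfg: ClassifierConfig, n_components: int):
    from sklearn.decomposition import PCA
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    return Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=n_components, random_state=cfg.seed)),
        ("clf", _make_estimator(cfg)),
    ])


def fit_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
    config_hash: str | None = None,
) -> ClassifierModel:
    """Fit standardize -> PCA -> estimator on a feature table.

    When ``cfg.select_by_cv`` the PCA component count is chosen by
    stratified ``n_folds``-fold cross-validation over ``cfg.pc_grid``
    (capped by the data size), keeping the grid value with the highest mean
    validation accuracy (ties favor fewer components); otherwise
    ``cfg.n_components`` is used directly.  Fully seeded and reproducible.
    """
    import warnings

    from sklearn.model_selection import StratifiedKFold, cross_val_score

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2:
        raise InvalidInputError("features must be a 2-D table")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("labels contain a single class")
    if counts.min() < 2:
        raise InvalidInputError("need at least 2 samples per class")
    if len(y) < cfg.n_folds:
        raise InvalidInputError(f"need at least n_folds={cfg.n_folds} samples")

    max_pc = min(X.shape[0] * (cfg.n_folds - 1) // cfg.n_folds, X.shape[1])
    cv_scores: dict[int, float] = {}
    with warnings.catch_warnings():
        # SVC(probability=True) = Platt scaling, our documented calibration;
        # newer sklearn flags the spelling, not the method
        warnings.filterwarnings("ignore", category=FutureWarning)
        if cfg.select_by_cv:
            grid = sorted({min(n, max_pc) for n in cfg.pc_grid})
            folds = min(cfg.n_folds, int(counts.min()))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
            best_n, best_score = grid[0], -1.0
            for n in grid:
                scores = cross_val_score(_make_pipeline(cfg, n), X, y, cv=skf,
                                         scoring="accuracy")
                cv_scores[n] = float(scores.mean())
                if cv_scores[n] > best_score:
                    best_n, best_score = n, cv_scores[n]
            n_components = best_n
        else:
            n_components = min(cfg.n_components, min(X.shape))
        pipe = _make_pipeline(cfg, n_components)
        pipe.fit(X, y)
    return ClassifierModel(pipe, cfg, n_components, cv_scores, X.shape[1], config_hash)


def predict_proba(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probabilities for a feature table (or one vector)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise InvalidInputError(
            f"feature length {X.shape[1]} does not match training layout {model.n_features}"
        )
    proba = model.pipeline.predict_proba(X)
    positive = list(model.pipeline.classes_).index(1)
    return proba[:, positive]


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "n": self.n,
        }


def classification_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> ClassificationReport:
    """Accuracy/precision/recall/F1 at the threshold plus ROC AUC.

    AUC is None (undefined) when only one class is present; the threshold
    metrics are still reported.
    """
    from sklearn.metrics import roc_auc_score

    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(p) != len(y):
        raise InvalidInputError("probabilities and labels differ in length")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = float(np.mean(pred == y))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    return ClassificationReport(accuracy, precision, recall, f1, auc, len(y))


def four_way_metrics(
    fourway: list[FourWayProbabilities],
    labels: list[str],
) -> dict:
    """Accuracy and macro-F1 of the argmax four-way classes."""
    if len(fourway) != len(labels):
        raise InvalidInputError("predictions and labels differ in length")
    for lab in labels:
        if lab not in FOUR_WAY_CLASSES:
            raise InvalidInputError(f"unknown four-way label {lab!r}")
    pred = [fw.predicted_class for fw in fourway]
    accuracy = float(np.mean([p == t for p, t in zip(pred, labels)]))
    f1s = []
    for cls in FOUR_WAY_CLASSES:
        tp = sum(1 for p, t in zip(pred, labels) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(pred, labels) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(pred, labels) if p != cls and t == cls)
        if tp + fp + fn == 0:
            continue  # class absent from both truth and prediction
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    return {"accuracy": accuracy, "macro_f1": float(np.mean(f1s)) if f1s else 0.0}


# ---------------------------------------------------------------------------
# persistence

_MODEL_FORMAT_VERSION = 1


def save_model(path, model: ClassifierModel) -> None:
    import joblib

    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> ClassifierModel:
    import joblib

    doc = joblib.load(path)
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise InvalidInputError(f"unsupported model format {doc.get('format_version')}")
    return doc["model"]
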