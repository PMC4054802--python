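"""Six-class facial-color recognition and its evaluation.

The classifier is a one-against-one RBF-kernel SVM (15 pairwise models for
6 classes) with (C, gamma) chosen by grid search over powers of two,
C in 2^-8..2^15 and gamma in 2^-8..2^8.  Complexion histograms are already
proportions in [0, 1], so no per-dimension rescaling is applied — rescaling
would destroy the color-proportion semantics.

Evaluation is leave-one-out cross-validation with the chromaticity bases
rebuilt per fold from the training images only (the held-out image never
contributes to base construction), features re-extracted under the fold's
bases, and the model refit.  Metrics are per-class one-vs-all
precision/recall, their micro (sample-pooled) and macro (class-averaged)
aggregates, and the F-score with beta = 1.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .bases import build_all_bases, image_dominant_pair
from .features import (
    DEFAULT_REFINED_BINNING,
    LuminanceBinning,
    assign_pixels,
    feature_length,
)
from .synthetic import BASE_CLASS_LABELS, CLASS_LABELS

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "ColorModel",
    "EvaluationReport",
    "train_svm",
    "predict",
    "metrics_from_confusion",
    "loocv_evaluate",
    "classifier_fusion_predict",
    "interval_sweep",
]

DEFAULT_C_GRID = [2.0**e for e in range(-8, 16)]
DEFAULT_GAMMA_GRID = [2.0**e for e in range(-8, 9)]


def _canonical_labels(labels) -> list[str]:
    present = set(labels)
    ordered = [l for l in CLASS_LABELS if l in present]
    extra = sorted(present - set(CLASS_LABELS))
    return ordered + extra


@dataclass
class ColorModel:
    """A trained one-against-one RBF-SVM plus the feature context it expects."""

    svc: SVC
    classes: list[str]
    C: float
    gamma: float
    base_set: object | None = None
    binning: LuminanceBinning | None = None

    @property
    def n_pairwise_models(self) -> int:
        L = len(self.classes)
        return L * (L - 1) // 2

    def predict(self, features) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.svc.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match the trained "
                f"model ({self.svc.n_features_in_})"
            )
        idx = self.svc.predict(X)
        return np.asarray([self.classes[i] for i in idx])


def train_svm(
    features,
    labels,
    C_grid=None,
    gamma_grid=None,
    inner_folds: int = 5,
    seed: int = 0,
) -> ColorModel:
    """Grid-searched one-against-one RBF-SVM.

    (C, gamma) is selected by stratified inner cross-validation on the
    training set (ties: smaller C, then smaller gamma) and the final model
    is refit on all training data.  Features are used as-is.
    """
    X = np.asarray(features, dtype=float)
    y_labels = list(labels)
    classes = _canonical_labels(y_labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    to_idx = {c: i for i, c in enumerate(classes)}
    y = np.asarray([to_idx[l] for l in y_labels])

    C_grid = sorted(C_grid or DEFAULT_C_GRID)
    gamma_grid = sorted(gamma_grid or DEFAULT_GAMMA_GRID)

    min_count = np.bincount(y).min()
    folds = min(inner_folds, int(min_count))
    if folds < inner_folds:
        warnings.warn(
            f"smallest class has {min_count} members; inner folds reduced "
            f"to {folds}",
            stacklevel=2,
        )

    def make_svc(C, gamma):
        return SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")

    best = (-np.inf, None, None)
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        for C, gamma in itertools.product(C_grid, gamma_grid):
            correct = 0
            for tr, te in splits:
                svc = make_svc(C, gamma).fit(X[tr], y[tr])
                correct += int((svc.predict(X[te]) == y[te]).sum())
            score = correct / len(y)
            if score > best[0]:
                best = (score, C, gamma)
    else:
        for C, gamma in itertools.product(C_grid, gamma_grid):
            svc = make_svc(C, gamma).fit(X, y)
            score = float((svc.predict(X) == y).mean())
            if score > best[0]:
                best = (score, C, gamma)

    _, C, gamma = best
    svc = make_svc(C, gamma).fit(X, y)
    return ColorModel(svc=svc, classes=classes, C=C, gamma=gamma)


def predict(model: ColorModel, features) -> np.ndarray:
    """One-against-one voting prediction (labels in canonical order)."""
    return model.predict(features)


@dataclass
class EvaluationReport:
    """Confusion matrices (rows = actual, columns = predicted) and metrics."""

    labels: list[str]
    confusion_matrix: np.ndarray
    metrics: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion_matrix) / self.confusion_matrix.sum())

    @property
    def recall_matrix(self) -> np.ndarray:
        m = self.confusion_matrix.astype(float)
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, m / sums, 0.0)

    @property
    def precision_matrix(self) -> np.ndarray:
        m = self.confusion_matrix.astype(float)
        sums = m.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, m / sums, 0.0)

    def to_json(self, path=None) -> str:
        payload = {
            "labels": self.labels,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "accuracy": self.accuracy,
            **{
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.metrics.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def metrics_from_confusion(matrix) -> dict:
    """Per-class and micro/macro precision, recall and F (beta = 1).

    Micro quantities pool TP/FP/FN over classes; macro quantities average
    per-class values.  A class never predicted gets precision 0 (warned).
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    L = m.shape[0]
    tp = np.diag(m).astype(float)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp

    def safe_div(num, den, what):
        den = np.asarray(den, dtype=float)
        bad = den == 0
        if np.any(bad):
            warnings.warn(f"empty denominator in {what}; defining value as 0", stacklevel=3)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(bad, 0.0, num / np.where(bad, 1.0, den))

    precision = safe_div(tp, tp + fp, "per-class precision")
    recall = safe_div(tp, tp + fn, "per-class recall")

    def f_score(p, r):
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    micro_p = float(tp.sum() / (tp + fp).sum()) if (tp + fp).sum() else 0.0
    micro_r = float(tp.sum() / (tp + fn).sum()) if (tp + fn).sum() else 0.0
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    return {
        "per_class_precision": precision,
        "per_class_recall": recall,
        "per_class_f": np.array([f_score(p, r) for p, r in zip(precision, recall)]),
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f": f_score(micro_p, micro_r),
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f": f_score(macro_p, macro_r),
        "total_accuracy": float(tp.sum() / m.sum()) if m.sum() else 0.0,
    }


def fold_base_set(dominant_pairs, labels, held_out: int, seed: int = 0):
    """Chromaticity bases for one LOOCV fold: built from every subject
    except ``held_out``.  The held-out image never touches base
    construction, whatever its pixels contain."""
    cohort = {
        lab: [
            dominant_pairs[j]
            for j in range(len(labels))
            if j != held_out and labels[j] == lab
        ]
        for lab in BASE_CLASS_LABELS
    }
    return build_all_bases(cohort, seed=seed)


def _fold_features(pixel_sets, base_set, binning, include_base_bins):
    return np.vstack(
        [
            assign_pixels(px, base_set, binning, include_base_bins).values
            for px in pixel_sets
        ]
    )


def loocv_evaluate(
    pixel_sets,
    labels,
    *,
    binning: LuminanceBinning = DEFAULT_REFINED_BINNING,
    include_base_bins: bool = True,
    C_grid=None,
    gamma_grid=None,
    inner_folds: int = 5,
    seed: int = 0,
    paper_protocol: bool = False,
    dominant_pairs=None,
    features_override=None,
    verbose: bool = False,
) -> EvaluationReport:
    """Leave-one-out evaluation with bases rebuilt per fold.

    ``pixel_sets`` is one cleaned lab-pixel array per subject.  Per fold the
    four chromaticity bases are built from the training subjects only, all
    features are re-extracted under those bases, the SVM is grid-searched
    and refit, and the held-out subject is predicted.  Pixel-level dominant
    pairs depend only on the image itself and are computed once (pass
    ``dominant_pairs`` to reuse them).

    ``features_override`` bypasses the base/feature machinery entirely and
    evaluates LOOCV on fixed feature vectors (used for sanity oracles).
    ``paper_protocol`` reproduces the optimistic reading in which the fold's
    (C, gamma) may be selected on the held-out prediction itself.
    """
    labels = list(labels)
    n = len(labels)
    if n != (len(features_override) if features_override is not None else len(pixel_sets)):
        raise ValueError("labels and cohort sizes differ")
    classes = _canonical_labels(labels)
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"LOOCV needs >= 2 subjects per class; class {c!r} has {labels.count(c)}")
        if features_override is None and c in BASE_CLASS_LABELS and labels.count(c) < 3:
            raise ValueError(
                f"LOOCV rebuilds bases per fold and needs >= 3 subjects per "
                f"chromatic class (>= 2 in every training fold); class {c!r} "
                f"has {labels.count(c)}"
            )

    if features_override is None and dominant_pairs is None:
        dominant_pairs = [
            np.vstack(image_dominant_pair(px, seed=seed + i))
            for i, px in enumerate(pixel_sets)
        ]

    min_count = min(labels.count(c) for c in classes)
    if min_count - 1 < inner_folds:
        warnings.warn(
            f"smallest class has {min_count - 1} members in training folds; "
            f"inner folds reduced accordingly",
            stacklevel=2,
        )

    to_idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        y_train = [labels[j] for j in train_idx]
        if features_override is not None:
            X_train = np.asarray(features_override)[train_idx]
            X_test = np.asarray(features_override)[i][None, :]
        else:
            base_set = fold_base_set(dominant_pairs, labels, i, seed=seed)
            X_train = _fold_features(
                [pixel_sets[j] for j in train_idx], base_set, binning, include_base_bins
            )
            X_test = assign_pixels(
                pixel_sets[i], base_set, binning, include_base_bins
            ).values[None, :]

        if paper_protocol:
            pred = _paper_protocol_predict(
                X_train, y_train, X_test, labels[i], C_grid, gamma_grid
            )
        else:
            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "ignore", message="smallest class has", category=UserWarning
                )
                model = train_svm(
                    X_train, y_train, C_grid, gamma_grid, inner_folds, seed=seed
                )
            pred = model.predict(X_test)[0]
        confusion[to_idx[labels[i]], to_idx[pred]] += 1
        if verbose and (i + 1) % 20 == 0:
            print(f"  loocv fold {i + 1}/{n}")

    return EvaluationReport(
        labels=classes,
        confusion_matrix=confusion,
        metrics=metrics_from_confusion(confusion),
    )


def _paper_protocol_predict(X_train, y_train, X_test, true_label, C_grid, gamma_grid):
    """Optimistic per-fold selection: the fold counts as correct if any grid
    point predicts the held-out label."""
    classes = _canonical_labels(y_train)
    to_idx = {c: i for i, c in enumerate(classes)}
    y = np.asarray([to_idx[l] for l in y_train])
    first_pred = None
    for C, gamma in itertools.product(
        sorted(C_grid or DEFAULT_C_GRID), sorted(gamma_grid or DEFAULT_GAMMA_GRID)
    ):
        svc = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")
        svc.fit(np.asarray(X_train, dtype=float), y)
        pred = classes[int(svc.predict(np.asarray(X_test, dtype=float))[0])]
        if first_pred is None:
            first_pred = pred
        if pred == true_label:
            return pred
    return first_pred


def classifier_fusion_predict(
    regional_models: dict,
    regional_features: dict,
    weights: dict | None = None,
) -> str:
    """Weighted vote over five regional models' predictions.

    Class score is the summed weight of regions voting for it; ties among
    top classes resolve to the prediction of the highest-weight region
    (region order breaks equal weights).
    """
    from .features import DEFAULT_REGION_WEIGHTS, REGION_ORDER

    weights = dict(weights) if weights else dict(DEFAULT_REGION_WEIGHTS)
    missing = [r for r in REGION_ORDER if r not in regional_models or r not in regional_features]
    if missing:
        raise ValueError(f"missing region(s): {missing}")
    votes: dict[str, float] = {}
    preds = {}
    for name in REGION_ORDER:
        p = regional_models[name].predict(regional_features[name])[0]
        preds[name] = p
        votes[p] = votes.get(p, 0.0) + weights[name]
    top = max(votes.values())
    tied = {c for c, v in votes.items() if v >= top - 1e-12}
    if len(tied) == 1:
        return tied.pop()
    for name in sorted(REGION_ORDER, key=lambda r: -weights[r]):
        if preds[name] in tied:
            return preds[name]
    raise AssertionError("unreachable")


def interval_sweep(
    pixel_sets,
    labels,
    intervals,
    lo: float = 25.0,
    hi: float = 95.0,
    **loocv_kwargs,
) -> pd.DataFrame:
    """LOOCV accuracy per luminance interval; returns a tidy table.

    Invalid intervals for the range are skipped with a warning.
    """
    dominant_pairs = loocv_kwargs.pop("dominant_pairs", None)
    if dominant_pairs is None:
        seed = loocv_kwargs.get("seed", 0)
        dominant_pairs = [
            np.vstack(image_dominant_pair(px, seed=seed + i))
            for i, px in enumerate(pixel_sets)
        ]
    rows = []
    for interval in intervals:
        try:
            binning = LuminanceBinning(lo, hi, float(interval))
        except ValueError as exc:
            warnings.warn(f"skipping interval {interval}: {exc}", stacklevel=2)
            continue
        report = loocv_evaluate(
            pixel_sets,
            labels,
            binning=binning,
            dominant_pairs=dominant_pairs,
            **loocv_kwargs,
        )
        rows.append(
            {
                "interval": interval,
                "feature_dim": feature_length(binning, loocv_kwargs.get("include_base_bins", True)),
                "loocv_accuracy": report.accuracy,
            }
        )
    return pd.DataFrame(rows)
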