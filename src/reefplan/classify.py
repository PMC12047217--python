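"""Habitat-classification accuracy machinery.

The object-based mapping stage of a benthic-habitat workflow classifies
image segments with a support vector machine and assesses the map with
Cohen's kappa. The pieces implemented and tested here are the kernel SVM
decision function

    f(x) = sum_i alpha_i * y_i * K(x, x_i) + b

with its sign rule (f > 0: one class, f < 0: the other), one-vs-rest voting
for the three-habitat problem, and kappa from a confusion matrix. Model
*training* is delegated to scikit-learn's maximum-margin solver; the fitted
dual coefficients, support vectors and bias are extracted into
:class:`SVMModel` so the decision function evaluated here is this module's
own code.

``synthetic_segments`` draws labelled per-segment spectral features
(band means for an 8-band very-high-resolution sensor) from per-class
Gaussians, standing in for real image segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@dataclass
class SVMModel:
    """A trained binary SVM in dual form.

    ``dual_weights`` holds the products alpha_i * y_i (training coefficient
    times class label in {-1, +1}), one per support vector.
    """

    support_vectors: np.ndarray  # (m, d)
    dual_weights: np.ndarray     # (m,)
    bias: float
    kernel: str = "rbf"          # "linear" or "rbf"
    gamma: float | None = None   # RBF width; defaults to 1/d

    def __post_init__(self):
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_weights = np.asarray(self.dual_weights, dtype=float)
        if self.support_vectors.ndim == 1:
            self.support_vectors = self.support_vectors.reshape(1, -1)
        if len(self.dual_weights) != len(self.support_vectors):
            raise ValueError(
                "one dual weight per support vector required: "
                f"{len(self.dual_weights)} weights, "
                f"{len(self.support_vectors)} support vectors"
            )
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel '{self.kernel}'")
        if self.kernel == "rbf":
            if self.gamma is None and self.support_vectors.size:
                self.gamma = 1.0 / self.support_vectors.shape[1]
            if self.gamma is not None and self.gamma <= 0:
                raise ValueError(f"RBF gamma must be positive, got {self.gamma}")


def _kernel_row(x: np.ndarray, model: SVMModel) -> np.ndarray:
    if model.kernel == "linear":
        return model.support_vectors @ x
    d2 = np.sum((model.support_vectors - x) ** 2, axis=1)
    return np.exp(-model.gamma * d2)


def svm_decision(x, model: SVMModel) -> float:
    """Evaluate f(x) = sum(alpha_i y_i K(x, x_i)) + b.

    The caller classifies by sign: positive scores belong to the model's
    positive class. An empty support set degenerates to the bias.
    """
    x = np.asarray(x, dtype=float).ravel()
    if model.support_vectors.size:
        if x.shape[0] != model.support_vectors.shape[1]:
            raise ValueError(
                f"feature dimension {x.shape[0]} does not match support "
                f"vectors of dimension {model.support_vectors.shape[1]}"
            )
        return float(model.dual_weights @ _kernel_row(x, model) + model.bias)
    return float(model.bias)


def svm_classify_multiclass(x, models: dict[str, SVMModel]) -> str:
    """One-vs-rest voting: the class with the largest decision score wins.

    Ties are broken by class order in ``models`` (first wins). Requires at
    least two classes.
    """
    if len(models) < 2:
        raise ValueError("multiclass voting needs at least two models")
    dims = {
        m.support_vectors.shape[1]
        for m in models.values()
        if m.support_vectors.size
    }
    if len(dims) > 1:
        raise ValueError(f"models disagree on feature dimension: {sorted(dims)}")
    best_label, best_score = None, -np.inf
    for label, model in models.items():
        s = svm_decision(x, model)
        if s > best_score:
            best_label, best_score = label, s
    return best_label


def from_sklearn(svc: SVC) -> SVMModel:
    """Extract a fitted binary scikit-learn SVC into dual form.

    The SVC must be binary with classes ordered (-1, +1) or equivalent so
    that positive decision values mean the positive class.
    """
    if len(svc.classes_) != 2:
        raise ValueError("only binary SVCs can be extracted")
    gamma = None
    if svc.kernel == "rbf":
        gamma = svc.gamma if isinstance(svc.gamma, (int, float)) else svc._gamma
    return SVMModel(
        support_vectors=svc.support_vectors_,
        dual_weights=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
        kernel=svc.kernel,
        gamma=float(gamma) if gamma is not None else None,
    )


def fit_one_vs_rest(
    X,
    y,
    kernel: str = "rbf",
    gamma: float | str | None = None,
    C: float = 1.0,
) -> dict[str, SVMModel]:
    """Train one binary max-margin model per class (class vs rest).

    Classes are ordered by first appearance in ``y``. ``gamma`` defaults to
    1/d for the RBF kernel.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if gamma is None:
        gamma = 1.0 / X.shape[1] if kernel == "rbf" else "scale"
    models: dict[str, SVMModel] = {}
    for label in dict.fromkeys(y.tolist()):
        target = np.where(y == label, 1, -1)
        svc = SVC(kernel=kernel, gamma=gamma, C=C)
        svc.fit(X, target)
        models[str(label)] = from_sklearn(svc)
    return models


def cohen_kappa(cm) -> float:
    """Cohen's kappa from a confusion matrix (rows = reference class).

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = trace/total and chance agreement p_e = sum(row_i * col_i)/total^2.
    Degenerate case: when p_e = 1 (all observations share one reference and
    one predicted class) kappa is 1 for perfect agreement, else 0.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.size == 0:
        raise ValueError("confusion matrix is empty")
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix total count must be positive")
    p_o = np.trace(cm) / total
    p_e = float(cm.sum(axis=1) @ cm.sum(axis=0)) / total**2
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if abs(1.0 - p_o) < 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


#: nominal band-mean spectra (arbitrary reflectance units) for the three
#: habitat classes over 8 spectral bands (coastal..NIR2)
DEFAULT_CLASS_SPECTRA: dict[str, np.ndarray] = {
    "coral": np.array([0.09, 0.12, 0.16, 0.10, 0.07, 0.05, 0.03, 0.02]),
    "seagrass": np.array([0.07, 0.09, 0.11, 0.13, 0.09, 0.06, 0.04, 0.03]),
    "mangrove": np.array([0.04, 0.05, 0.07, 0.09, 0.14, 0.18, 0.30, 0.33]),
}


def synthetic_segments(
    n_per_class: int,
    class_means: dict[str, np.ndarray] | None = None,
    class_covs: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labelled per-segment spectral feature vectors.

    Each class is a multivariate Gaussian over band-mean features
    (default: the three habitat spectra above with isotropic noise).
    Returns ``(X, y)`` with ``n_per_class`` rows per class, in class order.
    Deterministic given ``seed``.
    """
    if n_per_class < 0:
        raise ValueError(f"n_per_class must be >= 0, got {n_per_class}")
    means = class_means or DEFAULT_CLASS_SPECTRA
    d = len(next(iter(means.values())))
    covs = class_covs or {k: np.eye(d) * 0.0004 for k in means}
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for label in means:
        mean = np.asarray(means[label], dtype=float)
        cov = np.asarray(covs[label], dtype=float)
        if cov.shape != (d, d):
            raise ValueError(
                f"covariance for '{label}' must be {d}x{d}, got {cov.shape}"
            )
        if not np.allclose(cov, cov.T):
            raise ValueError(f"covariance for '{label}' is not symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-12:
            raise ValueError(f"covariance for '{label}' is not positive semidefinite")
        if n_per_class:
            X_parts.append(rng.multivariate_normal(mean, cov, size=n_per_class))
            y_parts.append(np.full(n_per_class, label, dtype=object))
    if not X_parts:
        return np.empty((0, d)), np.empty((0,), dtype=object)
    return np.vstack(X_parts), np.concatenate(y_parts)


def segments_to_dataframe(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Feature set as a CSV-friendly table (segment_id, band_*, label)."""
    df = pd.DataFrame(
        X, columns=[f"band_{i + 1}" for i in range(X.shape[1])]
    )
    df.insert(0, "segment_id", np.arange(1, len(df) + 1))
    df["label"] = y
    return df


def confusion_matrix(y_true, y_pred, classes: list[str]) -> pd.DataFrame:
    """Count matrix with rows = reference class, columns = predicted."""
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


def classification_demo(
    n_per_class: int = 120,
    kernel: str = "rbf",
    seed: int = 0,
    holdout_fraction: float = 0.5,
) -> dict:
    """Fit, predict on a held-out split and report kappa.

    A compact end-to-end exercise of the machinery on synthetic segments:
    returns the confusion matrix, kappa and overall accuracy. Band features
    are standardized before fitting, as usual for kernel classifiers on
    reflectance-scale values.
    """
    X, y = synthetic_segments(n_per_class, seed=seed)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(y))
    n_test = int(len(y) * holdout_fraction)
    test, train = order[:n_test], order[n_test:]
    models = fit_one_vs_rest(X[train], y[train], kernel=kernel)
    preds = np.array([svm_classify_multiclass(x, models) for x in X[test]])
    classes = list(dict.fromkeys(y.tolist()))
    cm = confusion_matrix(y[test].astype(str), preds, [str(c) for c in classes])
    return {
        "confusion_matrix": cm,
        "kappa": cohen_kappa(cm.values),
        "accuracy": float(np.trace(cm.values) / cm.values.sum()),
        "n_train": len(train),
        "n_test": len(test),
    }
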