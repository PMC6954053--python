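"""Single-trial classification of the spoken condition.

Each trial is summarized by a feature vector of per-electrode spike counts
and mean HLFP power in ten 100 ms bins spanning 0.5 s before to 0.5 s after
acoustic onset (silent trials use their faux AO), e.g. 104 electrodes x 2
feature types x 10 bins = 2080 features.

Classification is one-versus-one error-correcting output codes (ECOC) over
linear max-margin (hinge-loss) binary classifiers: one classifier per class
pair, trained on z-scored features (standardization fit on the training
trials of each fold only), with the predicted class minimizing the summed
hinge loss over the classifiers it participates in; ties go to the lowest
class index.  Accuracy is evaluated leave-one-trial-out, and chance is
estimated by re-running the whole procedure after randomly permuting the
trial labels (101 shuffles by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numba import njit

from .synthetic import Dataset

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "build_features",
    "loo_classify",
    "shuffle_chance",
]


@dataclass
class FeatureMatrix:
    X: np.ndarray                     # trials x features
    labels: np.ndarray                # condition per trial
    feature_map: list[tuple[int, str, int]]   # (electrode, type, bin)
    bin_centers: np.ndarray           # seconds relative to AO

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")


@dataclass
class ClassifierReport:
    predictions: np.ndarray
    classes: list[str]
    confusion: np.ndarray             # row = true class, columns sum to 100%
    accuracy: float                   # percent correct, overall
    per_class_accuracy: dict[str, float]
    chance: dict | None = None        # min/mean/max over shuffles
    n_shuffles: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def build_features(dataset: Dataset, n_bins: int = 10, bin_width: float = 0.1,
                   alignment: str = "AO") -> FeatureMatrix:
    """Per-trial spike-count + HLFP-power feature vectors around AO.

    Bins span ``[-n_bins/2 * bin_width, +n_bins/2 * bin_width)`` relative to
    the alignment event.  Trials lacking an HLFP channel produce spike-only
    features with a warning.
    """
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_width
    centers = (edges[:-1] + edges[1:]) / 2
    have_hlfp = all(tr.hlfp_power is not None for tr in dataset.trials
                    if not tr.excluded)
    if not have_hlfp:
        warnings.warn("HLFP channel missing; building spike-only features",
                      RuntimeWarning)
    rows, labels = [], []
    n_e = dataset.n_electrodes
    for tr in dataset.trials:
        if tr.excluded:
            continue
        align = tr.events.get(alignment)
        if align is None:
            raise ValueError(f"trial lacks event {alignment!r} "
                             "(assign a faux AO to silent trials first)")
        spike = np.zeros((n_e, n_bins))
        for e, st in enumerate(tr.spike_times):
            if len(st):
                spike[e], _ = np.histogram(st - align, bins=edges)
        feats = [spike]
        if have_hlfp:
            hl = np.zeros((n_e, n_bins))
            t = tr.hlfp_times - align
            for b in range(n_bins):
                m = (t >= edges[b]) & (t < edges[b + 1])
                if np.any(m):
                    hl[:, b] = tr.hlfp_power[:, m].mean(axis=1)
            feats.append(hl)
        rows.append(np.concatenate([f.ravel() for f in feats]))
        labels.append(tr.condition)
    fmap = [(e, kind, b)
            for kind in (["spike"] + (["hlfp"] if have_hlfp else []))
            for e in range(n_e) for b in range(n_bins)]
    # order within rows is electrode-major per feature type; rebuild map to match
    fmap = []
    for kind in ["spike"] + (["hlfp"] if have_hlfp else []):
        for e in range(n_e):
            for b in range(n_bins):
                fmap.append((e, kind, b))
    return FeatureMatrix(X=np.vstack(rows), labels=np.asarray(labels),
                         feature_map=fmap, bin_centers=centers)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    keep = sd > 0
    sd = np.where(keep, sd, 1.0)
    # constant features map to 0 in both sets (equivalent to dropping them)
    return np.where(keep, (train - mu) / sd, 0.0), \
        np.where(keep, (test - mu) / sd, 0.0)


@njit(cache=True)
def _svm_dual_cd(x: np.ndarray, y: np.ndarray, c: float, tol: float,
                 max_passes: int) -> np.ndarray:
    """Linear hinge-loss SVM by dual coordinate descent (liblinear algorithm).

    ``x`` must already carry the bias column; returns the weight vector
    (bias penalized, as in liblinear with unit intercept scaling).
    """
    n, d = x.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qdiag = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += x[i, j] * x[i, j]
        qdiag[i] = s if s > 1e-12 else 1e-12
    for _ in range(max_passes):
        max_viol = 0.0
        for i in range(n):
            g = -1.0
            for j in range(d):
                g += y[i] * w[j] * x[i, j]
            if alpha[i] <= 0.0:
                pg = min(g, 0.0)
            elif alpha[i] >= c:
                pg = max(g, 0.0)
            else:
                pg = g
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if abs(pg) > 1e-12:
                new = alpha[i] - g / qdiag[i]
                if new < 0.0:
                    new = 0.0
                elif new > c:
                    new = c
                delta = (new - alpha[i]) * y[i]
                alpha[i] = new
                for j in range(d):
                    w[j] += delta * x[i, j]
        if max_viol < tol:
            break
    return w


def _fit_binary_svm(x: np.ndarray, y: np.ndarray, c: float = 1.0,
                    tol: float = 1e-4, max_passes: int = 2000) -> np.ndarray:
    """Weight vector (with trailing bias) of a linear max-margin classifier."""
    xa = np.ascontiguousarray(np.column_stack([x, np.ones(x.shape[0])]))
    return _svm_dual_cd(xa, np.ascontiguousarray(y, dtype=np.float64), c,
                        tol, max_passes)


def svm_decision(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Decision values of a fitted weight vector on raw feature rows."""
    return x @ w[:-1] + w[-1]


def _predict_one(X_tr: np.ndarray, y_tr: np.ndarray, x_te: np.ndarray,
                 classes: np.ndarray, C: float) -> int:
    """One-vs-one ECOC prediction by minimum aggregate hinge loss."""
    losses = np.zeros(classes.size)
    for (ka, a), (kb, b) in combinations(enumerate(classes), 2):
        mask = (y_tr == a) | (y_tr == b)
        y_bin = np.where(y_tr[mask] == a, 1.0, -1.0)
        w = _fit_binary_svm(X_tr[mask], y_bin, c=C)
        f = float(x_te @ w[:-1] + w[-1])
        losses[ka] += max(0.0, 1.0 - f)
        losses[kb] += max(0.0, 1.0 + f)
    return int(np.argmin(losses))    # argmin takes the lowest class index on ties


def loo_classify(features: FeatureMatrix, C: float = 1.0,
                 labels: np.ndarray | None = None) -> ClassifierReport:
    """Leave-one-trial-out one-vs-one ECOC classification.

    ``labels`` overrides the feature matrix's labels (used internally by the
    shuffle test).  Deterministic given its inputs.
    """
    X = features.X
    y = np.asarray(labels if labels is not None else features.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if np.count_nonzero(y == c) < 2:
            raise ValueError(f"class {c!r} has < 2 trials")
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        X_tr, x_te = _standardize(X[tr], X[i:i + 1])
        k = _predict_one(X_tr, y[tr], x_te[0], classes, C)
        preds[i] = classes[k]
    preds = preds.astype(str)
    class_list = [str(c) for c in classes]
    conf = np.zeros((classes.size, classes.size))
    for i, true in enumerate(class_list):
        m = y.astype(str) == true
        for j, pred in enumerate(class_list):
            conf[i, j] = 100.0 * np.mean(preds[m] == pred)
    acc = 100.0 * float(np.mean(preds == y.astype(str)))
    per_class = {c: float(conf[i, i]) for i, c in enumerate(class_list)}
    return ClassifierReport(predictions=preds, classes=class_list,
                            confusion=conf, accuracy=acc,
                            per_class_accuracy=per_class)


def shuffle_chance(features: FeatureMatrix, n_shuffles: int = 101,
                   seed: int = 0, C: float = 1.0,
                   permutations: list[np.ndarray] | None = None) -> dict:
    """Chance accuracy distribution via label-shuffled re-classification.

    Each shuffle randomly permutes the class labels over trials and reruns
    the full leave-one-trial-out procedure.  Explicit ``permutations`` may be
    supplied (e.g. the identity, which reproduces the unshuffled accuracy).
    Returns ``{"accuracies", "min", "mean", "max", "seed"}``.
    """
    rng = np.random.default_rng(seed)
    n = features.X.shape[0]
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_shuffles)]
    accs = np.array([
        loo_classify(features, C=C, labels=features.labels[perm]).accuracy
        for perm in permutations
    ])
    return {"accuracies": accs, "min": float(accs.min()),
            "mean": float(accs.mean()), "max": float(accs.max()),
            "seed": seed}
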