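"""Classifiers and the leave-one-participant-out (LOPO) evaluation driver.

Four classifiers are supported, each operating on a participants x features
matrix where every row is one participant:

* LDA -- Fisher linear discriminant with pooled within-class covariance,
  implemented from its closed-form decision function

      D(x) = (mu1 - mu2)' S^-1 x - 1/2 (mu1 - mu2)' S^-1 (mu1 + mu2) + ln(p1/p2)

  (equal class penalty weights, priors = training class proportions); x is
  positive-class iff D(x) > 0, with the exact-zero tie going to the
  negative class.  An ill-conditioned covariance is ridge-regularised with
  lambda = 1e-6 * trace(S)/d.
* SVM -- soft-margin Gaussian-kernel SVM (scikit-learn SVC), C = 100 and
  gamma = 1 / (d * mean per-feature variance of the training inputs).
* KNN -- K = 3 nearest neighbours by Euclidean distance; exact distance
  ties at the K-th neighbour resolve to the lower training index, and a
  three-way vote tie resolves to the class of the nearest neighbour.
* LR -- logistic regression with (penalty, C) chosen by an inner LOPO grid
  search over {L1, L2} x {0.001, 0.01, 0.1, 1, 10, 100} on the training
  portion of each fold; accuracy ties prefer stronger regularisation
  (smaller C) and L2 before L1.

Three-class problems use one-against-one majority voting for the binary
classifiers (LDA, SVM); KNN and LR predict multiclass natively.  Features
are z-scored with training-fold statistics before SVM/KNN/LR (not LDA,
which is scale-equivariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassifierSpec",
    "ClassificationReport",
    "lda_train_predict",
    "svm_train_predict",
    "knn_predict",
    "lr_grid_train_predict",
    "oao_vote",
    "train_predict",
    "lopo_evaluate",
    "compute_gamma",
    "standardize_fit",
]

logger = logging.getLogger(__name__)

DEFAULT_LR_GRID = tuple(
    (penalty, C) for penalty in ("l2", "l1") for C in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
)

#: fixed class precedence used to break residual one-against-one ties
CLASS_ORDER = ("AD", "MCI", "HC")


@dataclass
class ClassifierSpec:
    """Which classifier to run and with which parameters.

    ``standardize=None`` resolves to the per-kind default: off for LDA,
    on for SVM/KNN/LR.
    """

    kind: str = "LDA"
    C: float = 100.0
    k: int = 3
    lr_grid: tuple = DEFAULT_LR_GRID
    standardize: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("LDA", "SVM", "KNN", "LR"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.C <= 0:
            raise ValueError("SVM penalty C must be positive")
        if self.k % 2 != 1:
            raise ValueError("KNN K must be odd")
        if not self.lr_grid:
            raise ValueError("LR grid must be non-empty")

    @property
    def standardize_resolved(self) -> bool:
        return self.kind != "LDA" if self.standardize is None else self.standardize


@dataclass
class ClassificationReport:
    """LOPO outcome: per-fold predictions, confusion counts and accuracy."""

    accuracy: float
    predictions: tuple
    truths: tuple
    classes: tuple
    confusion: np.ndarray
    d: int | None = None
    n_channels: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.truths)


# ---------------------------------------------------------------------------
# leak-sensitive helpers (kept as module-level seams so tests can instrument
# exactly what data they receive)


def standardize_fit(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and SD of the training matrix (SD floored at 1e-12)."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    return mu, np.maximum(sd, 1e-12)


def compute_gamma(X_train: np.ndarray) -> float:
    """Gaussian-kernel width gamma = 1 / (d * mean per-feature variance)."""
    d = X_train.shape[1]
    mean_var = float(X_train.var(axis=0, ddof=0).mean())
    if mean_var <= 0:
        mean_var = 1.0
    return 1.0 / (d * mean_var)


# ---------------------------------------------------------------------------
# binary classifiers


def _binary_classes(y: np.ndarray) -> tuple:
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    return tuple(classes)


def lda_train_predict(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    priors: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear discriminant prediction with decision values.

    The first class in sorted label order is the positive class (mu1); a
    test point is assigned to it iff the decision value is strictly
    positive.  Priors default to training class proportions.
    """
    y = np.asarray(y_train)
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.atleast_2d(np.asarray(X_test, dtype=float))
    pos, neg = _binary_classes(y)
    X1, X2 = Xtr[y == pos], Xtr[y == neg]
    if len(X1) < 1 or len(X2) < 1:
        raise ValueError("both classes must be present in training data")
    n, d = Xtr.shape
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    # pooled within-class covariance (scatter sum over classes / (n - 2))
    S = ((X1 - mu1).T @ (X1 - mu1) + (X2 - mu2).T @ (X2 - mu2)) / max(n - 2, 1)
    S = np.atleast_2d(S)
    if priors is None:
        priors = (len(X1) / n, len(X2) / n)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e8:
        S = S + (1e-6 * np.trace(S) / d) * np.eye(d)
    try:
        w = np.linalg.solve(S, mu1 - mu2)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular pooled covariance after regularisation: {e}")
    dec = Xte @ w - 0.5 * (mu1 + mu2) @ w + np.log(priors[0] / priors[1])
    labels = np.where(dec > 0, pos, neg)
    return labels, dec


def svm_train_predict(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    C: float = 100.0,
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel SVM prediction with decision values."""
    from sklearn.svm import SVC

    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.atleast_2d(np.asarray(X_test, dtype=float))
    if gamma is None:
        gamma = compute_gamma(Xtr)
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(Xtr, np.asarray(y_train))
    dec = clf.decision_function(Xte)
    return clf.predict(Xte), np.asarray(dec)


def knn_predict(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """K-nearest-neighbour majority vote (Euclidean).

    Stable neighbour ordering: an exact distance tie at the K-th neighbour
    goes to the lower training index.  A vote tie (possible only with >2
    classes) goes to the class of the nearest neighbour among tied classes.
    """
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.atleast_2d(np.asarray(X_test, dtype=float))
    y = np.asarray(y_train)
    if len(Xtr) < k:
        raise ValueError(f"need at least K={k} training points, got {len(Xtr)}")
    out = []
    for x in Xte:
        dists = np.linalg.norm(Xtr - x, axis=1)
        nn = np.argsort(dists, kind="stable")[:k]
        votes = y[nn]
        labs, counts = np.unique(votes, return_counts=True)
        best = counts.max()
        tied = set(labs[counts == best])
        if len(tied) == 1:
            out.append(tied.pop())
        else:
            out.append(next(v for v in votes if v in tied))
    return np.asarray(out)


def lr_grid_train_predict(
    X_train: np.ndarray,
    y_train: Sequence,
    X_test: np.ndarray,
    grid: Sequence[tuple[str, float]] = DEFAULT_LR_GRID,
) -> tuple[np.ndarray, tuple[str, float]]:
    """Logistic regression with nested LOPO grid search on the training set.

    Every (penalty, C) point is scored by leave-one-out accuracy on the
    training portion only; ties prefer smaller C, then L2 over L1.  The
    winning setting is refit on the whole training set.  Returns predictions
    and the chosen (penalty, C).
    """
    from sklearn.linear_model import LogisticRegression

    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.atleast_2d(np.asarray(X_test, dtype=float))
    y = np.asarray(y_train)
    n = len(Xtr)

    import sklearn

    new_api = tuple(int(v) for v in sklearn.__version__.split(".")[:2]) >= (1, 8)

    def make(penalty: str, C: float) -> "LogisticRegression":
        if new_api:  # 'penalty' deprecated in favour of l1_ratio
            return LogisticRegression(l1_ratio=1.0 if penalty == "l1" else 0.0,
                                      C=C, solver="liblinear", max_iter=2000)
        return LogisticRegression(penalty=penalty, C=C, solver="liblinear", max_iter=2000)

    scores: dict[tuple[str, float], float] = {}
    for penalty, C in grid:
        correct = 0
        failed = False
        for i in range(n):
            tr = np.arange(n) != i
            if len(set(y[tr])) < 2:
                continue
            try:
                m = make(penalty, C).fit(Xtr[tr], y[tr])
            except Exception:
                failed = True
                break
            correct += int(m.predict(Xtr[i:i + 1])[0] == y[i])
        if not failed:
            scores[(penalty, C)] = correct / n
    if not scores:
        raise RuntimeError("no logistic-regression grid point converged")
    # tie policy: highest accuracy, then smaller C, then l2 before l1
    best = max(scores, key=lambda pc: (scores[pc], -pc[1], pc[0] == "l2"))
    model = make(*best).fit(Xtr, y)
    return model.predict(Xte), best


# ---------------------------------------------------------------------------
# multiclass via one-against-one


def oao_vote(
    votes: Sequence,
    magnitudes: Sequence[float] | None = None,
    class_order: Sequence[str] = CLASS_ORDER,
):
    """Majority vote over one-against-one binary predictions.

    A label with at least two of the three votes wins.  A three-way tie is
    resolved by the vote with the largest absolute decision value, and any
    residual tie by the fixed class precedence ``class_order``.
    """
    votes = list(votes)
    labs, counts = np.unique(votes, return_counts=True)
    if counts.max() >= 2:
        return labs[counts.argmax()]
    if magnitudes is not None:
        mags = np.asarray(magnitudes, dtype=float)
        best = np.abs(mags).max()
        tied = {votes[i] for i in range(len(votes)) if abs(mags[i]) == best}
    else:
        tied = set(votes)
    for c in class_order:
        if c in tied:
            return c
    return sorted(tied)[0]


def _oao_train_predict(spec: ClassifierSpec, Xtr, ytr, Xte) -> np.ndarray:
    """Train one binary model per class pair and combine by majority vote."""
    classes = sorted(set(ytr))
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    all_votes = []
    all_mags = []
    for a, b in pairs:
        sel = (ytr == a) | (ytr == b)
        if spec.kind == "LDA":
            labels, dec = lda_train_predict(Xtr[sel], ytr[sel], Xte)
        else:
            labels, dec = svm_train_predict(Xtr[sel], ytr[sel], Xte, C=spec.C)
        all_votes.append(labels)
        all_mags.append(np.abs(dec))
    preds = []
    for j in range(len(Xte)):
        preds.append(oao_vote([v[j] for v in all_votes], [m[j] for m in all_mags]))
    return np.asarray(preds)


# ---------------------------------------------------------------------------
# unified fit/predict and the LOPO driver


def train_predict(spec: ClassifierSpec, X_train, y_train, X_test) -> np.ndarray:
    """Fit the specified classifier on training rows and predict test rows.

    Standardisation statistics and (for SVM) the kernel width are computed
    from the training rows only.
    """
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.atleast_2d(np.asarray(X_test, dtype=float))
    ytr = np.asarray(y_train)
    if spec.standardize_resolved:
        mu, sd = standardize_fit(Xtr)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    n_classes = len(set(ytr))
    if spec.kind == "KNN":
        return knn_predict(Xtr, ytr, Xte, k=spec.k)
    if spec.kind == "LR":
        return lr_grid_train_predict(Xtr, ytr, Xte, grid=spec.lr_grid)[0]
    if n_classes == 2:
        if spec.kind == "LDA":
            return lda_train_predict(Xtr, ytr, Xte)[0]
        return svm_train_predict(Xtr, ytr, Xte, C=spec.C)[0]
    return _oao_train_predict(spec, Xtr, ytr, Xte)


def lopo_evaluate(
    X: np.ndarray,
    y: Sequence,
    spec: ClassifierSpec,
    participants: Sequence[str] | None = None,
) -> ClassificationReport:
    """Leave-one-participant-out cross-validation.

    Exactly N folds; in each, one participant is held out and the classifier
    is trained on the remaining N-1.  A training failure marks the fold as
    misclassified rather than aborting the run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("LOPO needs at least 3 participants")
    classes = tuple(sorted(set(y)))
    preds = []
    for i in range(n):
        tr = np.arange(n) != i
        try:
            p = train_predict(spec, X[tr], y[tr], X[i:i + 1])[0]
        except Exception as e:  # fold failure counts as an error, not a crash
            logger.warning("fold %d (%s) failed: %s", i,
                           participants[i] if participants else i, e)
            p = "__failed__"
        preds.append(p)
    preds_arr = np.asarray(preds)
    acc = float(np.mean(preds_arr == y))
    conf = np.zeros((len(classes), len(classes) + 1), dtype=int)
    cols = {c: j for j, c in enumerate(classes)}
    for t, p in zip(y, preds_arr):
        conf[cols[t], cols.get(p, len(classes))] += 1
    return ClassificationReport(
        accuracy=acc, predictions=tuple(preds_arr), truths=tuple(y),
        classes=classes, confusion=conf,
        meta={"participants": tuple(participants) if participants else None},
    )
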