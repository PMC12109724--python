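"""Fisher-score feature ranking and top-n subset selection under LOPO-CV.

Each feature is scored by Fisher's criterion for a two-class problem,

    F = [(m1 - m)^2 + (m2 - m)^2] / (s1^2 + s2^2),

with class means m1, m2, grand mean m, and unbiased class variances.  The
features are sorted by descending F-score (stable, ties to the lower
feature index) and the top ``dc`` retained as candidates.  For every
n = 1..dc the leave-one-participant-out accuracy of a chosen classifier on
the top-n features is measured; the optimal subset size ``d_opt`` is the
smallest n attaining the maximum of that curve.

Two ranking protocols are provided.  ``mode='paper'`` ranks once on the
full cohort before the LOPO loop -- the protocol of the original framework.
Because the held-out participant then contributes to the ranking, this
estimate carries feature-selection bias; ``mode='nested'`` recomputes the
ranking inside every training fold so the held-out row is never touched by
selection.  The default follows the original protocol; prefer 'nested' for
unbiased accuracy estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ClassifierSpec, train_predict
from .tier import TierTable

__all__ = ["SelectionResult", "fisher_score", "fisher_scores", "rank_features",
           "top_n_lopo_curve"]

logger = logging.getLogger(__name__)

FISHER_VAR_FLOOR = 1e-12

_PAPER_MODE_WARNED = False  # the selection-bias warning fires once per process


def fisher_score(values: np.ndarray, labels: Sequence) -> float:
    """Fisher's criterion of one feature for a two-class problem."""
    return float(fisher_scores(np.asarray(values, dtype=float)[:, None], labels)[0])


def fisher_scores(X: np.ndarray, labels: Sequence) -> np.ndarray:
    """Vectorised Fisher scores for every column of a participants x D matrix.

    Zero within-class variance is handled by an additive floor on the
    denominator, so two constant equal classes score 0 rather than 0/0.

    For k > 2 classes the same criterion generalises to
    sum_k (m_k - m)^2 / sum_k s_k^2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"Fisher score needs at least 2 classes, got {classes}")
    m = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 participants")
        num += (Xc.mean(axis=0) - m) ** 2
        den += Xc.var(axis=0, ddof=1)
    return num / (den + FISHER_VAR_FLOOR)


def _as_matrix(table) -> np.ndarray:
    return table.matrix if isinstance(table, TierTable) else np.asarray(table, dtype=float)


def rank_features(
    table,
    labels: Sequence,
    dc: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by descending Fisher score.

    Stable sort: ties are broken by the lower feature index.  Returns
    (ranking, f_scores) where ranking is truncated to ``dc`` candidates if
    given.
    """
    X = _as_matrix(table)
    f = fisher_scores(X, labels)
    ranking = np.argsort(-f, kind="stable")
    if dc is not None:
        ranking = ranking[:dc]
    return ranking, f


@dataclass
class SelectionResult:
    """Ranking, LOPO accuracy curve, and the optimal feature subset."""

    f_scores: np.ndarray
    ranking: np.ndarray
    dc: int
    accuracy_curve: np.ndarray
    d_opt: int
    optimal_features: tuple
    n_channels: int
    mode: str = "paper"
    meta: dict = field(default_factory=dict)

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy_curve.max())

    def curve_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": np.arange(1, self.dc + 1),
                             "accuracy": self.accuracy_curve})


def _feature_identities(table, cols: np.ndarray) -> tuple:
    if isinstance(table, TierTable):
        return tuple(table.entry(int(c)) for c in cols)
    return tuple(int(c) for c in cols)


def _count_channels(features) -> int:
    chans = set()
    for f in features:
        if isinstance(f, tuple) and len(f) == 3:
            chans.update(f[1:])
    return len(chans)


def top_n_lopo_curve(
    table,
    labels: Sequence,
    spec: ClassifierSpec | None = None,
    dc: int = 100,
    ranking: np.ndarray | None = None,
    mode: str = "paper",
) -> SelectionResult:
    """LOPO accuracy of the top-n-ranked features for every n up to ``dc``.

    ``table`` is a TierTable or plain participants x D matrix.  In 'paper'
    mode the Fisher ranking is computed once on the full cohort (or taken
    from ``ranking``); in 'nested' mode it is recomputed inside each
    training fold and the provided ranking is ignored for classification.
    ``d_opt`` is the smallest n attaining the curve maximum.
    """
    if mode not in ("paper", "nested"):
        raise ValueError(f"mode must be 'paper' or 'nested', got {mode!r}")
    X = _as_matrix(table)
    y = np.asarray(labels)
    n_part, D = X.shape
    if n_part < 3:
        raise ValueError("LOPO needs at least 3 participants")
    dc = min(dc, D)
    spec = spec or ClassifierSpec("LDA")
    global _PAPER_MODE_WARNED
    if mode == "paper" and not _PAPER_MODE_WARNED:
        _PAPER_MODE_WARNED = True
        logger.warning(
            "selection mode 'paper': feature ranking uses the full cohort, "
            "including each fold's held-out participant; accuracies carry "
            "selection bias. Use mode='nested' for unbiased estimates."
        )

    # reporting ranking on the full cohort; nested-mode classification never
    # uses it (each fold calls rank_features on its own training rows)
    f = fisher_scores(X, y)
    full_ranking = (np.argsort(-f, kind="stable") if ranking is None
                    else np.asarray(ranking, dtype=int))
    correct = np.zeros(dc, dtype=int)
    for i in range(n_part):
        tr = np.arange(n_part) != i
        if mode == "nested":
            fold_ranking, _ = rank_features(X[tr], y[tr], dc=dc)
        else:
            fold_ranking = full_ranking[:dc]
        for n in range(1, dc + 1):
            cols = fold_ranking[:n]
            try:
                p = train_predict(spec, X[tr][:, cols], y[tr], X[i:i + 1, cols])[0]
            except Exception as e:
                logger.warning("fold %d, n=%d failed: %s", i, n, e)
                continue
            correct[n - 1] += int(p == y[i])
    curve = correct / n_part
    d_opt = int(np.argmax(curve)) + 1  # argmax returns the first (smallest n) maximum
    optimal = _feature_identities(table, full_ranking[:d_opt])
    return SelectionResult(
        f_scores=f, ranking=full_ranking[:dc], dc=dc, accuracy_curve=curve,
        d_opt=d_opt, optimal_features=optimal,
        n_channels=_count_channels(optimal), mode=mode,
        meta={"classifier": spec.kind, "n_participants": n_part},
    )
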