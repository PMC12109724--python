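"""Group-level connectivity contrasts and band-contribution summaries.

Two edge-wise contrasts are provided, both permutation-calibrated on the
mean difference (no variance assumptions on bounded connectivity values):

* within-group rest-to-task change -- paired: per-participant differences
  (task - rest) are tested edge by edge with a sign-flipping permutation
  test;
* between-group difference -- unpaired: group labels are shuffled and the
  difference of group means recomputed.

Raw p-values are corrected for multiple comparisons across the edges of
each band with Benjamini-Hochberg FDR at alpha = 0.05 (Bonferroni
available).  The effect sign convention is first-listed condition or group
minus the second: a task-state or first-group increase is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bands import DEFAULT_BANDS, BandSpec, FeatureIndex
from .spectral import FeatureVector

__all__ = [
    "EdgeContrastMap",
    "within_group_change",
    "between_group_difference",
    "band_contribution",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class EdgeContrastMap:
    """Per-(band, pair) effects, p-values and significance flags.

    ``table`` columns: band, ch1, ch2, effect, p_raw, p_corr, significant.
    """

    table: pd.DataFrame
    contrast: str
    alpha: float = ALPHA
    method: str = "fdr_bh"

    def significant_edges(self, band: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["significant"]]
        return t if band is None else t[t["band"] == band]

    def to_matrix(self, band: str, channels: Sequence[str]) -> np.ndarray:
        """Square signed adjacency matrix of significant effects for a band."""
        ch_idx = {c: i for i, c in enumerate(channels)}
        M = np.zeros((len(channels), len(channels)))
        for _, row in self.significant_edges(band).iterrows():
            i, j = ch_idx[row["ch1"]], ch_idx[row["ch2"]]
            M[i, j] = M[j, i] = row["effect"]
        return M


def _edge_index(index: FeatureIndex) -> pd.DataFrame:
    return index.to_frame()


def _correct(df: pd.DataFrame, alpha: float, method: str) -> pd.DataFrame:
    """Multiple-comparison correction applied within each band."""
    df = df.copy()
    df["p_corr"] = np.nan
    df["significant"] = False
    mt_method = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    for band in df["band"].unique():
        sel = df["band"] == band
        rej, p_corr, _, _ = multipletests(df.loc[sel, "p_raw"], alpha=alpha, method=mt_method)
        df.loc[sel, "p_corr"] = p_corr
        df.loc[sel, "significant"] = rej
    return df


def _stack(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, FeatureIndex]:
    index = vectors[0].index
    for v in vectors:
        if v.index != index:
            raise ValueError("feature index differs across participants")
    return np.stack([v.values for v in vectors]), index


def within_group_change(
    rest: Sequence[FeatureVector],
    task: Sequence[FeatureVector],
    group: str = "",
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = ALPHA,
    method: str = "fdr_bh",
) -> EdgeContrastMap:
    """Paired rest-to-task contrast for one group, edge by edge.

    The statistic per edge is the mean over participants of (task - rest);
    its null distribution comes from random sign flips of the
    per-participant differences (all 2^n flips enumerated exactly when the
    group is small).  Effects are positive where connectivity increases
    during the task.
    """
    R, index = _stack(rest)
    T, _ = _stack(task)
    if R.shape != T.shape:
        raise ValueError("rest and task cohorts differ in shape")
    diffs = T - R  # (n, E)
    n = diffs.shape[0]
    obs = diffs.mean(axis=0)
    if n < 5:
        logger.warning("group %s has only %d participants; enumerating all sign flips", group, n)
    if 2 ** n <= n_perm:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null = signs @ diffs / n  # (n_perm, E)
    p = (1.0 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (1.0 + len(signs))
    df = _edge_index(index)
    df["effect"] = obs
    df["p_raw"] = p
    df = _correct(df, alpha, method)
    return EdgeContrastMap(table=df, contrast=f"{group} rest->{task[0].state}",
                           alpha=alpha, method=method)


def between_group_difference(
    first: Sequence[FeatureVector] | np.ndarray,
    second: Sequence[FeatureVector] | np.ndarray,
    names: tuple[str, str] = ("first", "second"),
    index: FeatureIndex | None = None,
    n_perm: int = 10_000,
    seed: int | None = 0,
    alpha: float = ALPHA,
    method: str = "fdr_bh",
) -> EdgeContrastMap:
    """Unpaired two-group contrast per edge via label-shuffling permutation.

    Inputs may be FeatureVector sequences or plain (n x E) matrices on a
    shared ``index``.  The effect is mean(first) - mean(second).
    """
    if isinstance(first, np.ndarray):
        A, B = np.asarray(first, float), np.asarray(second, float)
        if index is None:
            raise ValueError("index required for matrix inputs")
    else:
        A, index = _stack(first)
        B, _ = _stack(second)
    n1 = A.shape[0]
    pooled = np.vstack([A, B])
    n = pooled.shape[0]
    obs = A.mean(axis=0) - B.mean(axis=0)
    if min(n1, n - n1) < 5:
        logger.warning("a group has fewer than 5 members; permutation p-values are coarse")
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, pooled.shape[1]))
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = pooled[perm[:n1]].mean(axis=0) - pooled[perm[n1:]].mean(axis=0)
    p = (1.0 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (1.0 + n_perm)
    df = _edge_index(index)
    df["effect"] = obs
    df["p_raw"] = p
    df = _correct(df, alpha, method)
    return EdgeContrastMap(table=df, contrast=f"{names[0]} minus {names[1]}",
                           alpha=alpha, method=method)


def band_contribution(
    optimal_features,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
) -> dict[str, float]:
    """Fraction of an optimal feature set contributed by each band.

    Accepts a SelectionResult or a sequence of (band, ch1, ch2) identities;
    fractions over the band list sum to 1.
    """
    feats = getattr(optimal_features, "optimal_features", optimal_features)
    if not feats:
        raise ValueError("empty optimal feature set")
    counts = {b.name: 0 for b in bands}
    for f in feats:
        counts[f[0]] += 1
    total = len(feats)
    return {name: c / total for name, c in counts.items()}
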