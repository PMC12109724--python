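"""WM-TIER: the rest-to-task inter-state change of a feature.

The task-induced response of feature i is its percentage change from the
resting state to the task state,

    change_i = (f_i_task - f_i_rest) / f_i_rest,

concatenated over all D features into one vector per participant.
Referencing task features to the participant's own resting baseline removes
inter-individual offsets that are unrelated to the task.

Near-zero resting denominators (|f_rest| < eps, default 1e-6) make the
ratio meaningless; such features are excluded cohort-wide so every
participant shares one common feature index -- a requirement for
leave-one-participant-out evaluation.  No clipping is applied: inter-state
changes of bounded features can legitimately exceed [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bands import FeatureIndex
from .spectral import FeatureVector

__all__ = ["TierTable", "inter_state_change", "build_tier_table"]

logger = logging.getLogger(__name__)

DEGENERATE_EPS = 1e-6


def inter_state_change(f_task: float, f_rs: float, eps: float = DEGENERATE_EPS) -> float:
    """Percentage change (f_task - f_rs) / f_rs of one feature.

    Raises for a degenerate resting denominator |f_rs| < eps.
    """
    if abs(f_rs) < eps:
        raise ValueError(f"degenerate resting-state denominator |{f_rs}| < {eps}")
    return (f_task - f_rs) / f_rs


@dataclass
class TierTable:
    """Participants x features matrix of inter-state changes with labels.

    ``feature_ids`` indexes columns into ``index.entries`` (features dropped
    for degenerate denominators are missing).  ``dropped`` lists the dropped
    feature positions of the original index.
    """

    matrix: np.ndarray
    participants: tuple[str, ...]
    labels: tuple[str, ...]
    index: FeatureIndex
    feature_ids: np.ndarray
    task_phase: str
    feature_type: str
    dropped: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.participants):
            raise ValueError("row count must equal participant count")
        if len(self.labels) != len(self.participants):
            raise ValueError("one group label per participant required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("TierTable values must be finite")
        self.feature_ids = np.asarray(self.feature_ids, dtype=int)
        if self.matrix.shape[1] != self.feature_ids.size:
            raise ValueError("column count must match feature_ids")

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def entry(self, col: int) -> tuple[str, str, str]:
        """(band, ch1, ch2) identity of table column ``col``."""
        return self.index.entries[self.feature_ids[col]]

    def to_frame(self):
        import pandas as pd

        rows = self.index.to_frame().iloc[self.feature_ids].reset_index(drop=True)
        frames = []
        for r, pid in enumerate(self.participants):
            df = rows.copy()
            df["value"] = self.matrix[r]
            df.insert(0, "state", f"{self.task_phase}-TIER")
            df.insert(0, "feature_type", self.feature_type)
            df.insert(0, "group", self.labels[r])
            df.insert(0, "participant", pid)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def build_tier_table(
    rest: Sequence[FeatureVector],
    task: Sequence[FeatureVector],
    phase: str,
    groups: Sequence[str] | None = None,
    eps: float = DEGENERATE_EPS,
) -> TierTable:
    """Element-wise inter-state change for a cohort of participants.

    ``rest`` and ``task`` must cover the same participants in the same order
    with identical feature type and index.  Features whose resting value is
    degenerate (|f_rs| < eps) for *any* participant are excluded for the
    whole cohort and logged, so the resulting table has a common index.
    """
    if len(rest) != len(task):
        raise ValueError(f"{len(rest)} rest vectors vs {len(task)} task vectors")
    pids_r = [fv.participant_id for fv in rest]
    pids_t = [fv.participant_id for fv in task]
    if pids_r != pids_t:
        diff = set(pids_r).symmetric_difference(pids_t)
        raise ValueError(f"participant mismatch between rest and task: {sorted(diff)}")
    ftype = rest[0].feature_type
    index = rest[0].index
    for fv in list(rest) + list(task):
        if fv.feature_type != ftype:
            raise ValueError("mixed feature types")
        if fv.index != index:
            raise ValueError("feature index differs across vectors")

    R = np.stack([fv.values for fv in rest])
    T = np.stack([fv.values for fv in task])
    degenerate = np.abs(R) < eps
    drop = np.any(degenerate, axis=0)
    if drop.any():
        dropped_ids = np.nonzero(drop)[0]
        logger.warning(
            "dropping %d feature(s) with degenerate resting denominator "
            "(|f_rest| < %g) for at least one participant", drop.sum(), eps,
        )
    else:
        dropped_ids = np.array([], dtype=int)
    keep = ~drop
    matrix = (T[:, keep] - R[:, keep]) / R[:, keep]
    if groups is None:
        groups = ["" for _ in rest]
    return TierTable(
        matrix=matrix,
        participants=tuple(pids_r),
        labels=tuple(groups),
        index=index,
        feature_ids=np.nonzero(keep)[0],
        task_phase=phase,
        feature_type=ftype,
        dropped=tuple(int(i) for i in dropped_ids),
    )
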