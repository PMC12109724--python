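"""End-to-end drivers: recordings -> features -> TIER -> selection -> accuracy.

The frameworks mirror the study design:

* ``rsEEG``   -- features from the resting state alone;
* ``ME-EEG``, ``MM-EEG`` -- features from a task phase alone;
* ``ME-TIER``, ``MM-TIER`` -- the rest-to-task inter-state change.

``evaluate_framework`` runs one (framework, feature type, classification
task, classifier) cell: it builds the participants x D matrix, ranks
features by Fisher score, sweeps the top-n LOPO accuracy curve and reports
the best accuracy with the optimal subset size d and its channel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bands import DEFAULT_BANDS
from .classify import ClassifierSpec
from .io import ParticipantData, load_container
from .recording import segment_rest, segment_task
from .selection import SelectionResult, top_n_lopo_curve
from .spectral import FeatureVector, assemble_feature_vector
from .tier import TierTable, build_tier_table

__all__ = [
    "extract_state_vectors",
    "build_framework_matrix",
    "evaluate_framework",
    "run_config",
    "FRAMEWORKS",
    "TASKS",
]

FRAMEWORKS = ("rsEEG", "ME-EEG", "MM-EEG", "ME-TIER", "MM-TIER")
TASKS = ("AD-HC", "MCI-HC", "AD-MCI", "3class")


def extract_state_vectors(
    participants: Sequence[ParticipantData],
    feature_type: str,
    state: str,
    bands=DEFAULT_BANDS,
    epoch_len_s: float = 2.0,
    n_rest_select: int = 20,
    seed: int = 0,
) -> list[FeatureVector]:
    """One feature vector per participant for a given state.

    Rest epochs are drawn with a per-participant seed derived from ``seed``
    so the selection is reproducible and independent across participants.
    """
    out = []
    for k, p in enumerate(participants):
        if state == "rest":
            es = segment_rest(p.rest_recording(), epoch_len_s,
                              n_select=n_rest_select, seed=seed + k)
            sets = es
        else:
            by_type = segment_task(p.trial_recordings(state), state, epoch_len_s)
            sets = by_type
        out.append(assemble_feature_vector(sets, feature_type, bands,
                                           participant_id=p.participant_id))
    return out


@dataclass
class FrameworkData:
    """Participants x D matrix with labels for one framework."""

    X: np.ndarray
    labels: tuple[str, ...]
    participants: tuple[str, ...]
    table: TierTable | None  # present for TIER frameworks


def build_framework_matrix(
    participants: Sequence[ParticipantData],
    framework: str,
    feature_type: str,
    bands=DEFAULT_BANDS,
    epoch_len_s: float = 2.0,
    n_rest_select: int = 20,
    seed: int = 0,
) -> FrameworkData:
    """Assemble the feature matrix of one framework for the whole cohort."""
    if framework not in FRAMEWORKS:
        raise ValueError(f"framework must be one of {FRAMEWORKS}")
    groups = tuple(p.group for p in participants)
    pids = tuple(p.participant_id for p in participants)
    kw = dict(bands=bands, epoch_len_s=epoch_len_s, n_rest_select=n_rest_select, seed=seed)
    if framework == "rsEEG":
        vecs = extract_state_vectors(participants, feature_type, "rest", **kw)
        return FrameworkData(np.stack([v.values for v in vecs]), groups, pids, None)
    phase = framework[:2]
    task_vecs = extract_state_vectors(participants, feature_type, phase, **kw)
    if framework.endswith("-EEG"):
        return FrameworkData(np.stack([v.values for v in task_vecs]), groups, pids, None)
    rest_vecs = extract_state_vectors(participants, feature_type, "rest", **kw)
    table = build_tier_table(rest_vecs, task_vecs, phase, groups=groups)
    return FrameworkData(table.matrix, groups, pids, table)


def _subset_for_task(data: FrameworkData, task: str) -> tuple[np.ndarray, np.ndarray, tuple]:
    if task == "3class":
        keep = np.ones(len(data.labels), dtype=bool)
    else:
        wanted = set(task.split("-"))
        keep = np.array([g in wanted for g in data.labels])
    y = np.asarray(data.labels)[keep]
    pids = tuple(np.asarray(data.participants)[keep])
    return data.X[keep], y, pids


def evaluate_framework(
    participants: Sequence[ParticipantData],
    framework: str,
    feature_type: str = "PLI",
    task: str = "3class",
    classifier: ClassifierSpec | str = "LDA",
    dc: int = 100,
    selection_mode: str = "paper",
    bands=DEFAULT_BANDS,
    seed: int = 0,
    n_rest_select: int = 20,
) -> tuple[dict, SelectionResult]:
    """Run one framework/feature/task/classifier cell end to end.

    Returns a report dict (accuracy, d, n_channels, ...) and the full
    :class:`SelectionResult` with the accuracy curve.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    spec = ClassifierSpec(classifier) if isinstance(classifier, str) else classifier
    data = build_framework_matrix(participants, framework, feature_type,
                                  bands=bands, seed=seed, n_rest_select=n_rest_select)
    X, y, pids = _subset_for_task(data, task)
    table = data.table if data.table is not None else X
    if data.table is not None:
        # restrict the TIER table rows to the task's participants
        keep = np.array([p in pids for p in data.table.participants])
        table = TierTable(
            matrix=data.table.matrix[keep],
            participants=tuple(np.asarray(data.table.participants)[keep]),
            labels=tuple(np.asarray(data.table.labels)[keep]),
            index=data.table.index,
            feature_ids=data.table.feature_ids,
            task_phase=data.table.task_phase,
            feature_type=data.table.feature_type,
            dropped=data.table.dropped,
        )
        X = table.matrix
    sel = top_n_lopo_curve(table, y, spec=spec, dc=dc, mode=selection_mode)
    report = {
        "framework": framework,
        "feature_type": feature_type,
        "task": task,
        "classifier": spec.kind,
        "selection_mode": selection_mode,
        "accuracy": sel.best_accuracy,
        "d": sel.d_opt,
        "n_channels": sel.n_channels,
        "n_participants": len(y),
        "dc": sel.dc,
    }
    return report, sel


def run_config(cfg: dict) -> list[dict]:
    """Run every combination requested by a configuration mapping.

    Keys: ``input`` (container path), ``frameworks``, ``feature_types``,
    ``classifiers``, ``tasks`` (lists or single values), ``dc``, ``seed``,
    ``selection_mode``, ``n_rest_select``.
    """
    participants = load_container(cfg["input"])

    def listify(key, default):
        v = cfg.get(key, default)
        return [v] if isinstance(v, str) else list(v)

    reports = []
    for fw in listify("frameworks", ["MM-TIER"]):
        for ft in listify("feature_types", ["PLI"]):
            for task in listify("tasks", ["3class"]):
                for clf in listify("classifiers", ["LDA"]):
                    rep, _ = evaluate_framework(
                        participants, fw, ft, task, clf,
                        dc=int(cfg.get("dc", 100)),
                        selection_mode=cfg.get("selection_mode", "paper"),
                        seed=int(cfg.get("seed", 0)),
                        n_rest_select=int(cfg.get("n_rest_select", 20)),
                    )
                    reports.append(rep)
    return reports
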