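"""Continuous EEG recordings and fixed-length epoch sets.

An :class:`EEGRecording` holds one participant's continuous multichannel
signal for one state: ``rest`` (eyes-open resting baseline), ``ME``
(memory-encoding phase of a delayed matching-to-sample trial) or ``MM``
(memory-maintaining phase).  Segmentation follows the study protocol:

* the 90 s resting recording is cut into 45 non-overlapping 2 s epochs
  starting at sample 0, of which a fixed number (default 20) are drawn
  uniformly without replacement;
* each task trial contributes exactly one 2 s epoch taken from phase onset
  (the full ME phase; the first 2 s of the 3 s MM phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["EEGRecording", "EpochSet", "segment_rest", "segment_task", "STATES", "GROUPS"]

STATES = ("rest", "ME", "MM")
GROUPS = ("HC", "MCI", "AD")


@dataclass
class EEGRecording:
    """One continuous multichannel EEG signal with metadata.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered channel labels; must match ``data.shape[0]`` and be unique.
    state
        One of ``rest``, ``ME``, ``MM``.
    task_type
        Task type 1/2/3 for task states, ``None`` for rest.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    state: str
    task_type: int | None = None
    participant_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            offenders = [self.channels[i] for i in np.unique(np.nonzero(bad)[0])]
            raise ValueError(f"non-finite samples in channel(s): {', '.join(offenders)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one or more recordings.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch).
    ``provenance`` records where each epoch came from: for rest, the epoch
    index on the full non-overlapping grid; for task states, the trial index.
    """

    epochs: np.ndarray
    fs: float
    channels: tuple[str, ...]
    epoch_len_s: float
    state: str
    task_type: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x samples)")
        if self.epochs.shape[0] < 1:
            raise ValueError("need at least one epoch")
        expected = round(self.epoch_len_s * self.fs)
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.epochs.shape[2]} != round(epoch_len_s*fs) = {expected}"
            )
        self.channels = tuple(self.channels)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def segment_rest(
    rec: EEGRecording,
    epoch_len_s: float = 2.0,
    n_select: int = 20,
    seed: int | None = 0,
) -> EpochSet:
    """Segment a resting recording and randomly select ``n_select`` epochs.

    The recording is cut into ``floor(duration / epoch_len_s)`` non-overlapping
    epochs starting at sample 0; a trailing remainder shorter than one epoch is
    discarded.  ``n_select`` epochs are then drawn uniformly without
    replacement with ``numpy.random.default_rng(seed)``; the selected grid
    indices are recorded in ``provenance['epoch_indices']``.
    """
    if rec.state != "rest":
        raise ValueError(f"segment_rest expects a rest recording, got state {rec.state!r}")
    spe = round(epoch_len_s * rec.fs)
    n_avail = rec.n_samples // spe
    if n_avail < n_select:
        raise ValueError(
            f"recording provides only {n_avail} epochs of {epoch_len_s} s "
            f"but {n_select} were requested"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_avail, size=n_select, replace=False))
    cut = rec.data[:, : n_avail * spe].reshape(rec.n_channels, n_avail, spe)
    epochs = cut.transpose(1, 0, 2)[idx]
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        channels=rec.channels,
        epoch_len_s=epoch_len_s,
        state="rest",
        provenance={
            "participant_id": rec.participant_id,
            "epoch_indices": idx.tolist(),
            "n_candidates": int(n_avail),
            "seed": seed,
        },
    )


def rest_candidate_count(rec: EEGRecording, epoch_len_s: float = 2.0) -> int:
    """Number of non-overlapping epochs available on the rest grid."""
    return rec.n_samples // round(epoch_len_s * rec.fs)


def segment_task(
    trials: Sequence[EEGRecording],
    phase: str,
    epoch_len_s: float = 2.0,
) -> dict[int, EpochSet]:
    """Cut one epoch from the onset of each task trial, grouped by task type.

    ME trials span exactly the 2 s encoding phase; MM trials span the 3 s
    maintenance phase of which only the first ``epoch_len_s`` seconds enter
    the epoch.

    Returns
    -------
    dict mapping task type -> EpochSet of one epoch per trial.
    """
    if phase not in ("ME", "MM"):
        raise ValueError(f"phase must be 'ME' or 'MM', got {phase!r}")
    if not trials:
        raise ValueError("no trials given")
    by_type: dict[int, list[tuple[int, EEGRecording]]] = {}
    for t, rec in enumerate(trials):
        if rec.state != phase:
            raise ValueError(f"trial {t} ({rec.participant_id!r}) has state {rec.state!r}, expected {phase!r}")
        spe = round(epoch_len_s * rec.fs)
        if rec.n_samples < spe:
            raise ValueError(
                f"trial {t} of participant {rec.participant_id!r} is {rec.duration:.3f} s, "
                f"shorter than the {epoch_len_s} s epoch"
            )
        ttype = rec.task_type if rec.task_type is not None else 0
        by_type.setdefault(ttype, []).append((t, rec))
    out: dict[int, EpochSet] = {}
    for ttype, items in sorted(by_type.items()):
        spe = round(epoch_len_s * items[0][1].fs)
        epochs = np.stack([rec.data[:, :spe] for _, rec in items])
        out[ttype] = EpochSet(
            epochs=epochs,
            fs=items[0][1].fs,
            channels=items[0][1].channels,
            epoch_len_s=epoch_len_s,
            state=phase,
            task_type=ttype if ttype != 0 else None,
            provenance={
                "participant_id": items[0][1].participant_id,
                "trial_indices": [t for t, _ in items],
            },
        )
    return out
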