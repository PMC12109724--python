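"""Reading and writing EEG recordings: HDF5 cohort containers and EDF files.

The cohort container is an HDF5 file with one group per participant::

    /<participant_id>/
        @fs, @channels, @group
        rest            (channels x samples)   first resting session
        rest2           (optional, second session -- stored but not analysed)
        ME/<type>/<trial>   one dataset per task trial (channels x samples)
        MM/<type>/<trial>

EDF (16-bit European Data Format) files are read through MNE.  A minimal
EDF writer is included for fixtures and export; it emits standard 16-bit
EDF readable by MNE and other EDF tools.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .recording import EEGRecording, GROUPS

__all__ = [
    "ParticipantData",
    "save_container",
    "load_container",
    "load_recording",
    "read_edf",
    "write_edf",
]


@dataclass
class ParticipantData:
    """All recordings of one participant, as stored in the cohort container.

    ``trials[(phase, task_type)]`` is the list of trial arrays (channels x
    samples) in presentation order, phase in {"ME", "MM"}, task_type in
    {1, 2, 3}.
    """

    participant_id: str
    group: str
    fs: float
    channels: tuple[str, ...]
    rest: np.ndarray
    trials: dict[tuple[str, int], list[np.ndarray]] = field(default_factory=dict)
    rest2: np.ndarray | None = None

    def rest_recording(self) -> EEGRecording:
        """First-session resting recording (the only one analysed)."""
        return EEGRecording(
            data=self.rest, fs=self.fs, channels=self.channels, state="rest",
            participant_id=self.participant_id, group=self.group,
        )

    def trial_recordings(self, phase: str) -> list[EEGRecording]:
        """All trials of one phase, ordered by task type then trial index."""
        recs = []
        for (ph, ttype) in sorted(self.trials):
            if ph != phase:
                continue
            for arr in self.trials[(ph, ttype)]:
                recs.append(EEGRecording(
                    data=arr, fs=self.fs, channels=self.channels, state=phase,
                    task_type=ttype, participant_id=self.participant_id, group=self.group,
                ))
        return recs


def save_container(path: str | Path, participants: Sequence[ParticipantData]) -> None:
    """Write a cohort of participants to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for p in participants:
            g = f.create_group(p.participant_id)
            g.attrs["fs"] = float(p.fs)
            g.attrs["channels"] = list(p.channels)
            g.attrs["group"] = p.group
            g.create_dataset("rest", data=np.asarray(p.rest, dtype=np.float32))
            if p.rest2 is not None:
                g.create_dataset("rest2", data=np.asarray(p.rest2, dtype=np.float32))
            for (phase, ttype), arrs in sorted(p.trials.items()):
                for k, arr in enumerate(arrs):
                    g.create_dataset(
                        f"{phase}/{ttype}/{k:03d}", data=np.asarray(arr, dtype=np.float32)
                    )


def load_container(path: str | Path) -> list[ParticipantData]:
    """Read all participants from an HDF5 cohort container."""
    out: list[ParticipantData] = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f):
            g = f[pid]
            if "fs" not in g.attrs:
                raise ValueError(f"participant {pid!r}: missing sampling rate attribute")
            fs = float(g.attrs["fs"])
            channels = tuple(
                c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["channels"]
            )
            group = str(g.attrs.get("group", ""))
            if group not in GROUPS:
                group = "HC" if not group else group
            trials: dict[tuple[str, int], list[np.ndarray]] = {}
            for phase in ("ME", "MM"):
                if phase not in g:
                    continue
                for ttype in sorted(g[phase], key=int):
                    arrs = [np.asarray(g[phase][ttype][k], dtype=float)
                            for k in sorted(g[phase][ttype])]
                    trials[(phase, int(ttype))] = arrs
            rest2 = np.asarray(g["rest2"], dtype=float) if "rest2" in g else None
            out.append(ParticipantData(
                participant_id=pid, group=group, fs=fs, channels=channels,
                rest=np.asarray(g["rest"], dtype=float), trials=trials, rest2=rest2,
            ))
    return out


def load_recording(
    path: str | Path,
    state: str,
    participant: str | None = None,
    task_type: int | None = None,
    trial: int = 0,
) -> EEGRecording:
    """Load one validated recording from an EDF file or a cohort container.

    For EDF files the whole file is the recording and ``state`` labels it.
    For containers, ``participant`` selects the participant (default: first
    stored), and task states additionally need ``task_type`` and ``trial``.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, state=state)
    with h5py.File(path, "r") as f:
        pid = participant if participant is not None else sorted(f)[0]
        if pid not in f:
            raise ValueError(f"participant {pid!r} not in container")
        g = f[pid]
        if "fs" not in g.attrs:
            raise ValueError(f"participant {pid!r}: missing sampling rate attribute")
        fs = float(g.attrs["fs"])
        channels = tuple(
            c.decode() if isinstance(c, bytes) else str(c) for c in g.attrs["channels"]
        )
        group = str(g.attrs.get("group", "")) or None
        if state == "rest":
            data = np.asarray(g["rest"], dtype=float)
            ttype = None
        else:
            if task_type is None:
                raise ValueError("task states need task_type")
            keys = sorted(g[state][str(task_type)])
            data = np.asarray(g[state][str(task_type)][keys[trial]], dtype=float)
            ttype = task_type
    return EEGRecording(
        data=data, fs=fs, channels=channels, state=state, task_type=ttype,
        participant_id=pid, group=group if group in GROUPS else None,
    )


# ---------------------------------------------------------------------------
# EDF

def read_edf(path: str | Path, state: str = "rest", participant_id: str = "") -> EEGRecording:
    """Read a 16-bit EDF file into an EEGRecording (microvolt scale)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        state=state,
        participant_id=participant_id or Path(path).stem,
    )


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        b = b[:n]
    return b.ljust(n)


def _fmt8(x: float) -> str:
    """Format a float into at most 8 ASCII chars without corrupting it."""
    for prec in (8, 6, 5, 4, 3, 2, 1):
        s = f"{x:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{x:.0e}"[:8]


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording as standard 16-bit EDF (one-second data records).

    The recording length must be a whole number of seconds and ``fs`` an
    integer, which holds for every fixture this package produces.  Values
    are quantised to 16 bits over each channel's physical range.
    """
    fs = int(round(rec.fs))
    if abs(rec.fs - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_rec = rec.n_samples // fs
    nch = rec.n_channels

    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    # guard degenerate flat channels
    flat = pmaxs - pmins < 1e-9
    pmaxs[flat] = pmins[flat] + 1.0
    # quantisation must use the values exactly as the 8-char header stores them
    pmin_strs = [_fmt8(v) for v in pmins]
    pmax_strs = [_fmt8(v) for v in pmaxs]
    pmins = np.array([float(s) for s in pmin_strs])
    pmaxs = np.array([float(s) for s in pmax_strs])
    pmaxs = np.where(pmaxs - pmins < 1e-9, pmins + 1.0, pmaxs)
    pmax_strs = [_fmt8(v) for v in pmaxs]
    pmaxs = np.array([float(s) for s in pmax_strs])
    dmin, dmax = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(rec.participant_id or "X", 80),
        _pad("Startdate 01-JAN-2000", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + nch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(nch), 4),
    ])
    sig_fields = [
        [_pad(ch, 16) for ch in rec.channels],
        [_pad("AgAgCl electrode", 80)] * nch,
        [_pad("uV", 8)] * nch,
        [_pad(pmin_strs[i], 8) for i in range(nch)],
        [_pad(pmax_strs[i], 8) for i in range(nch)],
        [_pad(str(dmin), 8)] * nch,
        [_pad(str(dmax), 8)] * nch,
        [_pad("", 80)] * nch,
        [_pad(str(fs), 8)] * nch,
        [_pad("", 32)] * nch,
    ]
    scale = (dmax - dmin) / (pmaxs - pmins)
    digital = np.round((rec.data - pmins[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for fields in sig_fields:
            f.write(b"".join(fields))
        for r in range(n_rec):
            # record = all channels' samples for this second, channel-blocked
            f.write(digital[:, r * fs:(r + 1) * fs].tobytes())
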