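"""Synthetic multi-channel EEG with controllable band-specific phase coupling.

Each channel is a sum of five narrowband oscillations (one per canonical
band, carrier at the band centre with slow frequency jitter) plus 1/f
background noise.  Pairwise coupling is imposed in phase: for a coupled
pair, the target channel's band phase equals the source phase plus a
von-Mises(mu, kappa) lag redrawn every 0.5 s block -- within-epoch phase
statistics are stationary while epochs vary, mimicking trial-to-trial
variability.  kappa = 0 gives independent phases (no coupling);
kappa -> inf a constant lag.

Cohorts emulate the study protocol: per participant one 90 s resting
recording and delayed matching-to-sample trials (2 s memory-encoding and
3 s memory-maintaining phases, 10 trials x 3 types x 2 sessions) at 500 Hz
on the 30-channel 10-20 montage.  Rest-to-task coupling changes follow
qualitative group patterns: healthy controls gain parietal coupling and
lose fronto-central coupling, the Alzheimer's group loses coupling
diffusely, and the mild-cognitive-impairment group changes around central
electrodes.  Participant-level lognormal random effects on kappa create
inter-individual variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi
from typing import Sequence

import numpy as np

from .bands import DEFAULT_BANDS, BandSpec
from .io import ParticipantData
from .recording import EEGRecording

__all__ = [
    "CouplingSpec",
    "NoiseSpec",
    "CohortSpec",
    "gen_coupled_signals",
    "gen_cohort",
    "default_cohort_spec",
    "MONTAGE_30",
]

#: the 30 analysis channels of the study's 10-20 montage
MONTAGE_30 = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "Fz",
    "FC3", "FC4", "FCz", "C3", "C4", "Cz",
    "CP3", "CP4", "CPz", "P3", "P4", "Pz",
    "O1", "O2", "Oz",
    "FT7", "T3", "TP7", "T5", "FT8", "T4", "TP8", "T6",
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling of one channel pair in one band.

    ``mu`` is the mean phase lag in radians, ``kappa`` the von-Mises
    concentration: 0 means independent, large values a nearly constant lag.
    """

    band: str
    pair: tuple[str, str]
    mu: float = pi / 3
    kappa: float = 10.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (-pi < self.mu <= pi):
            raise ValueError("mu must lie in (-pi, pi]")
        if self.pair[0] == self.pair[1]:
            raise ValueError("coupled channels must be distinct")
        if self.band not in BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^exponent background noise at a given in-band SNR (dB)."""

    exponent: float = 1.0
    snr_db: float = 0.0


def _jittered_phases(rng, n_ch: int, n: int, fs: float, band: BandSpec,
                     diffusion: float = 0.1) -> np.ndarray:
    """Independent narrowband phase processes, one per channel.

    Each channel gets its own carrier drawn from the middle half of the
    band, slow frequency jitter (std bw/6, smoothed over 0.25 s) and a weak
    phase-diffusion random walk, so phases of independent channels
    decorrelate across epochs while each oscillation stays inside its band.
    """
    bw = band.hi - band.lo
    fc = rng.uniform(band.lo + bw / 4, band.hi - bw / 4, size=(n_ch, 1))
    w = max(int(round(0.25 * fs)), 1)
    df = rng.standard_normal((n_ch, n))
    kernel = np.ones(w) / w
    df = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, df)
    sd = df.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    df = df / sd * (bw / 6.0)
    theta0 = rng.uniform(-pi, pi, size=(n_ch, 1))
    phase = theta0 + 2 * pi * np.cumsum(fc + df, axis=1) / fs
    if diffusion > 0:
        sigma = np.sqrt(pi * bw * diffusion / fs)
        phase = phase + np.cumsum(rng.standard_normal((n_ch, n)) * sigma, axis=1)
    return phase


def gen_coupled_signals(
    n_channels: int,
    duration: float,
    fs: float,
    couplings: Sequence[CouplingSpec] = (),
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = 0,
    channels: Sequence[str] | None = None,
    state: str = "rest",
    task_type: int | None = None,
    participant_id: str = "",
    group: str | None = None,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    block_s: float = 0.5,
) -> EEGRecording:
    """Generate one multichannel recording with the given phase couplings.

    Deterministic given ``seed``.  Raises if two couplings target the same
    (band, pair) or the same target channel twice within a band.
    """
    if channels is None:
        channels = MONTAGE_30[:n_channels] if n_channels <= 30 else tuple(
            f"ch{i:02d}" for i in range(n_channels))
    channels = tuple(channels)
    if len(channels) != n_channels:
        raise ValueError("channel list length must equal n_channels")
    ch_idx = {c: i for i, c in enumerate(channels)}
    seen_pairs = set()
    seen_targets = set()
    for c in couplings:
        key = (c.band, frozenset(c.pair))
        if key in seen_pairs:
            raise ValueError(f"conflicting couplings for band {c.band}, pair {c.pair}")
        seen_pairs.add(key)
        tgt = (c.band, c.pair[1])
        if tgt in seen_targets:
            raise ValueError(f"channel {c.pair[1]} is coupling target twice in band {c.band}")
        seen_targets.add(tgt)
        for ch in c.pair:
            if ch not in ch_idx:
                raise ValueError(f"coupling channel {ch!r} not in montage")
    if couplings and max(BAND_BY_NAME[c.band].hi for c in couplings) >= fs / 2:
        raise ValueError("coupled band exceeds Nyquist")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    block = max(int(round(block_s * fs)), 1)
    n_blocks = -(-n // block)
    data = np.zeros((n_channels, n))
    for band in bands:
        if band.hi >= fs / 2:
            continue
        ph = _jittered_phases(rng, n_channels, n, fs, band)
        for c in couplings:
            if c.band != band.name:
                continue
            i, j = ch_idx[c.pair[0]], ch_idx[c.pair[1]]
            lags = rng.vonmises(c.mu, c.kappa, size=n_blocks) if c.kappa > 0 else \
                rng.uniform(-pi, pi, size=n_blocks)
            ph[j] = ph[i] + np.repeat(lags, block)[:n]
        data += np.cos(ph)

    # 1/f background, scaled so in-band (1-45 Hz) SNR matches the spec
    white = rng.standard_normal((n_channels, n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-noise.exponent / 2.0)
    shape[0] = 0.0
    spec = np.fft.rfft(white, axis=1) * shape
    pink = np.fft.irfft(spec, n=n, axis=1)
    band_mask = (freqs >= 1.0) & (freqs < 45.0)
    frac = (np.abs(shape[band_mask]) ** 2).sum() / max((np.abs(shape[nz]) ** 2).sum(), 1e-30)
    sig_var = data.var(axis=1, keepdims=True)
    pink_var = pink.var(axis=1, keepdims=True)
    pink_var[pink_var == 0] = 1.0
    target_inband = sig_var / (10.0 ** (noise.snr_db / 10.0))
    pink = pink * np.sqrt(target_inband / (pink_var * frac))
    data = data + pink

    return EEGRecording(
        data=data, fs=fs, channels=channels, state=state, task_type=task_type,
        participant_id=participant_id, group=group,
    )


@dataclass
class CohortSpec:
    """Study-protocol cohort layout and group coupling structure."""

    group_sizes: dict = field(default_factory=lambda: {"HC": 27, "MCI": 24, "AD": 21})
    n_channels: int = 30
    fs: float = 500.0
    rest_duration: float = 90.0
    n_trials: int = 10
    n_sessions: int = 2
    task_types: tuple = (1, 2, 3)
    me_duration: float = 2.0
    mm_duration: float = 3.0
    rest_couplings: dict = field(default_factory=dict)   # group -> [CouplingSpec]
    task_couplings: dict = field(default_factory=dict)   # group -> [CouplingSpec]
    kappa_sigma: float = 0.25
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0
    channels: tuple | None = None

    def __post_init__(self) -> None:
        for g, s in self.group_sizes.items():
            if s < 2:
                raise ValueError(f"group {g} needs at least 2 participants")


def default_cohort_spec(**overrides) -> CohortSpec:
    """Paper-protocol cohort with qualitative theta-band group patterns.

    All groups share moderate resting theta coupling on a common edge set;
    the rest-to-task deltas differ: HC gains parietal and loses
    fronto-central coupling, AD loses coupling diffusely, MCI changes around
    the central midline.
    """
    # edges that will strengthen start from weak resting coupling, edges
    # that will weaken start strong, so both directions have dynamic range
    k_lo, k_hi = 1.5, 10.0
    up, down = 30.0, 0.3
    shared = [
        CouplingSpec("theta", ("P3", "Pz"), kappa=k_lo),
        CouplingSpec("theta", ("P4", "CPz"), kappa=k_lo),
        CouplingSpec("theta", ("Fz", "FCz"), kappa=k_hi),
        CouplingSpec("theta", ("F3", "FC3"), kappa=k_hi),
        CouplingSpec("theta", ("C3", "Cz"), kappa=k_lo),
        CouplingSpec("theta", ("C4", "FC4"), kappa=k_hi),
        CouplingSpec("theta", ("T3", "TP7"), kappa=k_hi),
        CouplingSpec("theta", ("O1", "Oz"), kappa=k_hi),
        CouplingSpec("alpha", ("P3", "O1"), kappa=8.0),
        CouplingSpec("alpha", ("P4", "O2"), kappa=8.0),
    ]
    rest = {g: list(shared) for g in ("HC", "MCI", "AD")}
    task = {
        # parietal increase + fronto-central decrease
        "HC": _merge(shared, [
            replace(shared[0], kappa=up), replace(shared[1], kappa=up),
            replace(shared[2], kappa=down), replace(shared[3], kappa=down),
        ]),
        # central changes
        "MCI": _merge(shared, [
            replace(shared[4], kappa=up), replace(shared[5], kappa=down),
        ]),
        # diffuse decrease, no compensatory increase
        "AD": _merge(shared, [
            replace(shared[k], kappa=down) for k in (2, 3, 5, 6, 7)
        ]),
    }
    spec = CohortSpec(rest_couplings=rest, task_couplings=task)
    if overrides:
        spec = replace(spec, **overrides)
    if spec.channels is None and spec.n_channels < 30:
        # keep the electrodes carrying planted couplings, pad from the montage
        wanted: list[str] = []
        for c in shared:
            for ch in c.pair:
                if ch not in wanted:
                    wanted.append(ch)
        wanted = [ch for ch in MONTAGE_30 if ch in wanted]
        pad = [ch for ch in MONTAGE_30 if ch not in wanted]
        chans = tuple((wanted + pad)[: spec.n_channels])
        present = set(chans)
        spec = replace(
            spec,
            channels=chans,
            rest_couplings={g: [c for c in v if set(c.pair) <= present]
                            for g, v in spec.rest_couplings.items()},
            task_couplings={g: [c for c in v if set(c.pair) <= present]
                            for g, v in spec.task_couplings.items()},
        )
    return spec


def _merge(base: Sequence[CouplingSpec], deltas: Sequence[CouplingSpec]) -> list[CouplingSpec]:
    """Task couplings = rest couplings with per-(band, pair) replacements."""
    out = {(c.band, frozenset(c.pair)): c for c in base}
    for c in deltas:
        out[(c.band, frozenset(c.pair))] = c
    return list(out.values())


def gen_cohort(spec: CohortSpec) -> list[ParticipantData]:
    """Generate the full cohort as container-ready participant records.

    Each participant gets one resting recording and, per session, task type
    and trial, one ME and one MM recording generated under the group's task
    couplings with that participant's kappa random effect.  Deterministic
    given ``spec.seed``.
    """
    channels = spec.channels
    if channels is None:
        channels = MONTAGE_30[:spec.n_channels] if spec.n_channels <= 30 else tuple(
            f"ch{i:02d}" for i in range(spec.n_channels))
    root = np.random.SeedSequence(spec.seed)
    out: list[ParticipantData] = []
    pid_no = 0
    for group in sorted(spec.group_sizes):
        for _ in range(spec.group_sizes[group]):
            pid_no += 1
            pid = f"sub-{pid_no:03d}"
            ss = root.spawn(1)[0]
            # the same participant factor applies to a coupling at rest and task
            eff_rng = np.random.default_rng(ss.spawn(1)[0])
            factors: dict = {}
            rest_c = [replace(c, kappa=c.kappa * _factor(factors, c, eff_rng, spec.kappa_sigma))
                      for c in spec.rest_couplings.get(group, [])]
            task_c = [replace(c, kappa=c.kappa * _factor(factors, c, eff_rng, spec.kappa_sigma))
                      for c in spec.task_couplings.get(group, [])]
            seeds = iter(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31, size=10_000))
            rest = gen_coupled_signals(
                len(channels), spec.rest_duration, spec.fs, rest_c, spec.noise,
                seed=int(next(seeds)), channels=channels, state="rest",
                participant_id=pid, group=group,
            ).data
            trials: dict = {}
            for ttype in spec.task_types:
                me_list, mm_list = [], []
                for _s in range(spec.n_sessions):
                    for _t in range(spec.n_trials):
                        me_list.append(gen_coupled_signals(
                            len(channels), spec.me_duration, spec.fs, task_c,
                            spec.noise, seed=int(next(seeds)), channels=channels,
                            state="ME", task_type=ttype, participant_id=pid, group=group,
                        ).data)
                        mm_list.append(gen_coupled_signals(
                            len(channels), spec.mm_duration, spec.fs, task_c,
                            spec.noise, seed=int(next(seeds)), channels=channels,
                            state="MM", task_type=ttype, participant_id=pid, group=group,
                        ).data)
                trials[("ME", ttype)] = me_list
                trials[("MM", ttype)] = mm_list
            out.append(ParticipantData(
                participant_id=pid, group=group, fs=spec.fs, channels=tuple(channels),
                rest=rest, trials=trials,
            ))
    return out


def _factor(factors: dict, c: CouplingSpec, rng, sigma: float) -> float:
    key = (c.band, frozenset(c.pair))
    if key not in factors:
        factors[key] = float(np.exp(rng.normal(0.0, sigma)))
    return factors[key]
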