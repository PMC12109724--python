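"""Spectral features: inter-electrode relative power and magnitude-squared coherence.

Both features are computed per frequency band and electrode pair from the
raw FFT of 2 s epochs (no taper, no zero padding); frequency bins belong to
a band via the half-open rule ``lo <= f < hi`` so adjacent bands never share
a bin.

Relative band power of a channel is the ratio of power in the band of
interest to power over the broadband range 1-45 Hz, with per-epoch power
spectra averaged before the ratio.  The inter-electrode relative power of a
pair (X, Y) is the asymmetry index

    RP = (P(X) - P(Y)) / (P(X) + P(Y))  in [-1, 1].

Magnitude-squared coherence uses auto- and cross-spectra estimated as means
of per-epoch periodograms:

    Coh(f) = |Gxy(f)|^2 / (Gxx(f) Gyy(f))  in [0, 1],

summarised per band as the unweighted mean over in-band bins (optionally by
pooling the spectra over bins before the ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bands import DEFAULT_BANDS, TOTAL_BAND, BandSpec, FeatureIndex
from .recording import EpochSet

__all__ = [
    "FeatureVector",
    "band_power",
    "relative_power",
    "coherence_band",
    "assemble_feature_vector",
]

FEATURE_TYPES = ("RP", "Coh", "PLI")


@dataclass
class FeatureVector:
    """A participant/state feature vector on the canonical (band, pair) index."""

    values: np.ndarray
    index: FeatureIndex
    feature_type: str
    state: str
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index),):
            raise ValueError(
                f"values length {self.values.shape} does not match index ({len(self.index)})"
            )
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"feature_type must be one of {FEATURE_TYPES}")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        df = self.index.to_frame()
        df["value"] = self.values
        df.insert(0, "state", self.state)
        df.insert(0, "feature_type", self.feature_type)
        df.insert(0, "participant", self.participant_id)
        return df


# ---------------------------------------------------------------------------
# power


def _epoch_psd(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies and per-epoch magnitude-squared FFT spectra (..., n_bins)."""
    L = epochs.shape[-1]
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    spec = np.fft.rfft(epochs, axis=-1)
    return freqs, np.abs(spec) ** 2


def band_power(
    epoch_channel: np.ndarray,
    fs: float,
    band: BandSpec,
    total_band: BandSpec = TOTAL_BAND,
) -> float:
    """Relative band power of a single-channel epoch.

    Ratio of FFT power summed over bins in ``[band.lo, band.hi)`` to power
    summed over the broadband range, so the result lies in [0, 1].
    """
    x = np.asarray(epoch_channel, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("epoch_channel must be a 1-D signal of at least 2 samples")
    if not (total_band.lo <= band.lo and band.hi <= total_band.hi):
        raise ValueError(f"band {band.name} not contained in total band")
    freqs, psd = _epoch_psd(x, fs)
    total = psd[total_band.contains(freqs)].sum()
    if total <= 0:
        raise ValueError("zero total power in the broadband range (flat signal?)")
    return float(psd[band.contains(freqs)].sum() / total)


def relative_power(P_X: float, P_Y: float) -> float:
    """Inter-electrode relative power (P_X - P_Y) / (P_X + P_Y)."""
    s = P_X + P_Y
    if s <= 0:
        raise ValueError("P_X + P_Y must be positive")
    return (P_X - P_Y) / s


def _rp_matrix(epochs: np.ndarray, fs: float, bands: Sequence[BandSpec],
               total_band: BandSpec = TOTAL_BAND) -> np.ndarray:
    """Relative band power per (channel, band) with epoch-averaged spectra.

    ``epochs``: (n_epochs, n_channels, L).  Returns (n_channels, n_bands).
    """
    freqs, psd = _epoch_psd(epochs, fs)
    mean_psd = psd.mean(axis=0)  # (n_ch, n_bins)
    total = mean_psd[:, total_band.contains(freqs)].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in the broadband range for some channel")
    P = np.stack([mean_psd[:, b.contains(freqs)].sum(axis=1) for b in bands], axis=1)
    return P / total[:, None]


# ---------------------------------------------------------------------------
# coherence


def coherence_band(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    fs: float,
    band: BandSpec,
    pooled: bool = False,
) -> float:
    """Band magnitude-squared coherence from epoch-averaged spectra.

    Auto-spectra are means of per-epoch |X(f)|^2, the cross-spectrum the mean
    of X(f) conj(Y(f)); per-bin coherence |Gxy|^2/(Gxx Gyy) is averaged over
    in-band bins.  Bins with a zero auto-spectrum are excluded; if every
    in-band bin is degenerate an error is raised.  With ``pooled=True`` the
    spectra are summed over bins before the ratio.
    """
    x = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"epoch shapes differ: {x.shape} vs {y.shape}")
    L = x.shape[1]
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    sel = band.contains(freqs)
    X = np.fft.rfft(x, axis=1)[:, sel]
    Y = np.fft.rfft(y, axis=1)[:, sel]
    Gxx = np.mean(np.abs(X) ** 2, axis=0)
    Gyy = np.mean(np.abs(Y) ** 2, axis=0)
    Gxy = np.mean(X * np.conj(Y), axis=0)
    if pooled:
        gx, gy = Gxx.sum(), Gyy.sum()
        if gx <= 0 or gy <= 0:
            raise ValueError(f"all in-band bins degenerate in band {band.name}")
        return float(np.abs(Gxy.sum()) ** 2 / (gx * gy))
    ok = (Gxx > 0) & (Gyy > 0)
    if not ok.any():
        raise ValueError(f"all in-band bins degenerate in band {band.name}")
    msc = np.abs(Gxy[ok]) ** 2 / (Gxx[ok] * Gyy[ok])
    return float(msc.mean())


def _coh_matrix(epochs: np.ndarray, fs: float, bands: Sequence[BandSpec],
                pooled: bool = False) -> np.ndarray:
    """Coherence per (band, pair) for one epoch set.

    ``epochs``: (n_epochs, n_channels, L).  Returns flat (n_bands * n_pairs,)
    in canonical band-major order.
    """
    n_ch = epochs.shape[1]
    L = epochs.shape[2]
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    keep = np.zeros_like(freqs, dtype=bool)
    for b in bands:
        keep |= np.asarray(b.contains(freqs))
    X = np.fft.rfft(epochs, axis=-1)[..., keep]  # (n_e, n_ch, nf)
    fk = freqs[keep]
    Gxx = np.mean(np.abs(X) ** 2, axis=0)  # (n_ch, nf)
    # cross-spectra for all ordered pairs at once
    Gxy = np.einsum("eif,ejf->ijf", X, np.conj(X)) / X.shape[0]
    iu, ju = np.triu_indices(n_ch, k=1)
    out = []
    for b in bands:
        sel = np.asarray(b.contains(fk))
        gxx = Gxx[:, sel]
        gxy = Gxy[:, :, sel][iu, ju]  # (n_pairs, nb)
        denom = gxx[iu] * gxx[ju]
        if pooled:
            num = np.abs(gxy.sum(axis=1)) ** 2
            den = gxx[iu].sum(axis=1) * gxx[ju].sum(axis=1)
            out.append(num / den)
        else:
            ok = denom > 0
            msc = np.zeros_like(denom)
            msc[ok] = np.abs(gxy[ok]) ** 2 / denom[ok]
            counts = ok.sum(axis=1)
            if np.any(counts == 0):
                raise ValueError(f"all in-band bins degenerate in band {b.name}")
            out.append(msc.sum(axis=1) / counts)
    return np.concatenate(out)


def _rp_pairs(P: np.ndarray) -> np.ndarray:
    """Inter-electrode RP for all pairs; P is (n_ch, n_bands) -> flat band-major."""
    n_ch = P.shape[0]
    iu, ju = np.triu_indices(n_ch, k=1)
    num = P[iu] - P[ju]  # (n_pairs, n_bands)
    den = P[iu] + P[ju]
    if np.any(den <= 0):
        raise ValueError("zero P_X + P_Y for some pair")
    return (num / den).T.ravel()  # band-major


# ---------------------------------------------------------------------------
# assembly


def _as_type_dict(epoch_sets) -> dict[int, EpochSet]:
    if isinstance(epoch_sets, EpochSet):
        return {0: epoch_sets}
    if isinstance(epoch_sets, Mapping):
        return dict(epoch_sets)
    return {k: es for k, es in enumerate(epoch_sets)}


def assemble_feature_vector(
    epoch_sets,
    feature_type: str,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    participant_id: str = "",
    pooled_coherence: bool = False,
) -> FeatureVector:
    """Reduce one state's epochs to a single D-dimensional feature vector.

    ``epoch_sets`` is a single :class:`EpochSet` (resting state) or a mapping
    task_type -> EpochSet (task state).  Task features are computed per type
    and averaged across types with equal weight; PLI is additionally computed
    per epoch and averaged over epochs within a type, while RP and coherence
    average per-epoch spectra within a type before forming the ratio.
    """
    sets = _as_type_dict(epoch_sets)
    if not sets:
        raise ValueError("no epoch sets given")
    first = next(iter(sets.values()))
    for es in sets.values():
        if es.channels != first.channels:
            raise ValueError("mismatched channel sets across epoch sets")
        if es.fs != first.fs:
            raise ValueError("mismatched sampling rates across epoch sets")
    index = FeatureIndex(bands, first.channels)

    per_type = []
    for ttype in sorted(sets):
        es = sets[ttype]
        if feature_type == "RP":
            P = _rp_matrix(es.epochs, es.fs, bands)
            per_type.append(_rp_pairs(P))
        elif feature_type == "Coh":
            per_type.append(_coh_matrix(es.epochs, es.fs, bands, pooled=pooled_coherence))
        elif feature_type == "PLI":
            from .pli import fb_pli_epochs

            vecs = fb_pli_epochs(es.epochs, es.fs, bands)
            per_type.append(vecs.mean(axis=0))
        else:
            raise ValueError(f"unknown feature_type {feature_type!r}")
    values = np.mean(per_type, axis=0)
    return FeatureVector(
        values=values, index=index, feature_type=feature_type,
        state=first.state, participant_id=participant_id or first.provenance.get("participant_id", ""),
    )
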