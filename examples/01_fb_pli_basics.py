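"""Filter-bank phase lag index on a synthetically coupled channel pair.

Generates a four-channel recording in which one theta-band pair is phase
coupled at a pi/2 lag, then measures per-band PLI for every pair.  The
coupled pair should stand far above the chance floor of band-limited
signals; uncoupled pairs should sit near it.
"""

import numpy as np

from wmtier import CouplingSpec, NoiseSpec, gen_coupled_signals, segment_rest
from wmtier.bands import DEFAULT_BANDS, FeatureIndex
from wmtier.pli import fb_pli_epochs

CHANNELS = ("F3", "Fz", "FC3", "FC4")

rec = gen_coupled_signals(
    n_channels=4, duration=44.0, fs=250.0, channels=CHANNELS,
    couplings=[CouplingSpec("theta", ("F3", "Fz"), mu=np.pi / 2, kappa=50.0)],
    noise=NoiseSpec(snr_db=6.0), seed=3,
)
epochs = segment_rest(rec, epoch_len_s=2.0, n_select=20, seed=0)
values = fb_pli_epochs(epochs.epochs, rec.fs).mean(axis=0)
index = FeatureIndex(DEFAULT_BANDS, CHANNELS)

print("mean PLI over 20 two-second epochs")
print(f"{'band':8s}{'pair':12s}{'PLI':>6s}")
for (band, c1, c2), v in zip(index.entries, values):
    marker = "  <- coupled pair" if (band, c1, c2) == ("theta", "F3", "Fz") else ""
    print(f"{band:8s}{c1 + '-' + c2:12s}{v:6.3f}{marker}")

print("\nThe coupled theta pair locks near 1; other pairs stay near the")
print("chance floor (~0.2-0.3 for 2 s epochs of narrowband signals).")
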