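"""Generator contracts: determinism, coupling recovery, chance levels, round-trips."""

import numpy as np
import pytest

from wmtier.bands import DEFAULT_BANDS, FeatureIndex
from wmtier.io import load_container, save_container
from wmtier.pli import bandpass, fb_pli_epochs
from wmtier.recording import segment_rest
from wmtier.synth import (
    CouplingSpec,
    NoiseSpec,
    default_cohort_spec,
    gen_cohort,
    gen_coupled_signals,
)

FS = 250.0
CH4 = ("F3", "Fz", "FC3", "FC4")


def chance_level_pli(band, fs=FS, n_epochs=20, length=500, seed=99):
    """Monte-Carlo oracle: mean per-epoch PLI of two independent band-limited
    Gaussian signals.  This is the chance floor against which coupling is
    judged; it scales like sqrt(2 / (pi * T * bandwidth)) and is therefore
    well above zero for narrow, low-frequency bands on 2 s epochs."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(3):
        x = bandpass(rng.standard_normal((2, n_epochs * length)), band, fs)
        ep = x.reshape(2, n_epochs, length).transpose(1, 0, 2)
        idx = FeatureIndex(DEFAULT_BANDS, ("a", "b"))
        k = [e[0] for e in idx.entries].index(band.name)
        vals.append(fb_pli_epochs(ep, fs).mean(axis=0)[k])
    return float(np.mean(vals))


def theta_pair_values(rec, n_epochs=20):
    es = segment_rest(rec, 2.0, n_select=n_epochs, seed=0)
    mean = fb_pli_epochs(es.epochs, rec.fs).mean(axis=0)
    idx = FeatureIndex(DEFAULT_BANDS, rec.channels)
    return {e[1:]: mean[k] for k, e in enumerate(idx.entries) if e[0] == "theta"}


class TestGenCoupledSignals:
    def test_same_seed_reproduces_recording_exactly(self):
        kw = dict(n_channels=4, duration=4.0, fs=FS, channels=CH4,
                  couplings=[CouplingSpec("theta", ("F3", "Fz"), kappa=20)])
        a = gen_coupled_signals(seed=5, **kw)
        b = gen_coupled_signals(seed=5, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        c = gen_coupled_signals(seed=6, **kw)
        assert not np.array_equal(a.data, c.data)

    def test_conflicting_couplings_rejected(self):
        with pytest.raises(ValueError, match="conflict"):
            gen_coupled_signals(4, 2.0, FS, channels=CH4, couplings=[
                CouplingSpec("theta", ("F3", "Fz"), kappa=5),
                CouplingSpec("theta", ("Fz", "F3"), kappa=9),
            ])

    def test_strong_theta_coupling_separates_from_chance(self):
        # moderate noise isolates the coupling machinery itself
        rec = gen_coupled_signals(
            4, 44.0, FS, channels=CH4, seed=3, noise=NoiseSpec(snr_db=6.0),
            couplings=[CouplingSpec("theta", ("F3", "Fz"), mu=np.pi / 2, kappa=50)],
        )
        vals = theta_pair_values(rec)
        chance = chance_level_pli(DEFAULT_BANDS[1])
        assert vals[("F3", "Fz")] >= 0.8
        others = [v for p, v in vals.items() if p != ("F3", "Fz")]
        # single uncoupled pairs fluctuate with the luck of the carrier draw,
        # but on average they sit at the band-limited chance floor
        assert abs(np.mean(others) - chance) < 0.08
        assert max(others) < chance + 0.2

    def test_no_coupling_stays_at_band_chance_level(self):
        rec = gen_coupled_signals(4, 44.0, FS, channels=CH4, seed=4, couplings=[])
        es = segment_rest(rec, 2.0, n_select=20, seed=0)
        mean = fb_pli_epochs(es.epochs, FS).mean(axis=0)
        idx = FeatureIndex(DEFAULT_BANDS, CH4)
        for band in DEFAULT_BANDS[:3]:
            chance = chance_level_pli(band)
            k = [i for i, e in enumerate(idx.entries) if e[0] == band.name]
            assert abs(mean[k].mean() - chance) < 0.08
            assert mean[k].max() < chance + 0.2

    def test_unknown_channel_in_coupling_rejected(self):
        with pytest.raises(ValueError, match="montage"):
            gen_coupled_signals(4, 2.0, FS, channels=CH4,
                                couplings=[CouplingSpec("theta", ("F3", "Oz"))])


class TestGenCohort:
    def test_cohort_round_trips_container_and_validates(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.h5"
        save_container(path, small_cohort[:3])
        back = load_container(path)
        assert len(back) == 3
        for a, b in zip(small_cohort[:3], back):
            assert a.participant_id == b.participant_id and a.group == b.group
            np.testing.assert_allclose(a.rest, b.rest, atol=1e-4)
            rec = b.rest_recording()  # validation runs in the constructor
            assert rec.duration == pytest.approx(44.0)
            assert len(b.trial_recordings("ME")) == 15
            assert len(b.trial_recordings("MM")) == 15

    def test_cohort_is_seed_deterministic(self):
        spec = default_cohort_spec(group_sizes={"HC": 2, "MCI": 2, "AD": 2},
                                   n_channels=8, fs=125.0, rest_duration=10.0,
                                   n_trials=1, n_sessions=1, seed=3)
        a = gen_cohort(spec)
        b = gen_cohort(spec)
        np.testing.assert_array_equal(a[0].rest, b[0].rest)
        np.testing.assert_array_equal(a[3].trials[("MM", 2)][0], b[3].trials[("MM", 2)][0])

    def test_null_cohort_tier_centred_on_zero(self):
        # no rest-to-task deltas: task couplings equal rest couplings
        spec = default_cohort_spec(group_sizes={"HC": 3, "MCI": 2, "AD": 2},
                                   n_channels=12, fs=250.0, rest_duration=44.0,
                                   n_trials=3, n_sessions=1, seed=7)
        spec.task_couplings = spec.rest_couplings
        cohort = gen_cohort(spec)
        from wmtier.pipeline import build_framework_matrix

        data = build_framework_matrix(cohort, "ME-TIER", "PLI", seed=0)
        assert abs(data.X.mean()) < 0.1

    def test_group_pattern_direction_matches_design(self, small_cohort):
        # HC parietal edges strengthen, AD frontal/temporal edges weaken
        from wmtier.pipeline import build_framework_matrix

        data = build_framework_matrix(small_cohort, "MM-TIER", "PLI", seed=0)
        tab = data.table
        entries = [tab.entry(c) for c in range(tab.n_features)]
        labels = np.asarray(tab.labels)

        def group_mean(pair_entry, group):
            col = entries.index(pair_entry)
            return tab.matrix[labels == group, col].mean()

        p3pz = ("theta", "P3", "Pz")
        assert group_mean(p3pz, "HC") > group_mean(p3pz, "AD") + 0.15
        assert group_mean(p3pz, "HC") > group_mean(p3pz, "MCI") + 0.15
        fzfcz = ("theta", "Fz", "FCz")
        assert group_mean(fzfcz, "AD") < -0.15
        assert group_mean(fzfcz, "MCI") > group_mean(fzfcz, "AD") + 0.15

    def test_kappa_dose_increases_separability(self):
        # rest-to-task coupling change planted in MCI only, at three doses
        from wmtier.pipeline import evaluate_framework
        from wmtier.synth import CohortSpec

        chans = ("F3", "Fz", "C3", "Cz", "P3", "Pz")
        base = [CouplingSpec("theta", ("C3", "Cz"), kappa=1.5)]
        accs = []
        for dose in (1.5, 6.0, 30.0):
            spec = CohortSpec(
                group_sizes={"HC": 5, "MCI": 5}, n_channels=6, fs=250.0,
                rest_duration=44.0, n_trials=5, n_sessions=1, task_types=(1,),
                channels=chans,
                rest_couplings={"HC": base, "MCI": base},
                task_couplings={"HC": base,
                                "MCI": [CouplingSpec("theta", ("C3", "Cz"), kappa=dose)]},
                seed=21,
            )
            rep, _ = evaluate_framework(gen_cohort(spec), "ME-TIER", "PLI",
                                        "MCI-HC", "LDA", dc=8, seed=0)
            accs.append(rep["accuracy"])
        assert accs[-1] >= accs[0]
        assert max(accs) > 0.5
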