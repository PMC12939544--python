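"""Ingest contracts: EDF round-trip, trial archives, filtering, resampling,
screening, cropping, segmentation, channel selection, balancing."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import welch

from eegaffect.containers import CohortSample, Epoch, RatedTrial
from eegaffect.edf import quantization_step, write_edf
from eegaffect.ingest import (
    ChannelError,
    CohortError,
    FormatError,
    balance_cohort,
    bandpass,
    crop_steady_state,
    epochs_from_rated_trials,
    read_deap_archive,
    read_edf,
    resample,
    screen_trial,
    segment,
    select_channels,
)
from eegaffect.montage import CANONICAL_CHANNELS
from eegaffect.synth import DEPRESSION_PRESET, generate_epoch


class TestEdfRoundTrip:
    def test_write_read_within_quantization(self, tmp_path):
        epoch = generate_epoch(DEPRESSION_PRESET, seed=3)
        path = tmp_path / "epoch.edf"
        write_edf(path, epoch.data, epoch.fs, list(epoch.channel_names))
        data, fs, names = read_edf(path)
        assert fs == 128.0
        assert [n.strip() for n in names] == list(CANONICAL_CHANNELS)
        step = quantization_step(epoch.data)
        assert np.all(np.abs(data - epoch.data) <= step[:, None] + 1e-9)

    def test_missing_channel_named_in_error(self, tmp_path):
        epoch = generate_epoch(DEPRESSION_PRESET, seed=3)
        path = tmp_path / "noc4.edf"
        names = [n for n in CANONICAL_CHANNELS if n != "C4"]
        write_edf(path, epoch.data[:7], epoch.fs, names)
        with pytest.raises(ChannelError, match="C4"):
            read_edf(path, channels=list(CANONICAL_CHANNELS))

    def test_sample_count_arithmetic(self, tmp_path):
        # 5 minutes at 128 Hz
        data = np.zeros((2, 5 * 60 * 128))
        data[:, 0] = 1.0
        path = tmp_path / "fivemin.edf"
        write_edf(path, data, 128.0, ["Fp1", "Fp2"])
        out, fs, _ = read_edf(path)
        assert out.shape[1] == 38400

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_edf("/nonexistent/file.edf")


class TestDeapArchive:
    @staticmethod
    def _make_archive(tmp_path, n_trials=40, n_ch=32, n_samp=8064, ratings=None):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(n_trials, n_ch, n_samp)).astype(np.float32)
        if ratings is None:
            ratings = rng.uniform(1, 9, size=(n_trials, 4))
        path = tmp_path / "s01.npz"
        np.savez(path, data=data, labels=ratings)
        return path

    def test_forty_trials_recovered(self, tmp_path):
        trials = read_deap_archive(self._make_archive(tmp_path))
        assert len(trials) == 40
        assert trials[0].signal.shape == (32, 8064)
        # 8064 samples at 128 Hz = 63 s (3 s baseline + 60 s stimulus)
        assert trials[0].duration_s == pytest.approx(63.0)

    def test_shape_mismatch_rejected(self, tmp_path):
        path = self._make_archive(tmp_path, n_samp=5000)
        with pytest.raises(FormatError, match="8064"):
            read_deap_archive(path)

    def test_out_of_scale_ratings_rejected(self, tmp_path):
        ratings = np.full((40, 4), 10.0)
        path = self._make_archive(tmp_path, ratings=ratings)
        with pytest.raises(ValueError):
            read_deap_archive(path)


class TestBandpass:
    def test_in_band_sine_preserved(self):
        t = np.arange(4 * 512) / 512
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass(x, fs=512)
        mid = slice(256, -256)  # ignore edge transients
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("freq,max_gain", [(1.0, 0.01), (55.0, 0.01)])
    def test_out_of_band_attenuation(self, freq, max_gain):
        """>= 20 dB power attenuation at 1 Hz and 55 Hz."""
        t = np.arange(8 * 512) / 512
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, fs=512)
        assert np.mean(y**2) <= max_gain * np.mean(x**2)

    def test_zero_signal(self):
        assert np.allclose(bandpass(np.zeros(1000), fs=256), 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), fs=80.0)


class TestResample:
    def test_identity_when_rates_equal(self):
        x = np.arange(100.0)
        assert np.array_equal(resample(x, 128, 128), x)

    def test_length_arithmetic(self):
        x = np.zeros((3, 38400))
        assert resample(x, 512, 128).shape == (3, 9600)

    def test_spectral_peak_preserved(self):
        t = np.arange(10 * 512) / 512
        x = np.sin(2 * np.pi * 10 * t)
        y = resample(x, 512, 128)
        f, p = welch(y, fs=128, nperseg=256)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            resample(np.zeros(10), 128, 512)


class TestScreenTrial:
    @staticmethod
    def _trial(valence, arousal):
        return RatedTrial(
            signal=np.zeros((1, 7680)), valence=valence, arousal=arousal, fs=128
        )

    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [
            (2.0, 4.0, True),
            (2.5, 4.0, False),  # strict inequality on valence
            (1.0, 5.0, False),  # strict inequality on arousal
            (2.49, 4.99, True),
        ],
    )
    def test_strict_thresholds(self, valence, arousal, expected):
        assert screen_trial(self._trial(valence, arousal)) is expected

    def test_monotone_in_valence_threshold(self):
        """Lowering valence_max never adds trials."""
        rng = np.random.default_rng(0)
        trials = [
            self._trial(v, a)
            for v, a in zip(rng.uniform(1, 9, 50), rng.uniform(1, 9, 50))
        ]
        passed = None
        for vmax in (4.0, 3.0, 2.5, 2.0, 1.5):
            current = {i for i, t in enumerate(trials) if screen_trial(t, vmax)}
            if passed is not None:
                assert current <= passed
            passed = current


class TestCropAndSegment:
    def test_deap_trial_crop_skips_baseline(self):
        # 63 s trial: 3 s baseline + 60 s stimulus; window [15, 60) s
        sig = np.tile(np.arange(63 * 128, dtype=float), (2, 1))
        trial = RatedTrial(signal=sig, valence=2.0, arousal=2.0, fs=128)
        out = crop_steady_state(trial)
        assert out.shape == (2, 5760)
        assert out[0, 0] == (3 + 15) * 128

    def test_bare_60s_trial(self):
        trial = RatedTrial(
            signal=np.zeros((1, 60 * 128)), valence=2.0, arousal=2.0, fs=128
        )
        assert crop_steady_state(trial).shape == (1, 5760)

    def test_short_trial_rejected(self):
        trial = RatedTrial(
            signal=np.zeros((1, 30 * 128)), valence=2.0, arousal=2.0, fs=128
        )
        with pytest.raises(ValueError):
            crop_steady_state(trial)

    def test_empty_window_rejected(self):
        trial = RatedTrial(
            signal=np.zeros((1, 63 * 128)), valence=2.0, arousal=2.0, fs=128
        )
        with pytest.raises(ValueError):
            crop_steady_state(trial, start_s=15, end_s=15)

    @pytest.mark.parametrize(
        "n_samples,n_epochs", [(5760, 6), (960, 1), (959, 0), (1919, 1)]
    )
    def test_segment_counts(self, n_samples, n_epochs):
        epochs = segment(np.zeros((8, n_samples)), channel_names=CANONICAL_CHANNELS)
        assert len(epochs) == n_epochs
        for e in epochs:
            assert e.n_samples == 960


class TestSelectChannels:
    def test_reorders_32_channel_montage(self):
        from eegaffect.montage import DEAP_CHANNELS

        rng = np.random.default_rng(1)
        data = rng.normal(size=(32, 960))
        out = select_channels((data, DEAP_CHANNELS))
        assert out.channel_names == CANONICAL_CHANNELS
        for i, name in enumerate(CANONICAL_CHANNELS):
            src = DEAP_CHANNELS.index(name)
            assert np.array_equal(out.data[i], data[src])

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(8, 960))
        shuffled_names = tuple(reversed(CANONICAL_CHANNELS))
        a = select_channels((data, CANONICAL_CHANNELS))
        b = select_channels((data[::-1].copy(), shuffled_names))
        assert np.array_equal(a.data, b.data)

    def test_identity_on_canonical(self):
        epoch = generate_epoch(DEPRESSION_PRESET, seed=1)
        out = select_channels(epoch)
        assert np.array_equal(out.data, epoch.data)

    def test_missing_channel_error(self):
        data = np.zeros((7, 960))
        names = CANONICAL_CHANNELS[:7]
        with pytest.raises(ChannelError, match="C4"):
            select_channels((data, names))


class TestBalanceCohort:
    @staticmethod
    def _cohort(n1, n0):
        def mk(label, i):
            return CohortSample(
                epoch=Epoch(data=np.full((8, 960), float(i))), label=label,
                source="t",
            )

        return [mk(1, i) for i in range(n1)] + [mk(0, 100 + i) for i in range(n0)]

    def test_downsamples_majority(self):
        out = balance_cohort(self._cohort(70, 51), seed=0)
        labels = [s.label for s in out]
        assert labels.count(1) == 51 and labels.count(0) == 51

    def test_already_balanced_unchanged(self):
        cohort = self._cohort(5, 5)
        out = balance_cohort(cohort, seed=0)
        assert [id(s) for s in out] == [id(s) for s in cohort]

    def test_deterministic(self):
        cohort = self._cohort(30, 10)
        a = balance_cohort(cohort, seed=7)
        b = balance_cohort(cohort, seed=7)
        assert [id(s) for s in a] == [id(s) for s in b]

    def test_single_class_rejected(self):
        with pytest.raises(CohortError):
            balance_cohort(self._cohort(5, 0), seed=0)


class TestPipelineComposition:
    def test_filtering_commutes_with_channel_selection(self):
        """Band-pass + resample then channel-select equals channel-select
        then band-pass + resample (row-wise operations)."""
        from eegaffect.montage import DEAP_CHANNELS

        rng = np.random.default_rng(8)
        data = rng.normal(size=(32, 4 * 512))
        a = select_channels((resample(bandpass(data, fs=512), 512, 128),
                             DEAP_CHANNELS))
        picked = select_channels((data, DEAP_CHANNELS))
        b = resample(bandpass(picked.data, fs=512), 512, 128)
        assert np.allclose(a.data, b, atol=1e-10)

    def test_rated_trials_to_standard_epochs(self):
        """Screen -> crop -> select -> segment yields only standardized
        epochs: 6 per passing 63 s trial."""
        from eegaffect.synth import generate_rated_trials

        trials = generate_rated_trials(
            4, valence_dist=1.5, arousal_dist=2.0, seed=5
        )
        samples, counts = epochs_from_rated_trials(trials, label=0, source="test")
        assert counts["trials_passing"] == 4
        # 63 s trial, window [15,60) = 45 s -> 6 epochs of 7.5 s
        assert counts["epochs"] == 24
        assert all(s.epoch.is_standard() for s in samples)
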