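"""Epoch periodograms, sleep/wake normalizations, QW/AW segmentation,
gamma ratios and the delta time course."""

import numpy as np
import pytest

import infrasleep as isl
from infrasleep.core import Hypnogram, Recording
from infrasleep.spectral import EpochSpectra


def make_rec(x, fs=200.0, name="EEG"):
    return Recording(np.atleast_2d(x), fs, [name], {name: "eeg"})


def hyp_for(n_samples, fs, label="N"):
    n_ep = int(n_samples / fs / 4)
    return Hypnogram(np.full(n_ep, label))


class TestEpochSpectra:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs = 200.0
        t = np.arange(int(40 * fs)) / fs
        rec = make_rec(np.sin(2 * np.pi * 10.0 * t), fs)
        es = isl.epoch_spectra(rec, hyp_for(len(t), fs), "EEG")
        assert es.psd.shape[1] == 10
        peak_bin = es.freqs[np.argmax(es.psd[:, 3])]
        assert peak_bin == pytest.approx(10.0, abs=0.25)

    def test_constant_signal_zero_psd(self):
        fs = 200.0
        rec = make_rec(np.full(int(16 * fs), 42.0), fs)
        es = isl.epoch_spectra(rec, hyp_for(16 * 200, fs), "EEG")
        assert np.allclose(es.psd, 0.0)

    def test_white_noise_flat_mean_psd(self):
        fs = 200.0
        rng = np.random.default_rng(0)
        rec = make_rec(rng.standard_normal(int(4000 * fs)), fs)
        es = isl.epoch_spectra(rec, hyp_for(4000 * 200, fs), "EEG")
        mean = es.psd[1:-1].mean(axis=1)
        assert mean.std() / mean.mean() < 0.05

    def test_transition_adjacency_flags(self):
        fs = 200.0
        labels = Hypnogram(np.array(list("NNNWWNNN")))
        rec = make_rec(np.random.default_rng(1).standard_normal(int(32 * fs)), fs)
        es = isl.epoch_spectra(rec, labels, "EEG")
        assert list(es.transition_adjacent) == [
            False, False, True, True, True, True, False, False,
        ]

    def test_missing_channel_rejected(self, short_sim):
        with pytest.raises(KeyError):
            isl.epoch_spectra(short_sim.recording, short_sim.hypnogram, "PrL")


class TestSleepSpectrum:
    def test_scale_invariance(self, short_sim):
        rec, hyp = short_sim.recording, short_sim.hypnogram
        es1 = isl.epoch_spectra(rec, hyp, "EEG")
        doubled = Recording(rec.data * 2.0, rec.fs, rec.channels, rec.roles)
        es2 = isl.epoch_spectra(doubled, hyp, "EEG")
        s1 = isl.sleep_state_spectrum(es1)
        s2 = isl.sleep_state_spectrum(es2)
        for st in s1:
            assert np.allclose(s1[st], s2[st], rtol=1e-9)

    def test_identical_states_normalize_to_unit_level(self):
        fs = 200.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(240 * fs))
        labels = np.array(list("NNNNNNNNNN" + "WWWWWWWWWW" + "RRRRRRRRRR") * 2)
        es = isl.epoch_spectra(make_rec(x, fs), Hypnogram(labels), "EEG")
        # replace spectra by one shared spectrum across all epochs
        es = EpochSpectra(
            es.freqs, np.tile(es.psd[:, :1], es.n_epochs), es.states, es.transition_adjacent
        )
        spectra = isl.sleep_state_spectrum(es)
        sel = (es.freqs >= 0.75) & (es.freqs <= 47.0)
        for st in spectra:
            assert spectra[st][sel].mean() == pytest.approx(1.0)
        assert np.allclose(spectra["N"], spectra["R"])

    def test_state_band_peaks_on_synthetic_data(self, default_sim):
        es = isl.epoch_spectra(default_sim.recording, default_sim.hypnogram, "EEG")
        spectra = isl.sleep_state_spectrum(es)
        f = es.freqs
        band_of = lambda s: f[np.argmax(np.where((f >= 1) & (f <= 20), spectra[s], 0))]
        assert 1.0 <= band_of("N") <= 4.0  # delta-dominated NREMS
        assert 5.0 <= band_of("R") <= 10.0  # theta-dominated REMS


class TestWakeSpectrum:
    def test_normalized_sum_is_one(self, short_sim):
        rec, hyp = short_sim.recording, short_sim.hypnogram
        es = isl.epoch_spectra(rec, hyp, "EEG")
        qw, aw = isl.segment_quiet_active_wake(rec.channel("EMG"), rec.fs, hyp)
        ws = isl.wake_spectrum(es, qw, aw)
        sel = (es.freqs >= 2.0) & (es.freqs <= 30.0)
        for key in ("QW", "AW"):
            assert ws[key]["spectrum"][sel].sum() == pytest.approx(1.0)

    def test_empty_set_rejected(self, short_sim):
        es = isl.epoch_spectra(short_sim.recording, short_sim.hypnogram, "EEG")
        with pytest.raises(ValueError, match="empty"):
            isl.wake_spectrum(es, set(), {1, 2})


class TestQuietActiveSegmentation:
    def test_percentile_bands_on_monotone_ramp(self):
        """With EMG power increasing monotonically over wake epochs, QW must
        be exactly the 10-25 percentile ranks (sort-based oracle)."""
        fs = 100.0
        n_ep = 100
        per = int(4 * fs)
        # epoch k has amplitude k+1; consecutive so the run rule passes
        emg = np.concatenate(
            [(k + 1) * np.ones(per) * np.sign(np.random.default_rng(k).standard_normal(per))
             for k in range(n_ep)]
        )
        hyp = Hypnogram(np.full(n_ep, "W"))
        qw, aw = isl.segment_quiet_active_wake(emg, fs, hyp)
        ln = np.log(np.square(emg).reshape(n_ep, per).mean(axis=1))
        q10, q25, q50, q99 = np.quantile(ln, [0.10, 0.25, 0.50, 0.99])
        expect_qw = {k for k in range(n_ep) if q10 <= ln[k] <= q25}
        expect_aw = {k for k in range(n_ep) if q50 <= ln[k] <= q99}
        assert qw == expect_qw
        assert aw == expect_aw

    def test_short_runs_excluded_from_qw(self):
        fs = 100.0
        per = int(4 * fs)
        # low-EMG epochs at isolated positions (runs of 2) never qualify
        amps = np.array([1, 1, 10, 10, 1, 1, 10, 10, 1, 1] + [10] * 30, dtype=float)
        rng = np.random.default_rng(0)
        emg = np.concatenate([a * rng.standard_normal(per) for a in amps])
        hyp = Hypnogram(np.full(len(amps), "W"))
        qw, _ = isl.segment_quiet_active_wake(emg, fs, hyp)
        assert qw == set()

    def test_qw_aw_disjoint(self, short_sim):
        rec, hyp = short_sim.recording, short_sim.hypnogram
        qw, aw = isl.segment_quiet_active_wake(rec.channel("EMG"), rec.fs, hyp)
        assert qw.isdisjoint(aw)

    def test_too_few_wake_epochs_rejected(self):
        hyp = Hypnogram(np.array(list("WWWWNNNN")))
        with pytest.raises(ValueError, match="wake epochs"):
            isl.segment_quiet_active_wake(np.ones(8 * 400), 100.0, hyp)


class TestGammaRatio:
    def test_identical_recordings_ratio_one(self, short_sim):
        es = isl.epoch_spectra(short_sim.recording, short_sim.hypnogram, "EEG")
        ratios = isl.gamma_ratio(es, es)
        for v in ratios.values():
            assert v == pytest.approx(1.0)

    def test_doubled_band_content_detected(self, short_sim):
        rec, hyp = short_sim.recording, short_sim.hypnogram
        es_base = isl.epoch_spectra(rec, hyp, "EEG")
        # inject extra 60-80 Hz content only (fs 500 resolves it)
        rng = np.random.default_rng(5)
        t = np.arange(rec.n_samples) / rec.fs
        extra = np.sin(2 * np.pi * 70.0 * t + rng.uniform(0, 2 * np.pi))
        boosted = Recording(
            rec.data + 5.0 * extra, rec.fs, rec.channels, rec.roles
        )
        es_fol = isl.epoch_spectra(boosted, hyp, "EEG")
        ratios = isl.gamma_ratio(es_base, es_fol)
        assert all(v > 1.5 for v in ratios.values())


class TestDeltaTimecourse:
    @staticmethod
    def synthetic_es(values, zt0_s=0.0):
        """EpochSpectra whose 1-4 Hz power per NREMS epoch equals ``values``."""
        n = len(values)
        freqs = np.arange(0, 50.25, 0.25)
        psd = np.zeros((len(freqs), n))
        sel = (freqs >= 1) & (freqs <= 4)
        psd[sel] = np.asarray(values)
        states = np.full(n, "N")
        return EpochSpectra(freqs, psd, states, np.zeros(n, bool), 4.0, zt0_s)

    def test_stationary_delta_flat_at_one(self):
        n = 12 * 3600 // 4  # one full light phase
        es = self.synthetic_es(np.full(n, 7.0))
        tc = isl.delta_timecourse(es, Hypnogram(np.full(n, "N")))
        assert len(tc["delta"]) == 12
        assert np.allclose(tc["delta"], 1.0)

    def test_light_periods_have_equal_epoch_counts(self):
        n = 12 * 3600 // 4
        es = self.synthetic_es(np.linspace(2, 1, n))
        tc = isl.delta_timecourse(es, Hypnogram(np.full(n, "N")), normalize=False)
        # 12 light periods; equal split of NREMS content (+-1 epoch)
        assert len(tc["delta"]) == 12

    def test_decaying_delta_monotone_trajectory(self):
        n = 12 * 3600 // 4
        es = self.synthetic_es(np.linspace(3.0, 1.0, n))
        tc = isl.delta_timecourse(es, Hypnogram(np.full(n, "N")))
        assert np.all(np.diff(tc["delta"]) < 0)

    def test_missing_reference_window_flagged(self):
        n = 100  # recording ends long before ZT9
        es = self.synthetic_es(np.ones(n))
        with pytest.raises(ValueError, match="ZT9-12"):
            isl.delta_timecourse(es, Hypnogram(np.full(n, "N")))
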