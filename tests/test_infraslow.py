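"""The 0.02 Hz machinery: sigma trace, Hilbert phase convention, cycle
detection against an analytic oracle, event-phase sampling, outcomes."""

import numpy as np
import pandas as pd
import pytest

import infrasleep as isl
from infrasleep.core import Hypnogram
from infrasleep.infraslow import SigmaTrace, compute_phase, smooth_infraslow


def cosine_trace(duration_s=1080.0, period_s=50.0, fs=10.0, depth=0.8, t0=25.0):
    """Noise-free sinusoidal sigma-power trace with peaks at t0 + k*period."""
    t = np.arange(int(duration_s * fs)) / fs
    power = 1.0 + depth * np.cos(2 * np.pi * (t - t0) / period_s)
    smoothed = smooth_infraslow(power, fs)
    mask = np.ones(len(t), bool)
    phase = compute_phase(smoothed, mask)
    return SigmaTrace(fs, power, smoothed, phase, mask)


def all_nrems_hyp(duration_s):
    return Hypnogram(np.full(int(duration_s / 4), "N"))


class TestPhaseConvention:
    def test_peak_zero_trough_180(self):
        st = cosine_trace(t0=0.0)
        t = st.t
        peaks = np.flatnonzero(np.isclose(t % 50.0, 0.0))[3:-3]
        troughs = np.flatnonzero(np.isclose(t % 50.0, 25.0))[3:-3]
        peak_dev = np.minimum(st.phase_deg[peaks], 360.0 - st.phase_deg[peaks])
        assert np.all(peak_dev <= 1.0)
        assert np.allclose(st.phase_deg[troughs], 180.0, atol=1.0)

    def test_quadrature_quarter_period(self):
        st = cosine_trace(t0=0.0)
        quarter = np.flatnonzero(np.isclose(st.t % 50.0, 12.5))[2:-2]
        assert np.allclose(st.phase_deg[quarter], 90.0, atol=1.0)

    def test_monotone_increase_modulo_360(self):
        st = cosine_trace(t0=0.0)
        ph = np.unwrap(np.deg2rad(st.phase_deg[1000:-1000]))
        assert np.all(np.diff(ph) > 0)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_phase(np.ones(1000))


class TestSigmaTrace:
    def test_mask_mean_is_one(self, default_sim, default_sigma):
        st, _ = default_sigma
        assert st.power[st.mask].mean() == pytest.approx(1.0)

    def test_gain_invariance(self, short_sim):
        rec, hyp = short_sim.recording, short_sim.hypnogram
        st1 = isl.compute_sigma_trace(rec, hyp)
        rec3 = isl.Recording(rec.data * 3.0, rec.fs, rec.channels, rec.roles)
        st3 = isl.compute_sigma_trace(rec3, hyp)
        assert np.allclose(st1.power, st3.power, rtol=1e-9)
        assert np.allclose(st1.phase_deg, st3.phase_deg, atol=1e-6)

    def test_am_carrier_envelope_recovered(self):
        """A 12 Hz carrier with a 50-s power envelope must yield a smoothed
        trace oscillating at 0.02 Hz, cross-checked against the envelope
        extracted independently by rectified band-pass filtering."""
        from scipy import signal as sps

        fs = 500.0
        t = np.arange(int(600 * fs)) / fs
        env = np.sqrt(1.0 + 0.8 * np.cos(2 * np.pi * t / 50.0))
        x = env * np.cos(2 * np.pi * 12.0 * t)
        rec = isl.Recording(x[None, :], fs, ["EEG"], {"EEG": "eeg"})
        st = isl.compute_sigma_trace(rec, all_nrems_hyp(600.0))
        # oracle: rectified band-passed signal, squared, low-passed
        sos = sps.butter(4, [10, 15], btype="bandpass", fs=fs, output="sos")
        oracle = sps.sosfiltfilt(sos, x) ** 2
        oracle = sps.sosfiltfilt(sps.butter(2, 0.1, fs=fs, output="sos"), oracle)
        oracle10 = oracle[:: int(fs / 10)][: len(st.power)]
        oracle10 = oracle10 / oracle10.mean()
        keep = slice(500, len(st.power) - 500)
        corr = np.corrcoef(st.smoothed[keep], oracle10[keep])[0, 1]
        assert corr > 0.99

    def test_no_nrems_rejected(self, short_sim):
        hyp = Hypnogram(np.full(short_sim.hypnogram.n_epochs, "W"))
        with pytest.raises(ValueError, match="NREMS"):
            isl.compute_sigma_trace(short_sim.recording, hyp)


class TestInfraslowSpectrum:
    def test_unmodulated_sigma_loses_the_peak(self):
        """Without envelope modulation the 0.02 Hz bin holds only the
        estimator-noise floor: orders of magnitude below the modulated
        case at matched conditions."""
        spec = {}
        for depth in (0.0, 0.85):
            res = isl.simulate_recording(
                seed=31, duration_s=1200.0, fs_signal=500.0,
                modulation_depth=depth, only_state="N", p_ma_per_fragility=0.0,
            )
            st = isl.compute_sigma_trace(res.recording, res.hypnogram)
            spec[depth] = isl.infraslow_spectrum(st, res.hypnogram)
        at_002 = lambda s: s["spectrum"][np.argmin(np.abs(s["freqs"] - 0.02))]
        assert at_002(spec[0.85]) > 20.0 * at_002(spec[0.0])
        assert spec[0.85]["peak_freq_hz"] == pytest.approx(0.02, abs=0.0025)

    def test_identical_traces_identical_spectra(self, default_sim, default_sigma):
        st, _ = default_sigma
        a = isl.infraslow_spectrum(st, default_sim.hypnogram)
        b = isl.infraslow_spectrum(st, default_sim.hypnogram)
        assert np.array_equal(a["spectrum"], b["spectrum"])

    def test_grid_is_201_points(self, default_sim, default_sigma):
        st, _ = default_sigma
        spec = isl.infraslow_spectrum(st, default_sim.hypnogram)
        assert len(spec["freqs"]) == 201
        assert spec["freqs"][0] == 0.0 and spec["freqs"][-1] == 0.5

    def test_no_qualifying_bout_rejected(self, default_sigma, default_sim):
        st, _ = default_sigma
        with pytest.raises(ValueError, match="bout"):
            isl.infraslow_spectrum(st, default_sim.hypnogram, min_bout_s=1e9)


class TestCycleDetection:
    def test_twenty_cycle_oracle(self):
        """A constructed envelope with 20 analytic cycles must give exactly
        20 detected cycles with extrema within one sample of the truth."""
        st = cosine_trace(duration_s=1032.0, t0=25.0)  # peaks 25..1025
        hyp = all_nrems_hyp(1032.0)
        cs = isl.detect_cycles(st, hyp)
        assert len(cs) == 20
        true_peaks = 25.0 + 50.0 * np.arange(21)
        true_troughs = 50.0 * np.arange(1, 21)
        for row, tp, tt in zip(cs.cycles.itertuples(), true_peaks, true_troughs):
            assert abs(row.peak1 / 10.0 - tp) <= 0.1
            assert abs(row.trough / 10.0 - tt) <= 0.1
        assert abs(cs.cycles["peak2"].iloc[-1] / 10.0 - true_peaks[20]) <= 0.1

    def test_close_extrema_rejected(self):
        """Oscillation with a 30-s period violates the >20 s same-type
        separation; at most sparse cycles survive, none 30 s long."""
        st = cosine_trace(duration_s=600.0, period_s=30.0, t0=0.0)
        cs = isl.detect_cycles(st, all_nrems_hyp(600.0))
        if len(cs):
            spans = (cs.cycles["peak2"] - cs.cycles["peak1"]) / 10.0
            assert (spans > 20.0).all()

    def test_submean_peak_rejected(self):
        """A bump that stays below the trace mean is not a cycle peak."""
        fs = 10.0
        t = np.arange(int(400 * fs)) / fs
        base = 1.0 + 0.8 * np.cos(2 * np.pi * t / 50.0)
        base[t > 200] = 0.4 + 0.05 * np.cos(2 * np.pi * t[t > 200] / 50.0)
        sm = smooth_infraslow(base)
        st = SigmaTrace(fs, base, sm, compute_phase(sm), np.ones(len(t), bool))
        cs = isl.detect_cycles(st, all_nrems_hyp(400.0))
        assert (cs.cycles["peak1"] / 10.0 < 200).all()
        assert (cs.cycles["peak2"] / 10.0 < 210).all()

    def test_trough_between_peaks_and_amplitudes(self, default_sigma):
        st, cs = default_sigma
        m = st.smoothed[st.mask].mean()
        for row in cs.cycles.itertuples():
            assert row.peak1 < row.trough < row.peak2
            assert st.smoothed[row.trough] < m
            assert st.smoothed[row.peak1] > m and st.smoothed[row.peak2] > m

    def test_phase_extrema_consistency_noise_free(self):
        """On a noise-free envelope, where only FIR edge effects act,
        every detected trough carries phase 180 +- 10 and every peak
        0 +- 10 degrees."""
        st = cosine_trace(duration_s=1032.0, t0=25.0)
        cs = isl.detect_cycles(st, all_nrems_hyp(1032.0))
        tr_ph = st.phase_deg[cs.cycles["trough"].to_numpy()]
        pk_ph = st.phase_deg[cs.cycles["peak1"].to_numpy()]
        assert np.all(np.abs(tr_ph - 180.0) <= 10.0)
        assert np.all(np.minimum(pk_ph, 360.0 - pk_ph) <= 10.0)

    def test_phase_extrema_consistency_noisy(self, default_sigma):
        """On noisy bouted data, estimator noise and Hilbert bout-edge
        distortion widen the spread: extrema phases stay centered on the
        convention (median within 10 degrees) with a bounded tail."""
        st, cs = default_sigma
        tr_ph = st.phase_deg[cs.cycles["trough"].to_numpy()]
        pk_ph = st.phase_deg[cs.cycles["peak1"].to_numpy()]
        tr_dev = np.abs(tr_ph - 180.0)
        pk_dev = np.minimum(pk_ph, 360.0 - pk_ph)
        assert np.median(tr_dev) <= 10.0
        assert np.median(pk_dev) <= 10.0
        # bout-edge extrema carry the Hilbert edge distortion tail
        assert np.quantile(tr_dev, 0.9) <= 30.0
        assert np.quantile(pk_dev, 0.9) <= 30.0


class TestEventPhase:
    def test_event_at_trough_reads_180(self):
        st = cosine_trace(t0=0.0)
        ev = isl.make_event_table([25.0 + 50 * 5], [8.0], ["MA"])
        ph = isl.phase_at_events(st, ev, offsets_s=(0.0,))
        assert ph["phase_minus_0s"].iloc[0] == pytest.approx(180.0, abs=1.0)

    def test_offsets_shift_by_28_8_degrees(self):
        """4 s at 0.02 Hz is 28.8 deg; offsets 4/8/12 s before the event."""
        st = cosine_trace(t0=0.0)
        ev = isl.make_event_table([275.0], [8.0], ["MA"])
        ph = isl.phase_at_events(st, ev)
        base = ph["phase_minus_0s"].iloc[0]
        for o, expect in ((4.0, 28.8), (8.0, 57.6), (12.0, 86.4)):
            got = ph[f"phase_minus_{o:g}s"].iloc[0]
            assert ((base - got) % 360) == pytest.approx(expect, abs=1.0)

    def test_event_outside_recording_rejected(self):
        st = cosine_trace()
        ev = isl.make_event_table([1e6], [4.0], ["MA"])
        with pytest.raises(IndexError):
            isl.phase_at_events(st, ev)


class TestOutcomes:
    def test_no_events_no_rems_all_continuing(self):
        st = cosine_trace(duration_s=1080.0, t0=25.0)
        hyp = all_nrems_hyp(1080.0)
        cs = isl.detect_cycles(st, hyp)
        out = isl.classify_fragility_outcomes(cs, st, hyp, isl.make_event_table())
        assert out["proportions"]["NREMS-continuing"] == pytest.approx(1.0)
        assert out["proportions"]["MA"] == 0.0

    def test_proportions_sum_to_one(self, default_sim, default_sigma):
        st, cs = default_sigma
        out = isl.classify_fragility_outcomes(
            cs, st, default_sim.hypnogram, default_sim.events
        )
        assert sum(out["proportions"].values()) == pytest.approx(1.0)

    def test_in_band_ma_marks_cycle(self):
        st = cosine_trace(duration_s=1080.0, t0=25.0)
        hyp = all_nrems_hyp(1080.0)
        cs = isl.detect_cycles(st, hyp)
        # one MA at the trough of the 6th detected cycle (phase 180)
        t_ma = cs.cycles["trough"].iloc[5] / 10.0
        ev = isl.make_event_table([t_ma], [8.0], ["MA"])
        out = isl.classify_fragility_outcomes(cs, st, hyp, ev)
        assert out["cycles"]["outcome"].iloc[5] == "MA"
        assert (out["cycles"]["outcome"] == "MA").sum() == 1
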