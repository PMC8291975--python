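"""Shared fixtures: synthetic sessions are generated once per test run."""

from __future__ import annotations

import numpy as np
import pytest

import infrasleep as isl


@pytest.fixture(scope="session")
def default_sim():
    """One default Sham animal (1 h at 1 kHz)."""
    return isl.simulate_recording(seed=101)


@pytest.fixture(scope="session")
def default_sigma(default_sim):
    st = isl.compute_sigma_trace(default_sim.recording, default_sim.hypnogram)
    cs = isl.detect_cycles(st, default_sim.hypnogram)
    return st, cs


@pytest.fixture(scope="session")
def short_sim():
    """A small, cheap session for scoring/spectral unit tests (20 min, 500 Hz)."""
    return isl.simulate_recording(seed=202, duration_s=1200.0, fs_signal=500.0)


@pytest.fixture(scope="session")
def cohort_stats():
    """Thirty default animals through the full phase pipeline.

    Returns per-animal MA onset phases (measured and generator truth) and
    the per-animal fragility-outcome proportions.
    """
    phases, true_phases, ma_props = [], [], []
    for seed in range(1, 31):
        res = isl.simulate_recording(seed=seed)
        st = isl.compute_sigma_trace(res.recording, res.hypnogram)
        cs = isl.detect_cycles(st, res.hypnogram)
        ph = isl.phase_at_events(st, res.events)["phase_minus_0s"].to_numpy()
        phases.append(ph)
        true_phases.append(res.ground_truth.ma_events["phase_deg"].to_numpy())
        out = isl.classify_fragility_outcomes(cs, st, res.hypnogram, res.events)
        ma_props.append(out["proportions"]["MA"])
    return {
        "phases": phases,
        "true_phases": true_phases,
        "ma_props": np.asarray(ma_props),
    }


@pytest.fixture(scope="session")
def trained_classifier():
    """Online thresholds + period classifier trained on one synthetic animal."""
    res = isl.simulate_recording(seed=21)
    st = isl.compute_sigma_trace(res.recording, res.hypnogram)
    cs = isl.detect_cycles(st, res.hypnogram)
    thr = isl.calibrate_thresholds(res.recording, res.hypnogram)
    onl = isl.run_online(res.recording, thr)
    X, y = isl.make_training_set(onl, cs)
    fit = isl.train_period_classifier(X, y, seed=0)
    return {"fit": fit, "thresholds": thr, "train": (res, st, cs, onl, X, y)}


@pytest.fixture(scope="session")
def sni_pair():
    """Matched Sham/SNI animals (same seed) with S1HL analyses."""
    out = {}
    for cond in ("sham", "sni"):
        r = isl.simulate_recording(seed=77, condition=cond)
        st = isl.compute_sigma_trace(r.recording, r.hypnogram, "S1HL")
        cs = isl.detect_cycles(st, r.hypnogram)
        bt = isl.band_power_traces(r.recording, r.hypnogram, "S1HL")
        cls = isl.classify_fragility_outcomes(cs, st, r.hypnogram, r.events)
        out[cond] = {"res": r, "st": st, "cs": cs, "bands": bt, "cls": cls}
    return out
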