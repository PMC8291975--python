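"""Phase-binned band dynamics, the activation index, local (AI-peak)
arousal detection, and EMG-derived heart rate.

The activation index AI = ln((P_beta + P_low_gamma) / P_delta) measures how
close NREMS momentarily moves toward wakefulness.  A fragility period that
continues into NREMS but contains an intermittent AI peak above the cycle's
mean AI — with no EMG burst — is a *local cortical arousal*; these carry
heart-rate transients and become more frequent under chronic pain (SNI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Hypnogram, Recording, NREMS_LIKE
from .infraslow import FRAGILITY_BAND, CycleSet, SigmaTrace, morlet_band_power

N_PHASE_BINS = 18  # 20-degree bins

_BAND_STEPS = {"delta": 0.5, "sigma": 0.5, "beta": 1.0, "low_gamma": 1.0, "high_gamma": 2.0}
_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "sigma": (10.0, 15.0),
    "beta": (16.0, 25.0),
    "low_gamma": (26.0, 40.0),
    "high_gamma": (60.0, 80.0),
}


def band_power_traces(
    rec: Recording,
    hyp: Hypnogram,
    channel: str,
    bands=("delta", "sigma", "beta", "low_gamma"),
    out_fs: float = 10.0,
) -> dict[str, np.ndarray]:
    """Morlet band-power traces at 10 Hz, jointly normalized in NREMS.

    All traces are divided by one constant — the sum of the band means over
    NREMS(+MA) samples — which preserves cross-band ratios, so the AI is
    unaffected by the normalization.
    """
    raw = {}
    for b in bands:
        lo, hi = _BAND_EDGES[b]
        raw[b] = morlet_band_power(
            rec.channel(channel), rec.fs, lo, hi, step=_BAND_STEPS[b], out_fs=out_fs
        )
    n = min(len(v) for v in raw.values())
    lab = hyp.sample_labels(out_fs, n)
    mask = np.isin(lab, NREMS_LIKE)
    if not mask.any():
        raise ValueError("no NREMS samples to normalize band traces")
    const = sum(raw[b][:n][mask].mean() for b in bands)
    return {b: raw[b][:n] / const for b in bands}


def _phase_bin_means(values, phase, idx):
    """Mean of ``values[idx]`` per 20-degree phase bin (NaN where empty)."""
    bins = np.floor(phase[idx] / (360.0 / N_PHASE_BINS)).astype(int) % N_PHASE_BINS
    out = np.full(N_PHASE_BINS, np.nan)
    for b in range(N_PHASE_BINS):
        sel = bins == b
        if sel.any():
            out[b] = values[idx[sel]].mean()
    return out


def phase_binned_power(
    band_traces: dict[str, np.ndarray],
    st: SigmaTrace,
    cs: CycleSet,
    outcomes: pd.Series | None = None,
) -> dict:
    """Per-band 18-bin phase profiles, split by cycle class.

    Averages band power per 20-degree phase bin across cycles, separately
    for MA-containing and NREMS-continuing cycles (all cycles when
    ``outcomes`` is None), plus continuity (270-90 deg) / fragility
    (90-270 deg) span means.
    """
    classes = {"all": np.ones(len(cs), dtype=bool)}
    if outcomes is not None:
        classes["MA"] = (outcomes == "MA").to_numpy()
        classes["NREMS-continuing"] = (outcomes == "NREMS-continuing").to_numpy()

    result = {}
    for band, trace in band_traces.items():
        if len(trace) < len(st.phase_deg):
            raise ValueError(f"band trace {band!r} shorter than the sigma trace")
        per_class = {}
        for cname, pick in classes.items():
            profiles, frag_means, cont_means = [], [], []
            for row in cs.cycles[pick].itertuples():
                idx = cs.span_indices(row)
                profiles.append(_phase_bin_means(trace, st.phase_deg, idx))
                fi = cs.fragility_indices(row, st.phase_deg)
                ci = cs.continuity_indices(row, st.phase_deg)
                if fi.size:
                    frag_means.append(trace[fi].mean())
                if ci.size:
                    cont_means.append(trace[ci].mean())
            if profiles:
                per_class[cname] = {
                    "profile": np.nanmean(profiles, axis=0),
                    "fragility_mean": float(np.mean(frag_means)) if frag_means else np.nan,
                    "continuity_mean": float(np.mean(cont_means)) if cont_means else np.nan,
                    "n_cycles": len(profiles),
                }
        result[band] = per_class
    result["bin_centers_deg"] = (np.arange(N_PHASE_BINS) + 0.5) * (360.0 / N_PHASE_BINS)
    return result


@dataclass
class AITrace:
    """Activation index ln((beta + low_gamma) / delta) at 10 Hz."""

    fs: float
    ai: np.ndarray
    valid: np.ndarray  # False where any band power was non-positive


def activation_index(band_traces: dict[str, np.ndarray], smooth_s: float = 2.0) -> AITrace:
    """Pointwise AI; samples with non-positive band power are masked.

    A short moving average (``smooth_s``) stabilizes the ratio: wavelet
    band power at 10 Hz is noisy and the AI's intermittent peaks of
    interest last seconds, not single samples.
    """
    delta = band_traces["delta"]
    num = band_traces["beta"] + band_traces["low_gamma"]
    n = min(len(delta), len(num))
    delta, num = delta[:n], num[:n]
    valid = (delta > 0) & (num > 0)
    ai = np.full(n, np.nan)
    ai[valid] = np.log(num[valid] / delta[valid])
    win = max(1, int(smooth_s * 10.0))
    if win > 1 and valid.any():
        filled = np.where(valid, ai, np.nanmean(ai[valid]))
        ai = np.convolve(filled, np.ones(win) / win, mode="same")
        ai[~valid] = np.nan
    return AITrace(10.0, ai, valid)


def detect_ai_peaks(
    ai: AITrace, cs: CycleSet, st: SigmaTrace, min_prominence: float = 1.5
) -> pd.DataFrame:
    """Flag cycles whose fragility span contains an intermittent AI peak.

    Within each cycle's 90-270 deg span, local maxima of the AI exceeding
    that cycle's mean AI (the per-cycle threshold) mark a peak; a peak
    counts when its maximum lies inside the span.  Because the AI passes
    smoothly through the cycle mean near the span edges, a candidate must
    additionally stand out by ``min_prominence`` ln-units — intermittent
    arousals jump by several units, the smooth passage does not.  Returns
    the cycle table with ``ai_peak`` flags and ``ai_peak_time_s`` (time of
    the largest peak, NaN when none).
    """
    flags, times = [], []
    for row in cs.cycles.itertuples():
        span = cs.span_indices(row)
        span = span[span < len(ai.ai)]
        vspan = span[ai.valid[span]]
        if vspan.size == 0:
            flags.append(False)
            times.append(np.nan)
            continue
        thr = ai.ai[vspan].mean()
        frag = cs.fragility_indices(row, st.phase_deg)
        frag = frag[frag < len(ai.ai)]
        frag = frag[ai.valid[frag]]
        if frag.size < 3:
            flags.append(False)
            times.append(np.nan)
            continue
        seg = ai.ai[frag]
        pk, props = signal.find_peaks(seg, height=thr, prominence=min_prominence)
        if pk.size == 0:
            flags.append(False)
            times.append(np.nan)
        else:
            best = pk[int(np.argmax(props["peak_heights"]))]
            flags.append(True)
            times.append(frag[best] / ai.fs)
    out = cs.cycles.copy()
    out["ai_peak"] = flags
    out["ai_peak_time_s"] = times
    return out


# ---------------------------------------------------------------------------
# heart rate


@dataclass
class HeartRateTrace:
    """R-peak times plus an instantaneous-rate trace (beats/min) at 10 Hz."""

    rpeak_times: np.ndarray
    fs: float
    rate_bpm: np.ndarray  # sample-and-hold instantaneous rate

    def rate_at(self, idx: np.ndarray) -> np.ndarray:
        return self.rate_bpm[np.clip(idx, 0, len(self.rate_bpm) - 1)]


def heart_rate_from_emg(
    emg: np.ndarray,
    fs: float,
    refractory_s: float = 0.05,
    k_mad: float = 8.0,
    smooth_s: float = 0.01,
    block_s: float = 1.0,
    out_fs: float = 10.0,
) -> HeartRateTrace:
    """Detect R peaks in the EMG and derive an instantaneous heart rate.

    The EMG is high-pass filtered above 25 Hz, squared and lightly smoothed;
    peaks must clear an adaptive threshold (per-block median + ``k_mad`` x
    MAD, so detection is invariant to a global gain) and respect the
    refractory floor on inter-beat intervals.  Warns and returns an empty
    trace when nothing is detectable.
    """
    if fs < 200.0:
        raise ValueError(f"R-peak detection needs fs >= 200 Hz, got {fs}")
    sos = signal.butter(4, 25.0, btype="highpass", fs=fs, output="sos")
    sq = signal.sosfiltfilt(sos, np.asarray(emg, dtype=float)) ** 2
    win = max(1, int(smooth_s * fs))
    sm = np.convolve(sq, np.ones(win) / win, mode="same")

    block = max(1, int(block_s * fs))
    n_blocks = int(np.ceil(len(sm) / block))
    thr = np.empty_like(sm)
    for b in range(n_blocks):
        seg = sm[b * block : (b + 1) * block]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        thr[b * block : (b + 1) * block] = med + k_mad * mad

    peaks, _ = signal.find_peaks(sm, distance=max(1, int(refractory_s * fs)))
    peaks = peaks[sm[peaks] > thr[peaks]]
    times = peaks / fs

    n_out = int(np.ceil(len(emg) / fs * out_fs))
    rate = np.full(n_out, np.nan)
    if times.size < 2:
        import warnings

        warnings.warn("no detectable R peaks in EMG", stacklevel=2)
        return HeartRateTrace(times, out_fs, rate)
    ibi = np.diff(times)
    inst = 60.0 / ibi
    idx = np.round(times[1:] * out_fs).astype(int)
    last = 0
    for i, r in zip(idx, inst):
        i = min(i, n_out - 1)
        rate[last : i + 1] = r
        last = i + 1
    rate[last:] = inst[-1]
    return HeartRateTrace(times, out_fs, rate)


def heart_rate_by_cycle(
    hr: HeartRateTrace, cs_flagged: pd.DataFrame, cs: CycleSet, st: SigmaTrace
) -> dict:
    """Phase-binned heart rate for NREMS-continuing cycles, split by AI-peak flag.

    Returns, per class ("peak"/"no_peak"), the 18-bin mean rate profile and
    the continuity/fragility span means; classes without cycles are omitted.
    ``cs_flagged`` must carry ``ai_peak`` and, when available, ``outcome``
    columns aligned with ``cs.cycles``.
    """
    if "outcome" in cs_flagged:
        continuing = cs_flagged["outcome"] == "NREMS-continuing"
    else:
        continuing = pd.Series(True, index=cs_flagged.index)
    out = {}
    for cname, pick in (
        ("peak", continuing & cs_flagged["ai_peak"]),
        ("no_peak", continuing & ~cs_flagged["ai_peak"]),
    ):
        rows = cs.cycles[pick.to_numpy()]
        if len(rows) == 0:
            continue
        profiles, frag, cont = [], [], []
        for row in rows.itertuples():
            idx = cs.span_indices(row)
            idx = idx[idx < len(hr.rate_bpm)]
            vals = hr.rate_at(idx)
            profiles.append(_phase_bin_means(hr.rate_bpm, st.phase_deg, idx))
            fi = cs.fragility_indices(row, st.phase_deg)
            ci = cs.continuity_indices(row, st.phase_deg)
            fi, ci = fi[fi < len(hr.rate_bpm)], ci[ci < len(hr.rate_bpm)]
            if fi.size:
                frag.append(np.nanmean(hr.rate_at(fi)))
            if ci.size:
                cont.append(np.nanmean(hr.rate_at(ci)))
        out[cname] = {
            "profile": np.nanmean(profiles, axis=0),
            "fragility_mean": float(np.nanmean(frag)) if frag else np.nan,
            "continuity_mean": float(np.nanmean(cont)) if cont else np.nan,
            "n_cycles": len(rows),
        }
    return out


def ai_peak_density(
    cs_flagged: pd.DataFrame, cs: CycleSet, hyp: Hypnogram, bin_h: float = 1.0
) -> dict:
    """Peak-flagged fragility periods per hour of NREMS across ZT bins,
    plus the two-level outcome breakdown {MA | continuing: {peak | no_peak}}."""
    zt = hyp.zt_hours()
    n_bins = int(np.ceil((zt[-1] + hyp.epoch_s / 3600.0) / bin_h)) if len(zt) else 0
    density = np.zeros(max(n_bins, 1))
    nrems_h = np.zeros(max(n_bins, 1))
    for e in range(hyp.n_epochs):
        if hyp.labels[e] == "N":
            b = min(int(zt[e] / bin_h), len(nrems_h) - 1)
            nrems_h[b] += hyp.epoch_s / 3600.0
    if "outcome" in cs_flagged:
        continuing = cs_flagged["outcome"] == "NREMS-continuing"
    else:
        continuing = pd.Series(True, index=cs_flagged.index)
    flagged = cs_flagged[continuing & cs_flagged["ai_peak"]]
    for row in flagged.itertuples():
        t_h = (cs.cycles.loc[row.Index, "trough"] / cs.fs - hyp.zt0_s) / 3600.0
        b = min(max(int(t_h / bin_h), 0), len(density) - 1)
        density[b] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        per_hour = np.where(nrems_h > 0, density / nrems_h, np.nan)

    n_ma = int((cs_flagged.get("outcome") == "MA").sum()) if "outcome" in cs_flagged else 0
    n_peak = int((continuing & cs_flagged["ai_peak"]).sum())
    n_nopeak = int((continuing & ~cs_flagged["ai_peak"]).sum())
    total = n_ma + n_peak + n_nopeak
    breakdown = {
        "MA": n_ma / total if total else np.nan,
        "peak": n_peak / total if total else np.nan,
        "no_peak": n_nopeak / total if total else np.nan,
    }
    return {"zt_bins_h": np.arange(len(per_hour)) * bin_h, "per_hour_nrems": per_hour,
            "breakdown": breakdown, "counts": {"MA": n_ma, "peak": n_peak, "no_peak": n_nopeak}}
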