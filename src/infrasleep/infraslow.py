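"""The 0.02 Hz-fluctuation machinery.

NREMS sigma power (10-15 Hz) fluctuates with a ~50 s period; the phase of
that infraslow fluctuation rasters NREMS into *continuity* periods
(trough-to-peak, phase 270-90 deg, low arousability) and *fragility*
periods (peak-to-trough, 90-270 deg, elevated arousability).

Processing chain, matching the offline analysis convention:

1. Morlet wavelet power (four cycles) at 10-15 Hz in 0.5 Hz steps,
   averaged, block-downsampled to 10 Hz;
2. zero-phase FIR low-pass (cutoff 0.0125 Hz, order 100 at 10 Hz — the low
   order deliberately lets the 0.02 Hz component through) applied
   forward-backward across the whole recording, so no per-bout edge
   transients corrupt the phase;
3. normalization by the mean over NREMS+MA samples;
4. Hilbert phase of the mean-subtracted smoothed trace, mapped so the
   envelope peak sits at 0 deg and the trough at 180 deg;
5. cycle detection: local extrema with peak values above / trough values
   below the mask mean, same-type extrema separated by > 20 s, assembled
   into trough-peak-trough (equivalently peak-to-peak) cycles that appear
   only within NREMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Hypnogram, Recording, NREMS_LIKE, state_runs_samples

FRAGILITY_BAND = (90.0, 270.0)
_FIR_CUTOFF_HZ = 0.0125
_FIR_ORDER = 100
_MIN_SEPARATION_S = 20.0


# ---------------------------------------------------------------------------
# wavelet band power


def morlet_band_power(
    x: np.ndarray,
    fs: float,
    f_lo: float,
    f_hi: float,
    step: float = 0.5,
    n_cycles: float = 4.0,
    out_fs: float = 10.0,
) -> np.ndarray:
    """Mean Morlet power across center frequencies, block-downsampled.

    Power is the squared magnitude of the continuous wavelet coefficient
    with an L2-normalized complex Morlet mother wavelet of ``n_cycles``
    cycles; the mean across the ``step``-spaced center frequencies is
    averaged over consecutive blocks of ``fs/out_fs`` samples.
    """
    x = np.asarray(x, dtype=np.float64)
    freqs = np.arange(f_lo, f_hi + 1e-9, step)
    acc = np.zeros_like(x)
    for f in freqs:
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(5.0 * sigma_t * fs))
        tk = np.arange(-half, half + 1) / fs
        w = np.exp(2j * np.pi * f * tk) * np.exp(-(tk**2) / (2.0 * sigma_t**2))
        w /= np.linalg.norm(w)
        coef = signal.oaconvolve(x, w, mode="same")
        acc += np.abs(coef) ** 2
    acc /= len(freqs)
    dec = int(round(fs / out_fs))
    n_out = len(acc) // dec
    return acc[: n_out * dec].reshape(n_out, dec).mean(axis=1)


# ---------------------------------------------------------------------------
# sigma trace


@dataclass
class SigmaTrace:
    """Normalized NREMS sigma-power trace at 10 Hz with infraslow phase.

    ``power`` is normalized so its mean over the validity mask (NREMS plus
    MA samples) is 1; ``phase_deg`` is defined everywhere but interpreted
    only on the mask.
    """

    fs: float
    power: np.ndarray
    smoothed: np.ndarray
    phase_deg: np.ndarray
    mask: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.power)) / self.fs

    def index_at(self, t_s: float) -> int:
        idx = int(round(t_s * self.fs))
        if not 0 <= idx < len(self.power):
            raise IndexError(f"time {t_s} s outside sigma trace")
        return idx


def smooth_infraslow(x: np.ndarray, fs: float = 10.0) -> np.ndarray:
    """Zero-phase windowed-sinc low-pass (Hamming, order 100, fc 0.0125 Hz)."""
    taps = signal.firwin(_FIR_ORDER + 1, _FIR_CUTOFF_HZ, window="hamming", fs=fs)
    return signal.filtfilt(taps, [1.0], x)


def compute_phase(smoothed: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Hilbert phase of the mean-subtracted trace, degrees on [0, 360).

    The analytic-signal angle of a cosine is 0 at its maxima and 180 at its
    minima and increases through the cycle, which is exactly the required
    convention (peak = 0 deg, trough = 180 deg).  Raises on a constant
    trace, where phase is undefined.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if np.ptp(smoothed) == 0:
        raise ValueError("phase undefined: trace is constant")
    ref = smoothed[mask].mean() if mask is not None and mask.any() else smoothed.mean()
    analytic = signal.hilbert(smoothed - ref)
    return np.rad2deg(np.angle(analytic)) % 360.0


def compute_sigma_trace(
    rec: Recording, hyp: Hypnogram, channel: str = "EEG", out_fs: float = 10.0
) -> SigmaTrace:
    """Wavelet -> downsample -> FIR smooth -> NREMS+MA normalization -> phase."""
    pw = morlet_band_power(rec.channel(channel), rec.fs, 10.0, 15.0, out_fs=out_fs)
    lab = hyp.sample_labels(out_fs, len(pw))
    mask = np.isin(lab, NREMS_LIKE)
    if not mask.any():
        raise ValueError("no NREMS samples: sigma-trace normalization undefined")
    pw = pw / pw[mask].mean()
    sm = smooth_infraslow(pw, out_fs)
    phase = compute_phase(sm, mask)
    return SigmaTrace(out_fs, pw, sm, phase, mask)


# ---------------------------------------------------------------------------
# infraslow spectrum


def infraslow_spectrum(
    st: SigmaTrace,
    hyp: Hypnogram,
    min_bout_s: float = 100.0,
    n_grid: int = 201,
    f_max: float = 0.5,
) -> dict:
    """Bout-averaged FFT of the sigma trace on a common 201-point 0-0.5 Hz grid.

    Per NREMS(+MA) bout longer than ``min_bout_s``, the mean-subtracted
    normalized sigma power is transformed; bins from 0 to 0.5 Hz are
    linearly interpolated onto the common grid before averaging across
    bouts.  Returns peak frequency/power (DC-adjacent bins below 0.005 Hz
    are excluded from the peak search) plus the averaged spectrum.
    """
    n = len(st.power)
    runs = [
        (a, b)
        for a, b in state_runs_samples(hyp, st.fs, n, NREMS_LIKE)
        if (b - a) / st.fs >= min_bout_s
    ]
    if not runs:
        raise ValueError(f"no NREMS bout of at least {min_bout_s} s")
    grid = np.linspace(0.0, f_max, n_grid)
    specs = []
    for a, b in runs:
        seg = st.power[a:b] - st.power[a:b].mean()
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / st.fs)
        ps = np.abs(np.fft.rfft(seg)) ** 2 / len(seg)
        sel = freqs <= f_max
        specs.append(np.interp(grid, freqs[sel], ps[sel]))
    mean_spec = np.mean(specs, axis=0)
    search = grid >= 0.005
    k = int(np.argmax(np.where(search, mean_spec, -np.inf)))
    return {
        "peak_freq_hz": float(grid[k]),
        "peak_power": float(mean_spec[k]),
        "freqs": grid,
        "spectrum": mean_spec,
        "n_bouts": len(runs),
    }


# ---------------------------------------------------------------------------
# cycle detection


@dataclass
class CycleSet:
    """Detected trough-peak-trough infraslow cycles.

    ``cycles`` columns: ``peak1, trough, peak2`` (sample indices into the
    sigma trace); classification adds ``outcome`` and AI-peak analysis adds
    ``ai_peak``.  The continuity span runs trough -> peak2, the fragility
    span peak1 -> trough; phase-defined spans use [90, 270) deg.
    """

    fs: float
    cycles: pd.DataFrame

    def __len__(self) -> int:
        return len(self.cycles)

    def span_indices(self, row) -> np.ndarray:
        return np.arange(int(row.peak1), int(row.peak2) + 1)

    def fragility_indices(self, row, phase_deg: np.ndarray) -> np.ndarray:
        idx = self.span_indices(row)
        ph = phase_deg[idx]
        return idx[(ph >= FRAGILITY_BAND[0]) & (ph < FRAGILITY_BAND[1])]

    def continuity_indices(self, row, phase_deg: np.ndarray) -> np.ndarray:
        idx = self.span_indices(row)
        ph = phase_deg[idx]
        return idx[(ph < FRAGILITY_BAND[0]) | (ph >= FRAGILITY_BAND[1])]


def detect_cycles(st: SigmaTrace, hyp: Hypnogram, min_bout_s: float = 40.0) -> CycleSet:
    """Find trough-peak-trough cycles of the smoothed sigma trace.

    Peaks must exceed and troughs undercut the mask mean, same-type extrema
    are separated by more than 20 s, and a cycle is retained only when its
    whole peak-to-peak span lies inside one NREMS(+MA) run.  Runs shorter
    than ``min_bout_s`` cannot satisfy two separations and are skipped.
    Ties/plateaus resolve to the plateau midpoint (scipy convention).
    """
    x = st.smoothed
    m = x[st.mask].mean()
    dist = int(_MIN_SEPARATION_S * st.fs) + 1
    peaks, _ = signal.find_peaks(x, height=m, distance=dist)
    troughs, _ = signal.find_peaks(-x, height=-m, distance=dist)

    runs = [
        (a, b)
        for a, b in state_runs_samples(hyp, st.fs, len(x), NREMS_LIKE)
        if (b - a) / st.fs >= min_bout_s
    ]
    rows = []
    for a, b in runs:
        p = peaks[(peaks >= a) & (peaks < b)]
        tr = troughs[(troughs >= a) & (troughs < b)]
        for p1, p2 in zip(p[:-1], p[1:]):
            between = tr[(tr > p1) & (tr < p2)]
            if between.size == 0:
                continue
            t0 = between[int(np.argmin(x[between]))]
            rows.append({"peak1": int(p1), "trough": int(t0), "peak2": int(p2)})
    return CycleSet(st.fs, pd.DataFrame(rows, columns=["peak1", "trough", "peak2"]))


# ---------------------------------------------------------------------------
# event-phase coupling


def phase_at_events(
    st: SigmaTrace, events: pd.DataFrame, offsets_s=(0.0, 4.0, 8.0, 12.0)
) -> pd.DataFrame:
    """Infraslow phase at event onsets and at fixed offsets before them.

    One row per event, one ``phase_minus_<o>s`` column per offset; events
    whose onset (or offset sample) falls outside the recording raise.
    """
    out = {}
    for o in offsets_s:
        vals = []
        for t in events["onset_s"].to_numpy(dtype=float):
            vals.append(st.phase_deg[st.index_at(t - o)])
        out[f"phase_minus_{o:g}s"] = vals
    df = pd.DataFrame(out)
    df.insert(0, "onset_s", events["onset_s"].to_numpy(dtype=float))
    return df


def classify_fragility_outcomes(
    cs: CycleSet,
    st: SigmaTrace,
    hyp: Hypnogram,
    events: pd.DataFrame,
    rems_lookahead_s: float | None = None,
) -> dict:
    """Label every fragility period MA / REMS-transition / NREMS-continuing.

    A cycle's fragility span (phase 90-270 deg within its peak-to-peak
    extent) is labeled ``MA`` when an MA onset with phase in the band falls
    inside it, else ``NREMS-continuing``.  Because a complete cycle cannot
    end in REMS, each NREMS run's final detected peak contributes one extra
    terminal fragility period labeled ``REMS-transition`` when the run ends
    within 1.5 infraslow periods after it and REMS follows.

    Returns ``{"cycles": DataFrame with outcome, "proportions": dict}``;
    the proportions sum to 1.
    """
    ma = events[events["type"] == "MA"] if len(events) else events
    onsets = ma["onset_s"].to_numpy(dtype=float) if len(ma) else np.empty(0)
    onset_idx = np.round(onsets * st.fs).astype(int)
    onset_idx = onset_idx[(onset_idx >= 0) & (onset_idx < len(st.phase_deg))]
    in_band = (st.phase_deg[onset_idx] >= FRAGILITY_BAND[0]) & (
        st.phase_deg[onset_idx] < FRAGILITY_BAND[1]
    )
    band_onsets = set(onset_idx[in_band])

    outcomes = []
    for row in cs.cycles.itertuples():
        frag = cs.fragility_indices(row, st.phase_deg)
        fragset = set(frag)
        outcomes.append("MA" if band_onsets & fragset else "NREMS-continuing")
    cycles = cs.cycles.copy()
    cycles["outcome"] = outcomes

    # Terminal fragility periods: after each NREMS run's final detected
    # peak no full cycle forms.  When the phase still completes the 90-270
    # span inside the run, that span is an ordinary fragility period (MA or
    # NREMS-continuing); when the run ends mid-span and REMS follows, it is
    # a fragility period containing a REMS transition (an in-band MA onset
    # takes priority).  Spans truncated by wake are not counted: brief
    # awakenings are MAs by definition and longer ones end the bout outside
    # the paper's three-way taxonomy.
    n_rems_term = 0
    n_term_ma = 0
    n_term_cont = 0
    if rems_lookahead_s is None:
        rems_lookahead_s = 75.0  # 1.5 x the nominal 50-s period
    lab10 = hyp.sample_labels(st.fs, len(st.power))
    runs = state_runs_samples(hyp, st.fs, len(st.power), NREMS_LIKE)
    peaks_all = cs.cycles[["peak1", "peak2"]].to_numpy().ravel() if len(cs.cycles) else np.empty(0)
    for a, b in runs:
        in_run = peaks_all[(peaks_all >= a) & (peaks_all < b)]
        if in_run.size == 0:
            continue
        last_peak = int(in_run.max())
        tail = np.arange(last_peak, min(b, last_peak + int(rems_lookahead_s * st.fs)))
        ph = st.phase_deg[tail]
        in_span = tail[(ph >= FRAGILITY_BAND[0]) & (ph < FRAGILITY_BAND[1])]
        if in_span.size == 0:
            continue
        has_ma = bool(band_onsets & set(in_span))
        # the span is complete when the phase passes 270 deg after having
        # been inside the band (not counting near-0 jitter at the peak)
        after_entry = tail > in_span[0]
        complete = bool(np.any(after_entry & (ph >= FRAGILITY_BAND[1])))
        if complete:
            if has_ma:
                n_term_ma += 1
            else:
                n_term_cont += 1
        elif b < len(lab10) and lab10[min(b, len(lab10) - 1)] == "R":
            if has_ma:
                n_term_ma += 1
            else:
                n_rems_term += 1

    counts = {
        "MA": int((cycles["outcome"] == "MA").sum()) + n_term_ma,
        "REMS-transition": n_rems_term,
        "NREMS-continuing": int((cycles["outcome"] == "NREMS-continuing").sum()) + n_term_cont,
    }
    total = sum(counts.values())
    props = {k: (v / total if total else np.nan) for k, v in counts.items()}
    return {"cycles": cycles, "proportions": props, "counts": counts}
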