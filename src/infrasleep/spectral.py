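"""Epoch FFTs and state-specific spectral normalizations.

Every scored 4-s epoch is mean-subtracted (offset correction) and
transformed with a single-taper periodogram, giving a 0.25 Hz bin width.
Two normalization schemes are provided:

- sleep spectra: per-state *median* spectrum over epochs non-adjacent to
  state transitions, divided by one constant — the average across states of
  each state's mean 0.75-47 Hz power — so every state carries equal weight;
- wake spectra: per-set (quiet/active wakefulness) *mean* spectrum with each
  bin divided by the summed 2-30 Hz power of that set.

Both are invariant to a global amplitude gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Hypnogram, Recording

#: default band edges in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 10.0),
    "sigma": (10.0, 15.0),
    "beta": (16.0, 25.0),
    "low_gamma": (26.0, 40.0),
    "high_gamma": (60.0, 80.0),
    "emg_high": (100.0, 500.0),
}


@dataclass
class EpochSpectra:
    """Per-epoch power spectral densities.

    ``psd`` has shape (n_freqs, n_epochs); ``transition_adjacent`` flags
    epochs whose predecessor or successor carries a different label.
    """

    freqs: np.ndarray
    psd: np.ndarray
    states: np.ndarray
    transition_adjacent: np.ndarray
    epoch_s: float = 4.0
    zt0_s: float = 0.0

    @property
    def n_epochs(self) -> int:
        return self.psd.shape[1]

    def band_power(self, lo: float, hi: float) -> np.ndarray:
        """Mean PSD in [lo, hi] Hz per epoch."""
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return self.psd[sel].mean(axis=0)

    def zt_hours(self) -> np.ndarray:
        return (np.arange(self.n_epochs) * self.epoch_s - self.zt0_s) / 3600.0


def epoch_spectra(rec: Recording, hyp: Hypnogram, channel: str) -> EpochSpectra:
    """Periodogram of every mean-subtracted 4-s epoch of ``channel``."""
    x = rec.channel(channel)
    per = int(round(hyp.epoch_s * rec.fs))
    n_ep = min(hyp.n_epochs, len(x) // per)
    seg = x[: n_ep * per].reshape(n_ep, per)
    seg = seg - seg.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(seg, axis=1)
    # one-sided periodogram density; the absolute scale cancels downstream
    psd = (np.abs(spec) ** 2) * (2.0 / (rec.fs * per))
    psd[:, 0] /= 2.0
    if per % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(per, d=1.0 / rec.fs)
    states = hyp.labels[:n_ep]
    adj = np.zeros(n_ep, dtype=bool)
    adj[1:] |= states[1:] != states[:-1]
    adj[:-1] |= states[:-1] != states[1:]
    return EpochSpectra(freqs, psd.T, states, adj, hyp.epoch_s, hyp.zt0_s)


def sleep_state_spectrum(
    es: EpochSpectra, states=("W", "N", "R"), norm_band=(0.75, 47.0)
) -> dict[str, np.ndarray]:
    """Normalized per-state median spectra (transition epochs excluded)."""
    sel_band = (es.freqs >= norm_band[0]) & (es.freqs <= norm_band[1])
    medians, levels = {}, []
    for s in states:
        pick = (es.states == s) & ~es.transition_adjacent
        if not pick.any():
            warnings.warn(f"state {s!r} has no non-transition epochs; omitted", stacklevel=2)
            continue
        med = np.median(es.psd[:, pick], axis=1)
        medians[s] = med
        levels.append(med[sel_band].mean())
    if not medians:
        raise ValueError("no state with non-transition epochs")
    constant = float(np.mean(levels))
    return {s: med / constant for s, med in medians.items()}


def wake_spectrum(
    es: EpochSpectra, qw_epochs: set[int], aw_epochs: set[int], norm_band=(2.0, 30.0)
) -> dict:
    """Normalized QW/AW mean spectra plus theta/beta/low-gamma summaries."""
    out = {}
    for name, epochs in (("QW", qw_epochs), ("AW", aw_epochs)):
        idx = sorted(epochs)
        if not idx:
            raise ValueError(f"{name} epoch set is empty")
        mean = es.psd[:, idx].mean(axis=1)
        sel = (es.freqs >= norm_band[0]) & (es.freqs <= norm_band[1])
        norm = mean / mean[sel].sum()
        bands = {
            b: float(norm[(es.freqs >= lo) & (es.freqs <= hi)].sum())
            for b, (lo, hi) in BANDS.items()
            if b in ("theta", "beta", "low_gamma")
        }
        out[name] = {"spectrum": norm, "bands": bands}
    out["freqs"] = es.freqs
    return out


def segment_quiet_active_wake(
    emg: np.ndarray, fs: float, hyp: Hypnogram, min_wake_epochs: int = 20
) -> tuple[set[int], set[int]]:
    """Quiet/active wakefulness epoch sets from ln(EMG^2) percentiles.

    Per-animal thresholds: QW spans the 10th-25th percentile of the
    per-wake-epoch ln squared EMG (only runs of >= 3 consecutive qualifying
    epochs are kept, > 12 s), AW the 50th-99th.  The 25-50 band is left
    unassigned by design.
    """
    per = int(round(hyp.epoch_s * fs))
    n_ep = min(hyp.n_epochs, len(emg) // per)
    wake_idx = np.flatnonzero(hyp.labels[:n_ep] == "W")
    if wake_idx.size < min_wake_epochs:
        raise ValueError(f"need >= {min_wake_epochs} wake epochs, got {wake_idx.size}")
    sq = np.square(emg[: n_ep * per]).reshape(n_ep, per).mean(axis=1)
    ln = np.log(sq[wake_idx])
    q10, q25, q50, q99 = np.quantile(ln, [0.10, 0.25, 0.50, 0.99])

    qual = wake_idx[(ln >= q10) & (ln <= q25)]
    qual_set = set(qual)
    qw = set()
    run = []
    for e in sorted(qual_set):
        if run and e == run[-1] + 1:
            run.append(e)
        else:
            if len(run) >= 3:
                qw.update(run)
            run = [e]
    if len(run) >= 3:
        qw.update(run)
    aw = set(wake_idx[(ln >= q50) & (ln <= q99)])
    return qw, aw


def gamma_ratio(
    es_baseline: EpochSpectra, es_followup: EpochSpectra, band=(60.0, 80.0)
) -> dict[str, float]:
    """Follow-up / baseline ratio of state-normalized 60-80 Hz power."""
    base = sleep_state_spectrum(es_baseline)
    fol = sleep_state_spectrum(es_followup)
    out = {}
    for s in base:
        if s not in fol:
            continue
        sel = (es_baseline.freqs >= band[0]) & (es_baseline.freqs <= band[1])
        out[s] = float(fol[s][sel].mean() / base[s][sel].mean())
    return out


def delta_timecourse(
    es: EpochSpectra,
    hyp: Hypnogram,
    n_light: int = 12,
    n_dark: int = 6,
    normalize: bool = True,
) -> dict:
    """Delta-power trajectory over periods of equal NREMS content.

    Light-phase (ZT 0-12) NREMS epochs are split into ``n_light`` periods of
    equal epoch count, dark-phase ones into ``n_dark``; raw 1-4 Hz power of
    non-transition NREMS epochs is averaged per period and normalized to the
    ZT9-12 mean.  Raises when normalization is requested but no ZT9-12
    NREMS exists.
    """
    delta = es.band_power(*BANDS["delta"])
    zt = es.zt_hours() % 24.0
    pick = (es.states == "N") & ~es.transition_adjacent
    idx = np.flatnonzero(pick)
    if idx.size == 0:
        raise ValueError("no non-transition NREMS epochs")

    phases = [("light", (zt[idx] >= 0) & (zt[idx] < 12), n_light),
              ("dark", (zt[idx] >= 12) & (zt[idx] < 24), n_dark)]
    times, values, labels = [], [], []
    for name, sel, n_per in phases:
        sub = idx[sel]
        if sub.size == 0:
            continue
        splits = np.array_split(sub, n_per)
        for part in splits:
            if part.size == 0:
                continue
            times.append(float(zt[part].mean()))
            values.append(float(delta[part].mean()))
            labels.append(name)
    values = np.asarray(values)
    if normalize:
        ref = idx[(zt[idx] >= 9.0) & (zt[idx] < 12.0)]
        if ref.size == 0:
            raise ValueError("no NREMS epochs in ZT9-12 to normalize against")
        values = values / delta[ref].mean()
    return {"zt_h": np.asarray(times), "delta": values, "phase": labels}
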