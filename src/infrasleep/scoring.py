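"""Epoch-level scoring: the microarousal rule, bout statistics, sleep-onset
latency and time-in-state summaries.

An MA is scored whenever a short awakening (at most four consecutive 4-s
epochs, i.e. <= 16 s) interrupts NREMS together with a burst of EMG
activity.  Because visual scoring is replaced here by rule-based scoring,
the EMG burst is defined as the squared-EMG epoch mean exceeding a multiple
of its NREMS median, and EEG desynchronization as a delta-power drop below
a fraction of the NREMS mean; both factors are configurable proxies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Hypnogram

MAX_MA_EPOCHS = 4  # 16 s at 4-s epochs
SLEEP_ONSET_RUN = 6  # six consecutive NREMS epochs (24 s)


def emg_burst_epochs(
    emg: np.ndarray, fs: float, hyp: Hypnogram, factor: float = 5.0
) -> set[int]:
    """Epochs whose mean squared EMG exceeds ``factor`` x the NREMS median."""
    per = int(round(hyp.epoch_s * fs))
    n_ep = min(hyp.n_epochs, len(emg) // per)
    sq = np.square(emg[: n_ep * per]).reshape(n_ep, per).mean(axis=1)
    nrems = sq[hyp.labels[:n_ep] == "N"]
    if nrems.size == 0:
        return set()
    thr = factor * np.median(nrems)
    return set(np.flatnonzero(sq > thr))


def eeg_desync_epochs(
    delta_power: np.ndarray, hyp: Hypnogram, fraction: float = 0.5
) -> set[int]:
    """Epochs whose delta power drops below ``fraction`` of the NREMS mean.

    A reproducible proxy for the visual 'desynchronization' criterion.
    """
    delta_power = np.asarray(delta_power, dtype=float)
    nrems = delta_power[hyp.labels[: len(delta_power)] == "N"]
    if nrems.size == 0:
        return set()
    return set(np.flatnonzero(delta_power < fraction * nrems.mean()))


def score_microarousals(hyp: Hypnogram, emg_burst: set[int]) -> Hypnogram:
    """Relabel qualifying short wake runs as MA.

    A wake run of at most four epochs, flanked on both sides by NREMS (or
    already-scored MA), and containing at least one EMG-burst epoch becomes
    ``M``.  Longer runs, unflanked runs, and burst-free runs are untouched.
    MAs interrupting REMS are not scored.  Idempotent; total epoch count is
    conserved.
    """
    out = hyp.copy()
    runs = out.runs()
    nrems_like = {"N", "M"}
    for r in runs.itertuples():
        if r.state != "W" or r.n_epochs > MAX_MA_EPOCHS:
            continue
        lo, hi = r.start_epoch, r.start_epoch + r.n_epochs
        if lo == 0 or hi == out.n_epochs:
            continue
        if out.labels[lo - 1] not in nrems_like or out.labels[hi] not in nrems_like:
            continue
        if not any(e in emg_burst for e in range(lo, hi)):
            continue
        out.labels[lo:hi] = "M"
    return out


def bout_table(hyp: Hypnogram) -> pd.DataFrame:
    """Maximal same-state runs: state, start_epoch, n_epochs, duration_s."""
    runs = hyp.runs()
    runs["duration_s"] = runs["n_epochs"] * hyp.epoch_s
    return runs


def bout_statistics(hyps: Hypnogram | list[Hypnogram], state: str) -> dict:
    """Bout-size distribution for one state, pooled across animals.

    The intermediate-bin edges are computed on the pooled bout-duration
    distribution as ``[mean - sd/2, mean + sd]``; occupancy is time spent
    in bouts of each size class.

    Returns a dict with keys ``bouts`` (per-animal DataFrame), ``edges_s``,
    ``occupancy_s`` ({short, intermediate, long}), and ``cumulative``
    (sorted durations and cumulative fraction).
    """
    if isinstance(hyps, Hypnogram):
        hyps = [hyps]
    frames = []
    for i, h in enumerate(hyps):
        bt = bout_table(h)
        bt = bt[bt["state"] == state].copy()
        bt["animal"] = i
        frames.append(bt)
    bouts = pd.concat(frames, ignore_index=True)
    if len(bouts) == 0:
        return {
            "bouts": bouts,
            "edges_s": (np.nan, np.nan),
            "occupancy_s": {"short": 0.0, "intermediate": 0.0, "long": 0.0},
            "cumulative": (np.empty(0), np.empty(0)),
        }
    d = bouts["duration_s"].to_numpy(dtype=float)
    mean, sd = d.mean(), d.std(ddof=0)
    lo, hi = mean - sd / 2.0, mean + sd
    occupancy = {
        "short": float(d[d < lo].sum()),
        "intermediate": float(d[(d >= lo) & (d <= hi)].sum()),
        "long": float(d[d > hi].sum()),
    }
    order = np.sort(d)
    cumfrac = np.arange(1, len(order) + 1) / len(order)
    return {
        "bouts": bouts,
        "edges_s": (lo, hi),
        "occupancy_s": occupancy,
        "cumulative": (order, cumfrac),
    }


def sleep_onset_latency(hyp: Hypnogram) -> float:
    """Seconds from recording start (ZT0) to the first run of six
    consecutive NREMS epochs; NaN when no such run exists."""
    isn = (hyp.labels == "N").astype(int)
    if len(isn) >= SLEEP_ONSET_RUN:
        kernel = np.ones(SLEEP_ONSET_RUN, dtype=int)
        runs = np.convolve(isn, kernel, mode="valid")
        hits = np.flatnonzero(runs == SLEEP_ONSET_RUN)
        if hits.size:
            return float(hits[0] * hyp.epoch_s)
    return float("nan")


def time_in_state(hyp: Hypnogram, window_s: tuple[float, float] | None = None) -> dict:
    """Per-state time percentages plus MA density per hour of NREMS.

    Percentages (over W/N/R/M) sum to 100 for any non-empty window.  The
    MA density counts MA episodes (maximal M runs starting in the window)
    per hour spent in plain-N epochs.
    """
    if window_s is None:
        window_s = (0.0, hyp.duration_s)
    lo = int(np.floor(window_s[0] / hyp.epoch_s))
    hi = int(np.ceil(window_s[1] / hyp.epoch_s))
    lo, hi = max(0, lo), min(hyp.n_epochs, hi)
    if hi <= lo:
        raise ValueError(f"empty window {window_s}")
    lab = hyp.labels[lo:hi]
    n = len(lab)
    percent = {s: 100.0 * np.count_nonzero(lab == s) / n for s in ("W", "N", "R", "M")}
    runs = hyp.runs()
    ma_runs = runs[(runs["state"] == "M") & (runs["start_epoch"] >= lo) & (runs["start_epoch"] < hi)]
    nrems_h = np.count_nonzero(lab == "N") * hyp.epoch_s / 3600.0
    density = len(ma_runs) / nrems_h if nrems_h > 0 else float("nan")
    return {"percent": percent, "ma_per_hour_nrems": density, "n_ma": len(ma_runs)}
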