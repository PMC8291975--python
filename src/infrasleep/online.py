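"""Streaming vigilance-state machine, online sigma estimate, training-set
construction, and the continuity/fragility classifier with shuffle
validation.

Two decision layers run once per second on causal buffers:

1. a rule-based likely-state machine on the delta/theta power ratio of the
   mean-centered last 4 s of EEG and the per-second EMG power, implementing
   the seven threshold transition rules out of Wake, NREMS and REMS;
2. a small feed-forward network (one 10-unit hidden layer, 3 outputs)
   deciding continuity / fragility / none from the last 200 s of online
   sigma power — normalized by a dynamically updated NREMS mean and
   summarized by a ninth-order polynomial fit — plus the current
   delta/theta ratio and EMG power.

Training labels come from offline cycle detection: continuity is
trough-to-peak, fragility peak-to-trough, none elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import Hypnogram, Recording
from .infraslow import CycleSet

BUFFER_S = 200
POLY_DEGREE = 9
LABELS = ("continuity", "fragility", "none")


@dataclass
class OnlineThresholds:
    """Heuristic state-machine thresholds (per recording)."""

    emg_high: float
    emg_low: float
    ratio_high: float
    ratio_low: float


def per_second_features(rec: Recording, eeg_channel: str = "EEG", emg_channel: str = "EMG"):
    """Per-second delta/theta ratio, sigma power and EMG power.

    Second ``k`` is evaluated at its end from the mean-centered last 4 s of
    EEG (FFT) and the squared EMG of second ``k`` itself; the first three
    seconds carry NaN ratios.  Returns a DataFrame with columns
    ``ratio, sigma, emg``.
    """
    fs = int(round(rec.fs))
    eeg, emg = rec.channel(eeg_channel), rec.channel(emg_channel)
    n_sec = len(eeg) // fs
    ratio = np.full(n_sec, np.nan)
    sigma = np.full(n_sec, np.nan)
    freqs = np.fft.rfftfreq(4 * fs, d=1.0 / fs)
    d_sel = (freqs >= 1.0) & (freqs <= 4.0)
    t_sel = (freqs >= 5.0) & (freqs <= 10.0)
    s_sel = (freqs >= 10.0) & (freqs <= 15.0)
    for k in range(3, n_sec):
        seg = eeg[(k - 3) * fs : (k + 1) * fs]
        seg = seg - seg.mean()
        ps = np.abs(np.fft.rfft(seg)) ** 2
        ratio[k] = ps[d_sel].mean() / ps[t_sel].mean()
        sigma[k] = ps[s_sel].mean()
    emg_pow = np.square(emg[: n_sec * fs]).reshape(n_sec, fs).mean(axis=1)
    return pd.DataFrame({"ratio": ratio, "sigma": sigma, "emg": emg_pow})


def calibrate_thresholds(
    rec: Recording,
    hyp: Hypnogram,
    window_s: float | None = 600.0,
    eeg_channel: str = "EEG",
    emg_channel: str = "EMG",
) -> OnlineThresholds:
    """Auto-calibrate thresholds from state-conditional feature distributions.

    Uses the first ``window_s`` of the recording (the whole recording when
    None, or when a needed state is missing from the window): the EMG high
    threshold is the 75th percentile of wake EMG power, the EMG low
    threshold sits between REMS- and NREMS-level EMG, and the ratio
    thresholds are geometric midpoints of the state-conditional medians.
    """
    feats = per_second_features(rec, eeg_channel, emg_channel)
    states = hyp.sample_labels(1.0, len(feats))
    states = np.where(states == "M", "W", states)  # MAs behave like brief wake

    def window(need):
        if window_s is not None:
            w = min(int(window_s), len(feats))
            sub = states[:w]
            if all((sub == s).sum() >= 10 for s in need):
                return feats.iloc[:w], sub
        return feats, states

    f, s = window(("W", "N"))
    valid = ~f["ratio"].isna().to_numpy()
    wake = valid & (s == "W")
    nrems = valid & (s == "N")
    rems = valid & (s == "R")
    if wake.sum() < 5 or nrems.sum() < 5:
        raise ValueError("calibration needs wake and NREMS seconds")
    emg_high = float(np.quantile(f["emg"][wake], 0.75))
    if rems.sum() >= 10:
        emg_low = float(
            np.sqrt(np.median(f["emg"][rems]) * np.median(f["emg"][nrems]))
        )
    else:
        emg_low = float(0.5 * np.median(f["emg"][nrems]))
    r_w = np.median(f["ratio"][wake])
    r_n = np.median(f["ratio"][nrems])
    ratio_high = float(np.sqrt(r_w * r_n))
    if rems.sum() >= 10:
        r_r = np.median(f["ratio"][rems])
        ratio_low = float(np.sqrt(r_r * r_n))
    else:
        ratio_low = float(0.5 * ratio_high)
    return OnlineThresholds(emg_high, emg_low, ratio_high, ratio_low)


class OnlineStateMachine:
    """Per-second likely-state classifier with no hidden state beyond the
    documented 5-s feature buffers and the current state."""

    def __init__(self, thresholds: OnlineThresholds, initial: str = "W"):
        self.thr = thresholds
        self.state = initial
        self._ratio: list[float] = []
        self._emg: list[float] = []

    def step(self, ratio: float, emg: float) -> str:
        t = self.thr
        self._ratio.append(ratio)
        self._emg.append(emg)
        if len(self._ratio) > 5:
            self._ratio.pop(0)
            self._emg.pop(0)
        r, e = self._ratio, self._emg
        if len(r) >= 5 and not any(np.isnan(r)):
            if self.state == "W":
                if all(v < t.emg_high for v in e[-3:]) and sum(
                    v > t.ratio_high for v in r[-3:]
                ) >= 2:
                    self.state = "N"
                elif all(v < t.emg_low for v in e) and all(v > t.ratio_high for v in r):
                    self.state = "R"
            elif self.state == "N":
                if e[-1] > t.emg_high:
                    self.state = "W"
                elif (
                    all(v < t.emg_low for v in e)
                    and sum(v < t.ratio_low for v in r) >= 4
                    and all(v < t.ratio_high for v in r)
                ):
                    self.state = "R"
            else:  # REMS
                if e[-1] > t.emg_high:
                    self.state = "W"
                elif sum(v > t.ratio_high for v in r) >= 4:
                    self.state = "N"
        return self.state


def run_state_machine(
    feats: pd.DataFrame, thresholds: OnlineThresholds, initial: str = "W"
) -> np.ndarray:
    """States for every second of a feature table (streaming-consistent:
    this is literally the per-second loop)."""
    sm = OnlineStateMachine(thresholds, initial)
    return np.array(
        [sm.step(r, e) for r, e in zip(feats["ratio"], feats["emg"])], dtype="<U1"
    )


class OnlineSigmaTracker:
    """Online normalized sigma buffer with a ninth-order polynomial summary.

    The NREMS sigma mean is updated as a running mean over seconds whose
    likely state is NREMS and normalizes every incoming value; the last
    200 s are kept regardless of state.
    """

    def __init__(self, buffer_s: int = BUFFER_S, degree: int = POLY_DEGREE):
        self.buffer_s = buffer_s
        self.degree = degree
        self._sum = 0.0
        self._n = 0
        self.buffer: list[float] = []

    @property
    def nrems_mean(self) -> float:
        return self._sum / self._n if self._n else np.nan

    def step(self, sigma: float, likely_state: str) -> float:
        if likely_state == "N" and np.isfinite(sigma):
            self._sum += sigma
            self._n += 1
        norm = sigma / self.nrems_mean if self._n else np.nan
        self.buffer.append(norm)
        if len(self.buffer) > self.buffer_s:
            self.buffer.pop(0)
        return norm

    @property
    def full(self) -> bool:
        return len(self.buffer) == self.buffer_s and np.isfinite(self.buffer).all()

    def fitted_curve(self) -> np.ndarray:
        """Degree-9 polynomial fit over the buffer (constant for a
        degenerate all-equal buffer)."""
        y = np.asarray(self.buffer, dtype=float)
        if len(y) < self.degree + 1 or np.ptp(y[np.isfinite(y)]) == 0:
            return np.full(len(y), np.nanmean(y) if len(y) else np.nan)
        x = np.linspace(-1.0, 1.0, len(y))
        ok = np.isfinite(y)
        coefs = np.polynomial.polynomial.polyfit(x[ok], y[ok], self.degree)
        return np.polynomial.polynomial.polyval(x, coefs)


def period_labels_from_cycles(cs: CycleSet, n_seconds: int) -> np.ndarray:
    """Per-second offline labels: continuity trough->peak2, fragility
    peak1->trough, none elsewhere."""
    lab = np.full(n_seconds, "none", dtype="<U10")
    for row in cs.cycles.itertuples():
        f0, f1 = int(row.peak1 / cs.fs), int(row.trough / cs.fs)
        c1 = int(row.peak2 / cs.fs)
        lab[max(0, f0) : min(n_seconds, f1)] = "fragility"
        lab[max(0, f1) : min(n_seconds, c1)] = "continuity"
    return lab


def run_online(
    rec: Recording,
    thresholds: OnlineThresholds,
    eeg_channel: str = "EEG",
    emg_channel: str = "EMG",
) -> dict:
    """Run the causal per-second pipeline over a whole recording.

    Returns per-second states, normalized sigma, and the polynomial-fit
    buffer (rows of 200 fitted values; NaN rows until the buffer fills).
    """
    feats = per_second_features(rec, eeg_channel, emg_channel)
    n = len(feats)
    sm = OnlineStateMachine(thresholds)
    tracker = OnlineSigmaTracker()
    states = np.empty(n, dtype="<U1")
    fitted = np.full((n, BUFFER_S), np.nan)
    sig_norm = np.full(n, np.nan)
    for k in range(n):
        states[k] = sm.step(feats["ratio"][k], feats["emg"][k])
        sig_norm[k] = tracker.step(feats["sigma"][k], states[k])
        if tracker.full:
            fitted[k] = tracker.fitted_curve()
    return {"features": feats, "states": states, "sigma_norm": sig_norm, "fitted": fitted}


def make_training_set(
    online: dict, cs: CycleSet, n_seconds: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """200-s moving-window chunks with offline continuity/fragility labels.

    One chunk per second once the sigma buffer is full; the feature vector
    is the 200-sample polynomial-fit sigma curve plus the current
    delta/theta ratio and EMG power; the label is the offline period
    containing the chunk's final second.  The number of usable chunks per
    recording is (usable seconds - buffer length + 1).
    """
    feats = online["features"]
    fitted = online["fitted"]
    if n_seconds is None:
        n_seconds = len(feats)
    labels = period_labels_from_cycles(cs, n_seconds)
    rows, y = [], []
    for k in range(n_seconds):
        if np.isnan(fitted[k]).any():
            continue
        rows.append(
            np.concatenate([fitted[k], [feats["ratio"][k], feats["emg"][k]]])
        )
        y.append(labels[k])
    return np.asarray(rows), np.asarray(y)


def train_period_classifier(X: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """Train the 10-unit single-hidden-layer network on a 70/15/15 split.

    Returns the fitted pipeline, the held-out test confusion matrix (rows
    true, columns predicted, label order continuity/fragility/none) and
    split accuracies; deterministic for a fixed seed.
    """
    present = set(np.unique(y))
    missing = set(LABELS) - present
    if missing:
        raise ValueError(f"training set misses label classes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_tr, n_va = int(0.70 * n), int(0.15 * n)
    tr = order[:n_tr]
    va = order[n_tr : n_tr + n_va]
    te = order[n_tr + n_va :]
    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(10,),
            max_iter=400,
            random_state=seed,
            early_stopping=False,
        ),
    )
    model.fit(X[tr], y[tr])

    def acc(idx):
        return float((model.predict(X[idx]) == y[idx]).mean()) if len(idx) else np.nan

    pred_te = model.predict(X[te])
    conf = np.zeros((3, 3), dtype=int)
    lab_idx = {l: i for i, l in enumerate(LABELS)}
    for t, p in zip(y[te], pred_te):
        conf[lab_idx[t], lab_idx[p]] += 1
    return {
        "model": model,
        "confusion": conf,
        "labels": LABELS,
        "accuracy": {"train": acc(tr), "validation": acc(va), "test": acc(te)},
        "split": {"train": tr, "validation": va, "test": te},
    }


def predict_periods(model, online: dict) -> np.ndarray:
    """Per-second continuity/fragility/none decisions ('none' while the
    buffer is filling)."""
    feats = online["features"]
    fitted = online["fitted"]
    out = np.full(len(feats), "none", dtype="<U10")
    ok = ~np.isnan(fitted).any(axis=1)
    if ok.any():
        X = np.column_stack(
            [fitted[ok], feats["ratio"][ok].to_numpy(), feats["emg"][ok].to_numpy()]
        )
        out[ok] = model.predict(X)
    return out


def validate_online_detection(
    period_labels: np.ndarray,
    ma_onsets_s: np.ndarray,
    nrems_seconds: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
) -> dict:
    """Shuffle test of MA capture by online-detected periods.

    Computes the proportion of scored MAs whose onset second carries each
    online label, then builds a null by repositioning the detected
    fragility/continuity seconds uniformly within the recording's NREMS
    seconds ``n_shuffles`` times (detection counts preserved); reports the
    percentile of the observed proportion within each null.
    """
    ma_onsets_s = np.asarray(ma_onsets_s, dtype=float)
    if ma_onsets_s.size == 0:
        raise ValueError("no MAs to validate against")
    ma_sec = np.floor(ma_onsets_s).astype(int)
    ma_sec = ma_sec[(ma_sec >= 0) & (ma_sec < len(period_labels))]
    obs = {
        lab: float((period_labels[ma_sec] == lab).mean())
        for lab in ("fragility", "continuity", "none")
    }

    rng = np.random.default_rng(seed)
    nrems_seconds = np.asarray(nrems_seconds, dtype=int)
    counts = {
        lab: int((period_labels[nrems_seconds] == lab).sum())
        for lab in ("fragility", "continuity")
    }
    null = {lab: np.empty(n_shuffles) for lab in counts}
    ma_set_order = ma_sec
    for s in range(n_shuffles):
        perm = rng.permutation(nrems_seconds)
        pos = 0
        shuffled = np.full(len(period_labels), "none", dtype="<U10")
        for lab in ("fragility", "continuity"):
            shuffled[perm[pos : pos + counts[lab]]] = lab
            pos += counts[lab]
        for lab in counts:
            null[lab][s] = (shuffled[ma_set_order] == lab).mean()
    percentiles = {
        lab: float(100.0 * ((null[lab] < obs[lab]).mean() + 0.5 * (null[lab] == obs[lab]).mean()))
        for lab in counts
    }
    return {"proportions": obs, "null": null, "percentiles": percentiles, "n_ma": len(ma_sec)}


def validate_online_detection_pooled(
    animals: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_shuffles: int = 500,
    seed: int = 0,
) -> dict:
    """Multi-animal shuffle validation of MA capture.

    ``animals`` is a list of ``(period_labels, ma_onsets_s, nrems_seconds)``
    triples.  The observed statistic is the mean across animals of the
    per-animal MA proportion in each online period; the null averages
    per-animal shuffled proportions, preserving each animal's detection
    counts and NREMS pool.  Returns the observed means and their
    percentiles within the null distribution.
    """
    per = [
        validate_online_detection(pl, ma, nr, n_shuffles=n_shuffles, seed=seed + i)
        for i, (pl, ma, nr) in enumerate(animals)
    ]
    out = {}
    for lab in ("fragility", "continuity"):
        obs = float(np.mean([v["proportions"][lab] for v in per]))
        null = np.mean([v["null"][lab] for v in per], axis=0)
        pctl = float(100.0 * ((null < obs).mean() + 0.5 * (null == obs).mean()))
        out[lab] = {"observed_mean": obs, "percentile": pctl, "null_mean": float(null.mean())}
    out["n_ma_total"] = int(sum(v["n_ma"] for v in per))
    out["n_animals"] = len(per)
    return out
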