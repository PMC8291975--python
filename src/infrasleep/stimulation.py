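"""Simulated closed-loop vibration sessions and the automatic
wake-up / sleep-through trial scorer.

The closed loop mirrors the stimulation protocol: when the online detector
reports the target period, it waits 4 s, re-assesses, and — if the
detection persists — delivers a 3-s vibration with 25 % probability.  The
generator's response model decides wake-up vs sleep-through from the *true*
period at stimulus time (wake-ups are more likely in true fragility, and
more likely after SNI) and writes the response into the signals so the
autoscorer sees it.

Trials are scored from three quantities computed on 5-s windows around the
stimulus: (1) the theta/delta ratio before stimulation, (2) the drop in the
low/high-frequency ratio (1-4 Hz over 100-500 Hz) across the stimulus, and
(3) the squared-EMG after/before ratio.  Rejection rules run first (pre
theta/delta > 1, or EMG larger before than after); then a marked low/high
drop together with EMG activity scores a wake-up, with an escape clause for
trials where one channel reacts very strongly while the other changes only
moderately; everything else is a sleep-through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Recording, make_event_table
from .online import OnlineSigmaTracker, OnlineStateMachine, per_second_features
from .synthetic import GroundTruth, SimConfig, true_phase_deg

STIM_DURATION_S = 3.0
GATE_WAIT_S = 4
STIM_PROBABILITY = 0.25


@dataclass
class AutoscoreThresholds:
    """Thresholds for the rule-based trial scorer.

    ``drop`` thresholds apply to ln(pre/post) of the low/high ratio,
    ``emg`` thresholds to the squared-EMG post/pre ratio.  The ``*_hi`` /
    ``*_mild`` pairs implement the escape clause (very strong change in one
    channel with a moderate one in the other).
    """

    drop: float = 0.7
    emg: float = 2.0
    drop_hi: float = 2.0
    emg_mild: float = 1.2
    emg_hi: float = 8.0
    drop_mild: float = 0.2


def _true_period(t: float, cfg: SimConfig) -> str:
    """True period in the online (extremum) convention: fragility is the
    declining, peak-to-trough half-cycle (phase 0-180 deg), continuity the
    rising trough-to-peak half."""
    ph = true_phase_deg(np.array([t]), cfg.infraslow_period_s)[0]
    return "fragility" if ph < 180.0 else "continuity"


def closed_loop_session(
    rec: Recording,
    gt: GroundTruth,
    model,
    thresholds,
    target_period: str = "fragility",
    seed: int = 0,
    refractory_s: float = 30.0,
    response_dur_s: float = 6.0,
) -> tuple[pd.DataFrame, Recording]:
    """Run a closed-loop stimulation session over a synthetic recording.

    Per second: state machine -> sigma tracker -> (buffer full and likely
    NREMS) classifier decision.  A target-period detection at ``t`` that is
    still present at ``t + 4`` s triggers a 3-s stimulus with probability
    0.25.  The generator's response model then decides wake-up vs
    sleep-through from the true infraslow period and condition, and writes
    the response (EEG desynchronization + EMG burst) into a copy of the
    recording starting 0.5 s after stimulus onset.

    Returns the stimulus table (onset_s, duration_s, online period, true
    period, responded flag) and the response-bearing recording.
    """
    if target_period not in ("continuity", "fragility"):
        raise ValueError(f"target_period must be continuity or fragility, got {target_period!r}")
    if model is None:
        raise ValueError("classifier model is untrained/missing")
    cfg = gt.config
    rng = np.random.default_rng(seed)
    rec_out = rec.copy()
    fs = rec.fs
    n = rec.n_samples

    feats = per_second_features(rec)
    n_sec = len(feats)
    sm = OnlineStateMachine(thresholds)
    tracker = OnlineSigmaTracker()

    emg_row = rec.channels.index("EMG")
    eeg_rows = [rec.channels.index(c) for c in rec.channels if c != "EMG"]

    pending = {}  # second -> True, gate re-assessment queue
    last_stim = -np.inf
    rows = []
    for k in range(n_sec):
        state = sm.step(feats["ratio"][k], feats["emg"][k])
        tracker.step(feats["sigma"][k], state)
        decision = "none"
        if tracker.full and state == "N":
            X = np.concatenate(
                [tracker.fitted_curve(), [feats["ratio"][k], feats["emg"][k]]]
            )
            decision = model.predict(X[None, :])[0]

        if k in pending:
            del pending[k]
            if decision == target_period and k - last_stim > refractory_s:
                if rng.random() < STIM_PROBABILITY:
                    t_stim = float(k)
                    last_stim = k
                    true_p = _true_period(t_stim, cfg)
                    p_wake = gt.wakeup_probability(true_p)
                    woke = bool(rng.random() < p_wake)
                    rows.append(
                        {
                            "onset_s": t_stim,
                            "duration_s": STIM_DURATION_S,
                            "online_period": target_period,
                            "true_period": true_p,
                            "woke_up": woke,
                        }
                    )
                    i0 = int((t_stim + 0.5) * fs)
                    i1 = min(n, int((t_stim + 0.5 + response_dur_s) * fs))
                    if woke and i1 > i0:
                        m = i1 - i0
                        # wake-like EEG: drop slow content, add broadband
                        for r in eeg_rows:
                            rec_out.data[r, i0:i1] = 100.0 * (
                                0.35 * _shaped(rng, m, fs, 5.0, 10.0)
                                + 0.30 * rng.standard_normal(m)
                            )
                        rec_out.data[emg_row, i0:i1] = (
                            100.0 * 2.5 * _shaped_hp(rng, m, fs, 25.0)
                        )
                    elif i1 > i0:
                        # sleep-through: brief postural adjustment raises
                        # post-stimulus EMG mildly without cortical change
                        m = i1 - i0
                        pre = rec_out.data[emg_row, max(0, i0 - 5 * int(fs)) : i0]
                        rms = float(np.sqrt(np.mean(pre**2))) if pre.size else 1.0
                        rec_out.data[emg_row, i0:i1] += (
                            0.55 * rms * _shaped_hp(rng, m, fs, 25.0)
                        )
        elif decision == target_period and k - last_stim > refractory_s:
            pending[k + GATE_WAIT_S] = True

    stim = pd.DataFrame(rows, columns=["onset_s", "duration_s", "online_period", "true_period", "woke_up"])
    return stim, rec_out


def _shaped(rng, m, fs, lo, hi):
    from scipy import signal as sps

    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(m))
    return x / x.std()


def _shaped_hp(rng, m, fs, lo):
    from scipy import signal as sps

    sos = sps.butter(4, lo, btype="highpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(m))
    return x / x.std()


def autoscore_trials(
    rec: Recording,
    stimuli: pd.DataFrame,
    thresholds: AutoscoreThresholds | None = None,
    eeg_channel: str = "EEG",
    emg_channel: str = "EMG",
    window_s: float = 5.0,
    high_band: tuple[float, float] = (100.0, 500.0),
    low_band: tuple[float, float] = (1.0, 4.0),
) -> pd.DataFrame:
    """Score every stimulus trial as rejected / wake_up / sleep_through.

    Windows are ``window_s`` before stimulus onset and after stimulus end.
    Requires a sampling rate able to host the high band (fs >= 2x its upper
    edge) — reconfigure ``high_band`` for lower rates.  Trials without full
    margins are dropped with a warning.  Deterministic given thresholds and
    independent of trial order.
    """
    if thresholds is None:
        thresholds = AutoscoreThresholds()
    if rec.fs < 2.0 * high_band[1]:
        raise ValueError(
            f"fs = {rec.fs} Hz cannot resolve the {high_band} Hz band; "
            "reconfigure high_band for lower sampling rates"
        )
    eeg, emg = rec.channel(eeg_channel), rec.channel(emg_channel)
    fs = rec.fs
    n = rec.n_samples

    def band_power(x, lo, hi):
        seg = x - x.mean()
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / fs)
        ps = np.abs(np.fft.rfft(seg)) ** 2
        sel = (freqs >= lo) & (freqs <= hi)
        return ps[sel].mean()

    rows = []
    for tr in stimuli.itertuples():
        t0, dur = tr.onset_s, tr.duration_s
        i_pre0, i_pre1 = int((t0 - window_s) * fs), int(t0 * fs)
        i_post0, i_post1 = int((t0 + dur) * fs), int((t0 + dur + window_s) * fs)
        if i_pre0 < 0 or i_post1 > n:
            import warnings

            warnings.warn(f"trial at {t0} s too close to the recording edge; dropped",
                          stacklevel=2)
            continue
        pre_eeg, post_eeg = eeg[i_pre0:i_pre1], eeg[i_post0:i_post1]
        pre_emg, post_emg = emg[i_pre0:i_pre1], emg[i_post0:i_post1]

        theta_delta = band_power(pre_eeg, 5.0, 10.0) / band_power(pre_eeg, *low_band)
        r_pre = band_power(pre_eeg, *low_band) / band_power(pre_eeg, *high_band)
        r_post = band_power(post_eeg, *low_band) / band_power(post_eeg, *high_band)
        drop = float(np.log(r_pre / r_post))
        emg_ratio = float(np.mean(post_emg**2) / np.mean(pre_emg**2))

        th = thresholds
        if theta_delta > 1.0 or emg_ratio < 1.0:
            verdict = "rejected"
        elif (
            (drop > th.drop and emg_ratio > th.emg)
            or (drop > th.drop_hi and emg_ratio > th.emg_mild)
            or (emg_ratio > th.emg_hi and drop > th.drop_mild)
        ):
            verdict = "wake_up"
        else:
            verdict = "sleep_through"
        rows.append(
            {
                "onset_s": t0,
                "theta_delta_pre": float(theta_delta),
                "lowhigh_drop": drop,
                "emg_ratio": emg_ratio,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(
        rows, columns=["onset_s", "theta_delta_pre", "lowhigh_drop", "emg_ratio", "verdict"]
    )


def calibrate_autoscore_thresholds(
    scores_wake: pd.DataFrame, scores_sleep: pd.DataFrame
) -> AutoscoreThresholds:
    """Equal-error style calibration from labeled synthetic exemplars.

    Sets the primary drop/EMG thresholds at the midpoint between the class
    means of known wake-up and known sleep-through trials.
    """
    drop = 0.5 * (scores_wake["lowhigh_drop"].mean() + scores_sleep["lowhigh_drop"].mean())
    emg = float(
        np.sqrt(scores_wake["emg_ratio"].mean() * max(scores_sleep["emg_ratio"].mean(), 1e-9))
    )
    base = AutoscoreThresholds()
    return AutoscoreThresholds(drop=float(drop), emg=emg, drop_hi=base.drop_hi,
                               emg_mild=base.emg_mild, emg_hi=base.emg_hi,
                               drop_mild=base.drop_mild)


def wakeup_probability(
    scores: pd.DataFrame, period_labels: pd.Series | np.ndarray, zt_bin_h: float | None = None,
    epoch_zt0_s: float = 0.0,
) -> pd.DataFrame:
    """Wake-up probability per period type (and optionally per ZT bin).

    Probability = wake_up / (wake_up + sleep_through); rejected trials are
    excluded.  Cells without scorable trials come back NaN-flagged.
    """
    df = scores.copy()
    df["period"] = np.asarray(period_labels)[: len(df)]
    df = df[df["verdict"] != "rejected"]
    if zt_bin_h is not None:
        df["zt_bin"] = ((df["onset_s"] - epoch_zt0_s) / 3600.0 / zt_bin_h).astype(int)
        keys = ["period", "zt_bin"]
    else:
        keys = ["period"]
    rows = []
    for key, grp in df.groupby(keys):
        wake = int((grp["verdict"] == "wake_up").sum())
        tot = len(grp)
        rows.append(
            dict(
                zip(keys, key if isinstance(key, tuple) else (key,)),
                n_trials=tot,
                p_wakeup=wake / tot if tot else np.nan,
            )
        )
    return pd.DataFrame(rows)
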