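"""Ground-truthed synthetic mouse polysomnography.

Generates Sham and SNI (spared nerve injury, a chronic neuropathic pain
model) recordings whose statistics emulate undisturbed mouse sleep:

- semi-Markov vigilance-state bout alternation quantized to 4-s epochs;
- state-specific EEG spectral content built by noise shaping (band-filtered
  Gaussian noise; only spectral statistics matter downstream, there is no
  biophysics here);
- an NREMS sigma-band (10-15 Hz) component whose *power* envelope follows
  ``1 + m*cos(phase)`` of an infraslow (~0.02 Hz) oscillation, with phase 0
  degrees at the envelope peak and 180 at the trough;
- microarousals (MAs) phase-locked to that fluctuation: each infraslow cycle
  fully contained in an NREMS bout receives at most one MA, with onset phase
  drawn von Mises around the preferred phase 151.6 degrees;
- EMG with state-dependent tone, phasic bursts during MAs, and an additive
  R-peak impulse train at state-dependent heart rates;
- an SNI condition with a tonic beta/low-gamma elevation on the S1HL
  channel, a blunted fragility-period delta surge, and extra "AI-peak"
  local-arousal events (transient delta drop plus 16-40 Hz burst, no EMG
  burst) with a heart-rate transient.

Everything downstream is tested against the ground truth this module emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .core import Hypnogram, Recording, make_event_table

# ---------------------------------------------------------------------------
# configuration


def solve_phase_kappa(mu_deg: float = 151.6, band_mass: float = 0.89) -> float:
    """Concentration kappa of a von Mises at ``mu_deg`` whose probability
    mass on the fragility band [90, 270] degrees equals ``band_mass``.

    With the defaults this gives kappa ~ 2.015.
    """
    mu = np.deg2rad(mu_deg)

    def mass(kappa):
        d = stats.vonmises(kappa, loc=mu)
        lo, hi = np.deg2rad(90.0), np.deg2rad(270.0)
        return d.cdf(hi) - d.cdf(lo)

    return float(optimize.brentq(lambda k: mass(k) - band_mass, 1e-3, 200.0))


_PROB_FIELDS = (
    "modulation_depth",
    "p_ma_per_fragility",
    "p_ai_peak_fragility",
    "wakeup_prob_continuity",
    "wakeup_prob_fragility",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic animal.

    The phase-locking and outcome defaults are the published statistics the
    generator is meant to reproduce (preferred MA phase 151.6 deg, 89 % of
    MA onsets inside [90, 270] deg, 33.6 % of fragility periods containing
    an MA); the remaining defaults are documented generator choices.
    """

    duration_s: float = 3600.0
    fs_signal: float = 1000.0
    fs_sigma: float = 10.0
    epoch_s: float = 4.0

    infraslow_period_s: float = 50.0
    modulation_depth: float = 0.85

    ma_phase_mu_deg: float = 151.6
    ma_phase_kappa: float | None = None  # None -> solved for 89 % band mass
    p_ma_per_fragility: float = 0.336  # P(fragility period contains an MA)

    condition: str = "sham"  # {"sham", "sni"}
    sni_hf_gain: float = 1.5  # tonic 16-40 Hz power multiplier, S1HL
    sni_delta_surge_gain: float = 0.25  # multiplies the fragility delta surge
    p_ai_peak_fragility: float | None = None  # None -> per-condition default
    delta_surge_amp: float = 0.6  # Sham fragility-period delta power surge

    hr_nrems_hz: float = 10.0
    hr_rems_hz: float = 11.0
    hr_wake_hz: float = 12.0
    hr_ai_transient_hz: float = 2.5

    wakeup_prob_continuity: float = 0.45
    wakeup_prob_fragility: float = 0.75
    sni_wakeup_boost: float = 0.17  # additive, capped at 0.97

    # bout-structure parameters (semi-Markov, seconds)
    wake_bout_mean_s: float = 80.0
    nrems_bout_mean_s: float = 320.0
    rems_bout_mean_s: float = 70.0
    p_rems_after_nrems: float = 0.3

    only_state: str | None = None  # e.g. "N": single-bout hypnogram
    seed: int = 0

    # per-condition default AI-peak probabilities
    _P_AI_DEFAULT = {"sham": 0.10, "sni": 0.28}

    def __post_init__(self):
        if self.ma_phase_kappa is None:
            self.ma_phase_kappa = solve_phase_kappa(self.ma_phase_mu_deg)
        if self.p_ai_peak_fragility is None:
            if self.condition in self._P_AI_DEFAULT:
                self.p_ai_peak_fragility = self._P_AI_DEFAULT[self.condition]
        self.validate()

    def validate(self):
        if self.condition not in ("sham", "sni"):
            raise ValueError(f"condition must be 'sham' or 'sni', got {self.condition!r}")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.infraslow_period_s <= 40.0:
            raise ValueError(
                "infraslow_period_s must exceed 40 s so the >20 s cycle-detection "
                f"separation rule is satisfiable, got {self.infraslow_period_s}"
            )
        # highest deterministically synthesized band edge is the 120 Hz
        # R-peak carrier; everything EEG-shaped tops out at 40 Hz
        if self.fs_signal < 250.0:
            raise ValueError(f"fs_signal must be >= 250 Hz, got {self.fs_signal}")
        if self.duration_s <= 0 or self.epoch_s <= 0 or self.fs_sigma <= 0:
            raise ValueError("duration_s, epoch_s and fs_sigma must be positive")
        if self.only_state is not None and self.only_state not in ("W", "N", "R"):
            raise ValueError(f"only_state must be one of W/N/R, got {self.only_state!r}")

    @property
    def ma_band_mass(self) -> float:
        """von Mises mass on [90, 270] deg under the configured mu/kappa."""
        d = stats.vonmises(self.ma_phase_kappa, loc=np.deg2rad(self.ma_phase_mu_deg))
        return float(d.cdf(np.deg2rad(270.0)) - d.cdf(np.deg2rad(90.0)))


_FIELD_NAMES = None


def build_sim_config(overrides: dict | None = None, **kw) -> SimConfig:
    """Build a validated :class:`SimConfig` from default values plus overrides.

    Unknown keys and invariant violations raise ``ValueError``.
    """
    global _FIELD_NAMES
    if _FIELD_NAMES is None:
        _FIELD_NAMES = {f.name for f in fields(SimConfig)}
    merged = dict(overrides or {})
    merged.update(kw)
    unknown = set(merged) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**merged)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: SimConfig
    bouts: pd.DataFrame  # state, start_s, end_s (tile the recording)
    phase_deg: np.ndarray  # true infraslow phase at fs_sigma
    cycles: pd.DataFrame  # full infraslow cycles inside NREMS bouts
    ma_events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["onset_s", "duration_s", "phase_deg", "cycle"]
        )
    )
    ai_events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["onset_s", "duration_s", "cycle"])
    )
    rpeak_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def wakeup_probability(self, period: str) -> float:
        cfg = self.config
        p = (
            cfg.wakeup_prob_fragility
            if period == "fragility"
            else cfg.wakeup_prob_continuity
        )
        if cfg.condition == "sni":
            p = min(0.97, p + cfg.sni_wakeup_boost)
        return p


def true_phase_deg(t_s: np.ndarray, period_s: float) -> np.ndarray:
    """Global infraslow phase: 0 deg at envelope peaks (t = k*period)."""
    return (360.0 * np.asarray(t_s, dtype=float) / period_s) % 360.0


# ---------------------------------------------------------------------------
# hypnogram


def _draw_bout_s(rng, mean_s, lo, hi):
    return float(np.clip(rng.gamma(2.0, mean_s / 2.0), lo, hi))


def simulate_hypnogram(cfg: SimConfig, seed=None) -> tuple[Hypnogram, GroundTruth]:
    """Semi-Markov Wake -> NREMS -> {Wake | REMS} -> Wake alternation.

    NREMS bout durations are drawn long enough that several uninterrupted
    infraslow cycles occur per bout.  Labels are quantized to 4-s epochs and
    the bout list tiles the recording exactly.
    """
    if cfg.duration_s < 3 * cfg.infraslow_period_s:
        raise ValueError(
            f"duration_s must cover at least three infraslow periods "
            f"({3 * cfg.infraslow_period_s:.0f} s), got {cfg.duration_s}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_epochs = int(round(cfg.duration_s / cfg.epoch_s))

    if cfg.only_state is not None:
        labels = np.full(n_epochs, cfg.only_state, dtype="<U1")
    else:
        labels = np.empty(n_epochs, dtype="<U1")
        pos = 0
        state = "W"
        first_wake = True
        while pos < n_epochs:
            if state == "W":
                # short first wake bout so sleep onset happens early
                mean = 40.0 if first_wake else cfg.wake_bout_mean_s
                first_wake = False
                dur = _draw_bout_s(rng, mean, 20.0, 240.0)
                nxt = "N"
            elif state == "N":
                dur = _draw_bout_s(
                    rng, cfg.nrems_bout_mean_s, max(160.0, 3.2 * cfg.infraslow_period_s), 640.0
                )
                nxt = "R" if rng.random() < cfg.p_rems_after_nrems else "W"
            else:  # REMS
                dur = _draw_bout_s(rng, cfg.rems_bout_mean_s, 40.0, 120.0)
                nxt = "W"
            n_ep = max(1, int(round(dur / cfg.epoch_s)))
            labels[pos : pos + n_ep] = state
            pos += n_ep
            state = nxt

    hyp = Hypnogram(labels, epoch_s=cfg.epoch_s)
    gt = _ground_truth_from_hypnogram(hyp, cfg)
    return hyp, gt


def _ground_truth_from_hypnogram(hyp: Hypnogram, cfg: SimConfig) -> GroundTruth:
    runs = hyp.runs()
    bouts = pd.DataFrame(
        {
            "state": runs["state"],
            "start_s": runs["start_epoch"] * cfg.epoch_s,
            "end_s": (runs["start_epoch"] + runs["n_epochs"]) * cfg.epoch_s,
        }
    )
    n10 = int(round(hyp.duration_s * cfg.fs_sigma))
    t10 = np.arange(n10) / cfg.fs_sigma
    phase = true_phase_deg(t10, cfg.infraslow_period_s)

    T = cfg.infraslow_period_s
    rows = []
    for run_id, b in bouts[bouts["state"] == "N"].iterrows():
        # every infraslow unit whose fragility window [T/4, 3T/4] lies
        # inside the bout can host an MA (the unit's nominal start k*T may
        # precede the bout start by up to a quarter period); the final unit
        # may be 'terminal': its cycle completes only after the bout ends
        k0 = int(np.ceil((b.start_s - T / 4.0) / T))
        k1 = int(np.floor((b.end_s - 3.0 * T / 4.0) / T))
        for k in range(k0, k1 + 1):
            rows.append(
                {
                    "bout": run_id,
                    "t_start": k * T,
                    "t_end": (k + 1) * T,
                    "frag_start": k * T + T / 4.0,
                    "frag_end": k * T + 3.0 * T / 4.0,
                    "terminal": (k + 1) * T > b.end_s,
                    "has_ma": False,
                    "has_ai_peak": False,
                }
            )
    cycles = pd.DataFrame(
        rows,
        columns=[
            "bout", "t_start", "t_end", "frag_start", "frag_end",
            "terminal", "has_ma", "has_ai_peak",
        ],
    )
    return GroundTruth(config=cfg, bouts=bouts, phase_deg=phase, cycles=cycles)


# ---------------------------------------------------------------------------
# microarousals


def place_microarousals(hyp: Hypnogram, gt: GroundTruth, cfg: SimConfig, seed=None) -> pd.DataFrame:
    """Place phase-locked MAs and relabel the covered epochs in ``hyp``.

    Each full infraslow cycle inside an NREMS bout receives, with probability
    ``p_ma_per_fragility / mass([90, 270])``, one MA whose onset phase is a
    von Mises draw; the scaling makes ``p_ma_per_fragility`` the probability
    that the cycle's *fragility period* contains an MA onset.  Durations are
    uniform on [4, 16] s.  Modifies ``hyp`` in place (epochs whose start lies
    inside the MA window are relabeled ``M``) and records the events in
    ``gt``; returns the event table.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    q = min(1.0, cfg.p_ma_per_fragility / cfg.ma_band_mass)
    mu = np.deg2rad(cfg.ma_phase_mu_deg)
    T = cfg.infraslow_period_s

    onsets, durs, phases, cyc_idx = [], [], [], []
    bout_start = dict(gt.bouts["start_s"])
    bout_end = dict(gt.bouts["end_s"])
    for i, cyc in gt.cycles.iterrows():
        if rng.random() >= q:
            continue
        alpha = float(np.rad2deg(rng.vonmises(mu, cfg.ma_phase_kappa)) % 360.0)
        onset = cyc.t_start + alpha / 360.0 * T
        run_end = bout_end[cyc.bout]
        if onset < bout_start[cyc.bout] or run_end - onset < 2.0:
            continue
        dur = float(rng.uniform(4.0, 16.0))
        first = int(np.ceil(onset / cfg.epoch_s - 1e-9))
        last = int(np.ceil((min(onset + dur, run_end)) / cfg.epoch_s - 1e-9))
        ep = np.arange(first, min(last, hyp.n_epochs))
        ep = ep[hyp.labels[ep] == "N"]
        if ep.size == 0:
            continue
        hyp.labels[ep] = "M"
        onsets.append(onset)
        durs.append(dur)
        phases.append(alpha)
        cyc_idx.append(i)

    gt.ma_events = pd.DataFrame(
        {"onset_s": onsets, "duration_s": durs, "phase_deg": phases, "cycle": cyc_idx}
    )
    in_band = [(90.0 <= a <= 270.0) for a in phases]
    gt.cycles.loc[[c for c, b in zip(cyc_idx, in_band) if b], "has_ma"] = True
    return make_event_table(onsets, durs, ["MA"] * len(onsets))


def _place_ai_events(gt: GroundTruth, cfg: SimConfig, rng) -> None:
    """SNI/Sham local-arousal events in MA-free fragility periods."""
    p = cfg.p_ai_peak_fragility or 0.0
    rows = []
    for i, cyc in gt.cycles.iterrows():
        if cyc.has_ma or rng.random() >= p:
            continue
        onset = float(rng.uniform(cyc.frag_start + 2.0, cyc.frag_end - 8.0))
        rows.append({"onset_s": onset, "duration_s": 6.0, "cycle": i})
        gt.cycles.loc[i, "has_ai_peak"] = True
    gt.ai_events = pd.DataFrame(rows, columns=["onset_s", "duration_s", "cycle"])


# ---------------------------------------------------------------------------
# signals

# amplitude gains per state for the shaped-noise components
_GAINS = {
    #        W      N      R      M
    "delta": {"W": 0.30, "N": 1.00, "R": 0.15, "M": 0.30},
    "theta": {"W": 0.80, "N": 0.18, "R": 1.00, "M": 0.25},
    # MAs keep the NREMS sigma envelope: desynchronization is expressed in
    # delta/theta/HF and EMG, so the infraslow sigma trace stays unbiased
    "sigma": {"W": 0.71, "N": 1.00, "R": 0.63, "M": 1.00},
    "hf": {"W": 0.35, "N": 0.18, "R": 0.22, "M": 0.50},
    "broad": {"W": 0.12, "N": 0.05, "R": 0.08, "M": 0.15},
}
_EMG_TONE = {"W": 1.0, "N": 0.25, "R": 0.12, "M": 2.5}
_EEG_SCALE_UV = 100.0
_RPEAK_REL_AMP = 12.0  # R-peak amplitude relative to the local EMG tone
_RPEAK_CARRIER_HZ = 120.0
_RPEAK_WIDTH_S = 0.008
_IBI_JITTER = 0.04
_IBI_FLOOR_S = 0.06


def _ar1(rng, n, rho):
    """Unit-variance AR(1) series (smooth random wander)."""
    e = rng.standard_normal(n) * np.sqrt(1.0 - rho**2)
    out = np.empty(n)
    acc = rng.standard_normal()
    for i in range(n):
        acc = rho * acc + e[i]
        out[i] = acc
    return out


def _band_noise(rng, n, fs, lo, hi):
    """Unit-variance band-limited Gaussian noise (gains stay interpretable
    as relative amplitudes across components)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return (x / x.std()).astype(np.float32)


def _state_gain(lab, table):
    g = np.empty(lab.size, dtype=np.float32)
    for s, v in table.items():
        g[lab == s] = v
    return g


def synthesize_signals(
    hyp: Hypnogram, gt: GroundTruth, cfg: SimConfig, seed=None
) -> Recording:
    """Noise-shaped EEG / S1HL-LFP / EMG signals consistent with ``hyp``/``gt``.

    The S1HL channel carries the condition-specific manipulations (tonic
    16-40 Hz gain in wake and NREMS, blunted delta surge, AI-peak events);
    the EEG channel is the unmanipulated contralateral reference.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    fs = cfg.fs_signal
    n = int(round(cfg.duration_s * fs))
    if abs(hyp.duration_s - cfg.duration_s) > cfg.epoch_s:
        raise ValueError(
            f"hypnogram covers {hyp.duration_s} s but config requests {cfg.duration_s} s"
        )
    lab = hyp.sample_labels(fs, n)
    t = np.arange(n, dtype=np.float64) / fs
    phase = true_phase_deg(t, cfg.infraslow_period_s)
    cosph = np.cos(np.deg2rad(phase)).astype(np.float32)

    if cfg.condition == "sni" or (cfg.p_ai_peak_fragility or 0.0) > 0:
        _place_ai_events(gt, cfg, rng)

    nrems_like = (lab == "N") | (lab == "M")

    def eeg_like(is_lfp: bool) -> np.ndarray:
        g_delta = _state_gain(lab, _GAINS["delta"])
        g_theta = _state_gain(lab, _GAINS["theta"])
        g_sigma = _state_gain(lab, _GAINS["sigma"])
        g_hf = _state_gain(lab, _GAINS["hf"])
        g_broad = _state_gain(lab, _GAINS["broad"])

        # sinusoidal sigma *power* envelope in NREMS (and, attenuated, in MAs)
        env = np.sqrt(np.clip(1.0 + cfg.modulation_depth * cosph, 0.0, None))
        g_sigma = np.where(nrems_like, g_sigma * env, g_sigma)

        # fragility-period delta surge (Sham); blunted after SNI on S1HL
        surge_amp = cfg.delta_surge_amp
        if is_lfp and cfg.condition == "sni":
            surge_amp *= cfg.sni_delta_surge_gain
        u = np.sin(np.deg2rad(phase) / 2.0) ** 2
        surge = np.sqrt(1.0 + surge_amp * u).astype(np.float32)
        g_delta = np.where(lab == "N", g_delta * surge, g_delta)

        if is_lfp and cfg.condition == "sni":
            boost = np.sqrt(cfg.sni_hf_gain)
            g_hf = np.where((lab == "N") | (lab == "W") | (lab == "M"), g_hf * boost, g_hf)

        if is_lfp and len(gt.ai_events):
            for ev in gt.ai_events.itertuples():
                i0 = int(ev.onset_s * fs)
                i1 = min(n, int((ev.onset_s + ev.duration_s) * fs))
                g_delta[i0:i1] *= 0.35
                g_hf[i0:i1] *= 2.5

        # spindle-band activity is an oscillatory carrier (slowly wandering
        # 11.5-13.5 Hz instantaneous frequency), not band noise: its wavelet
        # power then tracks the imposed envelope with little variance, as
        # real spindle-band power tracks spindle density
        f_inst = 12.5 + 0.8 * _ar1(rng, int(np.ceil(n / (fs / 10.0))), 0.9)
        f_inst = np.repeat(f_inst, int(fs / 10.0))[:n]
        carrier = np.sqrt(2.0) * np.cos(
            2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
        ).astype(np.float32)

        x = g_delta * _band_noise(rng, n, fs, 1.0, 4.0)
        x += g_theta * _band_noise(rng, n, fs, 5.0, 10.0)
        x += g_sigma * carrier
        x += g_hf * _band_noise(rng, n, fs, 16.0, 40.0)
        x += g_broad * rng.standard_normal(n).astype(np.float32)
        return (x * _EEG_SCALE_UV).astype(np.float64)

    eeg = eeg_like(is_lfp=False)
    s1hl = eeg_like(is_lfp=True)

    # ---- EMG: tone * highpassed noise + R-peak train -----------------------
    tone = _state_gain(lab, _EMG_TONE)
    # slow per-epoch wake-tone modulation so QW and AW both occur
    log_l, per = 0.0, int(round(cfg.epoch_s * fs))
    n_ep = hyp.n_epochs
    wake_factor = np.ones(n_ep)
    for k in range(n_ep):
        log_l = 0.85 * log_l + 0.55 * rng.standard_normal()
        wake_factor[k] = np.exp(np.clip(log_l, -1.2, 1.2))
    wf = np.repeat(wake_factor, per)[:n]
    if len(wf) < n:
        wf = np.concatenate([wf, np.full(n - len(wf), wf[-1])])
    tone = np.where(lab == "W", tone * wf.astype(np.float32), tone)

    hp = signal.butter(4, 25.0, btype="highpass", fs=fs, output="sos")
    hp_noise = signal.sosfiltfilt(hp, rng.standard_normal(n))
    emg = tone * (hp_noise / hp_noise.std()).astype(np.float32)

    rate = np.full(n, cfg.hr_wake_hz)
    rate[lab == "N"] = cfg.hr_nrems_hz
    rate[lab == "R"] = cfg.hr_rems_hz
    for ev in gt.ai_events.itertuples():
        i0 = int(ev.onset_s * fs)
        i1 = min(n, int((ev.onset_s + ev.duration_s + 2.0) * fs))
        rate[i0:i1] += cfg.hr_ai_transient_hz

    rtimes = []
    tt = float(rng.uniform(0.0, 0.1))
    while tt < cfg.duration_s:
        r = rate[min(n - 1, int(tt * fs))]
        ibi = max(_IBI_FLOOR_S, (1.0 / r) * (1.0 + _IBI_JITTER * rng.standard_normal()))
        rtimes.append(tt)
        tt += ibi
    rtimes = np.asarray(rtimes)
    gt.rpeak_times = rtimes

    nk = max(4, int(_RPEAK_WIDTH_S * fs))
    tk = np.arange(nk) / fs
    kernel = np.hanning(nk) * np.cos(2 * np.pi * _RPEAK_CARRIER_HZ * (tk - _RPEAK_WIDTH_S / 2))
    emg = np.asarray(emg, dtype=np.float64)
    for rt in rtimes:
        i0 = int(rt * fs)
        if i0 + nk > n:
            break
        emg[i0 : i0 + nk] += _RPEAK_REL_AMP * tone[i0] * kernel
    emg *= _EEG_SCALE_UV

    return Recording(
        np.vstack([eeg, s1hl, emg]),
        fs,
        channels=["EEG", "S1HL", "EMG"],
        roles={"EEG": "eeg", "S1HL": "lfp", "EMG": "emg"},
    )


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SimResult:
    recording: Recording
    hypnogram: Hypnogram
    events: pd.DataFrame
    ground_truth: GroundTruth
    config: SimConfig


def simulate_recording(cfg: SimConfig | None = None, seed=None, **overrides) -> SimResult:
    """Full synthetic animal: hypnogram, MAs, signals, ground truth.

    ``seed`` (falls back to ``cfg.seed``) is split into independent
    substreams for the three stochastic stages, so the result is
    bit-reproducible for a given (config, seed) pair.
    """
    if cfg is None:
        cfg = build_sim_config(overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    root = int(cfg.seed if seed is None else seed)
    s_hyp, s_ma, s_sig = np.random.SeedSequence(root).spawn(3)
    hyp, gt = simulate_hypnogram(cfg, seed=s_hyp)
    events = place_microarousals(hyp, gt, cfg, seed=s_ma)
    rec = synthesize_signals(hyp, gt, cfg, seed=s_sig)
    return SimResult(rec, hyp, events, gt, cfg)
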