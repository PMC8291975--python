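# Methods

## The measurement chain

Sigma-band power is extracted with a complex Morlet wavelet (four cycles,
L2-normalized mother wavelet) at center frequencies 10–15 Hz in 0.5 Hz
steps; the squared coefficient magnitudes are averaged across centers and
block-averaged down to 10 Hz. The resulting trace is smoothed with a
linear-phase windowed-sinc FIR low-pass (Hamming window, order 100 at
10 Hz sampling, cutoff 0.0125 Hz) applied forward–backward, so the filter
is exactly zero-phase. The low order is deliberate: at 101 taps the
truncated sinc behaves almost like a 10-s boxcar, passing the ~0.02 Hz
fluctuation nearly unattenuated while removing spindle-scale jitter.
The trace is normalized by its mean over NREMS and microarousal (MA)
samples, making every later statistic invariant to amplifier gain.

The infraslow phase is the analytic-signal angle of the mean-subtracted
smoothed trace, mapped to [0°, 360°) so that a cosine's maxima read 0° and
its minima 180°, increasing through the cycle. The Hilbert transform is
computed once over the whole recording and consumed only on NREMS∪MA
samples: per-bout transforms would put an edge transient at every bout
border exactly where phase accuracy matters. The residual cost of the
global transform is a distortion near bout borders (the trace steps
between the NREMS oscillation and the lower wake/REMS sigma level), which
widens the phase spread of bout-edge extrema; away from borders the phase
error of the chain on noise-free input is well under a degree.

Cycles are detected on the smoothed trace: candidate peaks must exceed and
troughs undercut the mask mean, same-type extrema must be separated by
more than 20 s (ties and plateaus resolve to the plateau midpoint), and a
trough–peak–trough triplet is kept only when its whole peak-to-peak span
lies inside one NREMS∪MA run; runs shorter than 40 s cannot satisfy two
separations and are skipped. The fragility span of a cycle is the subset
of its samples with phase in [90°, 270°), the continuity span the
complement.

Fragility-period outcomes are three-way: *MA* when an MA onset with
in-band phase falls inside the span, *REMS-transition*, or
*NREMS-continuing*. Because a complete trough–peak–trough cycle can never
end in REMS, each NREMS run's final detected peak contributes one terminal
fragility period: if the phase completes the 90–270° span inside the run
it is an ordinary period (MA or continuing); if the run ends mid-span and
REMS follows within 1.5 nominal periods it counts as a REMS transition
(an in-band MA onset takes priority); spans truncated by wake are not
counted — brief awakenings are MAs by definition, and longer ones end the
bout outside this three-way taxonomy.

The bout-averaged infraslow spectrum takes, per NREMS∪MA run of at least
100 s, the periodogram of the mean-subtracted normalized trace, keeps
0–0.5 Hz, interpolates linearly onto a common 201-point grid and averages;
the peak search excludes the DC-adjacent bins below 0.005 Hz. Linear
interpolation onto the grid is a documented choice; at these smooth
spectra the scheme is immaterial.

Epoch spectra use a single-taper periodogram on each mean-subtracted 4-s
epoch (0.25 Hz bins). Sleep spectra are per-state medians over epochs not
adjacent to a state transition (an epoch is transition-adjacent when its
predecessor or successor carries a different label), divided by one
constant: the average across states of each state's mean 0.75–47 Hz
power, so every state weighs equally. Wake spectra are per-set means with
each bin divided by the summed 2–30 Hz power. Quiet/active wakefulness is
segmented per animal on the natural log of the per-epoch squared EMG:
quiet wake spans the 10th–25th percentile (runs of ≥3 consecutive epochs
only, >12 s), active wake the 50th–99th; the 25–50 band is unassigned by
design. Percentiles are linear-interpolation quantiles.

Band-power traces for the activation index (AI) use the same wavelet
path (delta 1–4 Hz at 0.5 Hz steps; beta 16–25 and low-gamma 26–40 Hz at
1 Hz steps) and are normalized by a single constant — the sum of the band
means over NREMS — which preserves cross-band ratios, so the AI
ln((P_beta + P_low-gamma)/P_delta) is unaffected by the normalization.
The AI is smoothed with a 2-s moving average: wavelet power at 10 Hz is
approximately chi-square distributed per sample and the arousal events of
interest last seconds. AI peaks are local maxima within a cycle's
fragility span exceeding that cycle's mean AI; a candidate must
additionally have a prominence of at least 1.5 ln-units. The prominence
floor is required because the AI passes smoothly through its cycle mean
near the 90°/270° span edges, where estimator noise (σ ≈ 0.8 ln-units)
otherwise always produces a qualifying local maximum; 1.5 is the
equal-error point between MA-driven peaks (median prominence ≈ 2.3) and
noise-only fragility spans (95th percentile ≈ 1.8) measured on labeled
synthetic data. Peaks whose maximum lies inside the span count; partial
overlap of a peak's flanks with the edges does not.

Heart rate comes from the EMG: high-pass above 25 Hz, squared, smoothed
over 10 ms, and peak-picked against an adaptive threshold (per-1-s-block
median + 8×MAD, hence gain-invariant) with a 50 ms refractory floor on
inter-beat intervals; instantaneous rate is 60/IBI, held between beats.
The 1-s threshold blocks matter: longer blocks straddle state transitions
and mask low-tone beats next to high-tone wakefulness.

## The online detector

Every second, the delta/theta power ratio of the mean-centered last 4 s
of EEG and the EMG power of the current second feed a rule-based
likely-state machine (thresholded transitions out of wake, NREMS and REMS
over 3–5 s buffers). Thresholds are auto-calibrated per recording from
state-conditional feature distributions (EMG high threshold = 75th
percentile of wake EMG power; ratio thresholds at geometric midpoints of
the state medians), over the first 10 min by default, falling back to the
whole recording when a state is missing from the window. Sigma power per
second (periodogram of the same 4-s window) is normalized by a running
mean over likely-NREMS seconds; the last 200 s are kept regardless of
state and summarized by a ninth-order polynomial fit (domain scaled to
[-1, 1] for conditioning; an all-equal buffer yields a flat curve). A
ninth-order polynomial cannot follow four full 0.02 Hz cycles exactly
(direct fit r ≈ 0.69; r > 0.99 at 1.5 cycles) — it is a smoothing feature
transform, not an interpolant, and the classifier does not require more.

The continuity/fragility classifier is a feed-forward network with one
10-unit hidden layer and three outputs (continuity, fragility, none),
trained on 200-s moving-window chunks (one per second; features = the 200
fitted sigma samples + the current ratio and EMG power; labels from
offline cycle detection, continuity = trough→peak, fragility =
peak→trough) with a seeded 70/15/15 split behind a standardizing scaler.
Validation uses a shuffle null: detected fragility/continuity seconds are
repositioned uniformly within the recording's NREMS seconds, preserving
counts; multi-animal validation averages per-animal proportions against
per-animal nulls. Note the online taxonomy is extremum-based (fragility =
the full declining half-cycle, 0–180°), while MA phase statistics use the
90–270° band; an MA at, say, 200° is past the trough and legitimately
falls in online continuity, which is why MA-capture proportions beat the
null by margins rather than approaching 1.

## Closed-loop stimulation and trial scoring

When the online decision reports the target period and still reports it
4 s later, a 3-s vibration is delivered with probability 0.25 (30 s
refractory). The generator's response model decides wake-up vs
sleep-through from the true period in the online convention — wake-up
probability 0.75 in true fragility and 0.45 in continuity for Sham, +0.17
after SNI — and writes the response into the signals (wake-like EEG with
an EMG burst for wake-ups; a mild post-stimulus EMG elevation without
cortical change for sleep-throughs, the postural-adjustment artifact that
keeps the after/before EMG comparison from being a coin flip).

Trials are scored from 5-s windows before stimulus onset and after
stimulus end: rejection first (pre theta/delta > 1, or post EMG power
below pre), then wake-up when the log drop of the low/high ratio
(1–4 Hz over 100–500 Hz) exceeds 0.7 together with a squared-EMG
after/before ratio above 2, with an escape clause for one channel
reacting very strongly (drop > 2 with EMG ratio > 1.2, or EMG ratio > 8
with drop > 0.2); otherwise sleep-through. The defaults were calibrated
as midpoints between labeled synthetic wake-up and sleep-through
exemplars and a calibration helper re-derives them for other data. The
100–500 Hz band requires a sampling rate of at least 1 kHz; the scorer
refuses lower rates unless the band is reconfigured.

## The synthetic generator

The generator emulates statistics, not biophysics. Vigilance states
follow a semi-Markov alternation Wake → NREMS → {Wake | REMS} → Wake with
gamma-distributed bout durations (means 80 / 320 / 70 s, clipped; REMS
follows NREMS with probability 0.3), quantized to 4-s epochs; sessions
default to 3600 s at 1000 Hz. EEG-like channels are sums of
unit-variance band-shaped Gaussian noise (delta, theta, 16–40 Hz,
broadband floor) with state-dependent gains, except the spindle band,
which is an amplitude-modulated oscillatory carrier with a slowly
wandering 11.5–13.5 Hz instantaneous frequency — spindle-band activity is
oscillatory, and a carrier makes the wavelet power track the imposed
envelope with little estimator variance, which is what makes the phase of
the fluctuation a recoverable ground truth. The carrier's amplitude in
NREMS is √(1 + m·cos φ) with modulation depth m = 0.85 and global phase
φ = 360°·t/T (T = 50 s), so the *power* envelope is exactly sinusoidal; a
(1 + m·cos φ)² power envelope would carry a second harmonic that biases
Hilbert phase by ~5° at the MA preferred phase. Wake and REMS keep sigma
floors of ~0.5 and ~0.4 of the NREMS mean (the realistic 2–3× contrast),
which also limits Hilbert edge distortion at bout borders. The delta gain
in NREMS carries a fragility-period surge, 1 + 0.6·sin²(φ/2) in power.

MAs: every infraslow unit whose fragility window [T/4, 3T/4] lies inside
an NREMS bout receives, with probability p/mass₉₀₋₂₇₀ (p = 0.336,
mass ≈ 0.89), one MA whose onset phase is a von Mises draw with
μ = 151.6° and κ ≈ 2.015, κ solved so the von Mises mass on [90°, 270°]
is exactly 0.89. The division makes p the probability that a fragility
period contains an in-band MA — the statistic it is named for. Durations
are uniform on [4, 16] s; epochs whose start falls inside the MA window
are relabeled. MAs desynchronize the EEG through a delta drop and an HF
rise plus an EMG burst; the sigma envelope is deliberately left intact
during the (≤16 s) MA so the infraslow trace measurement stays unbiased —
a documented departure from full realism (real MAs also depress sigma).

EMG is high-passed unit-variance noise scaled by a state tone (wake tone
wanders log-AR(1) across epochs so quiet and active wakefulness both
occur) plus an additive R-peak train: 8-ms Hann-windowed 120 Hz bursts at
state-dependent rates (NREMS 10, REMS 11, Wake 12 beats/s — configuration
choices; mouse heart rate ~600 bpm — with 4% IBI jitter and a 60 ms
floor), amplitude 12× the local tone so R peaks are unambiguous, matching
the practice of analyzing only animals with clearly visible R peaks.

SNI (applied to the S1HL channel only; the EEG channel is the
unmanipulated contralateral reference): 16–40 Hz power ×1.5 in NREMS and
wake, delta-surge amplitude ×0.25, AI-peak events (6-s transients with
delta ×0.35 and HF ×2.5 in power, no EMG change, heart rate +2.5 beats/s)
in 28% of MA-free fragility periods versus 10% for Sham, and +0.17
wake-up probability in the stimulation response model.

What the generator does not emulate: biophysical waveforms, movement and
chewing artifacts, electrode drift, spindle discreteness (the envelope is
continuous), state-transition dynamics (gains switch per epoch), circadian
modulation within a session, and vibration-motor physics. Passing tests
therefore demonstrate that the measurement chain recovers known
parameters under realistic spectral statistics and bout structure — not
robustness to every artifact of real recordings.

## Problem sizes and determinism

Desk-scale defaults keep everything on one CPU: single sessions of 3600 s
at 1 kHz; the phase-recovery cohort uses 30 such animals (≈580 MAs);
online validation pools ten held-out animals against a 400-draw shuffle
null; the stimulation contrast uses two animals per condition and target.
Full 12-h sessions are available through the configuration. All
randomness flows from integer seeds through split substreams
(hypnogram / MA placement / signals), so identical configuration and seed
reproduce bit-identical recordings, and training, closed-loop sessions
and shuffle nulls are seeded likewise.

## Known limitations

- The circular-mean CI uses the standard dispersion-based construction;
  it is undefined (flagged NaN) for nearly uniform samples, and the
  Rayleigh p uses the large-sample series, rough below n ≈ 10.
- EDF export writes plain 16-bit EDF with equal per-channel rates and 1-s
  records; round trips are exact for labels and within one quantization
  step for signals, but EDF+ annotations are not supported.
- The online state machine implements fixed threshold rules; its accuracy
  (≈90–95% per-second agreement on synthetic data, MA seconds excluded)
  depends on the calibration window containing wake and NREMS.
- Terminal fragility periods truncated by wake are excluded from outcome
  proportions; a taxonomy with a wake-transition class would need a
  different denominator.
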