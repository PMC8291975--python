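"""Shared containers for multichannel polysomnography analysis.

A recording is a plain channels-by-samples matrix with a sampling rate and
per-channel roles (``eeg``, ``lfp``, ``emg``).  Vigilance states follow the
standard mouse 4-s-epoch scoring convention with four labels:

- ``W`` wakefulness
- ``N`` non-rapid eye movement sleep (NREMS)
- ``R`` rapid eye movement sleep (REMS)
- ``M`` microarousal (brief, <=16 s awakening interrupting NREMS)

Event tables are ordinary :class:`pandas.DataFrame` objects with the columns
``onset_s, duration_s, type, channel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATES = ("W", "N", "R", "M")
#: states whose samples belong to consolidated NREMS for sigma-trace purposes
NREMS_LIKE = ("N", "M")

EVENT_COLUMNS = ["onset_s", "duration_s", "type", "channel"]


def make_event_table(onsets=(), durations=(), types=(), channels=None) -> pd.DataFrame:
    """Build an event table; empty call returns an empty, correctly typed table."""
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    types = list(types)
    if channels is None:
        channels = [""] * len(onsets)
    df = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": durations,
            "type": types,
            "channel": list(channels),
        }
    )
    return df[EVENT_COLUMNS]


@dataclass
class Recording:
    """Multichannel signal matrix.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Channel names, one per row of ``data``.
    roles
        Mapping channel name -> role in ``{"eeg", "lfp", "emg"}``.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} signal rows but {len(self.channels)} channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        return self.data[idx]

    def channels_with_role(self, role: str) -> list[str]:
        return [c for c in self.channels if self.roles.get(c) == role]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channels), dict(self.roles))


@dataclass
class Hypnogram:
    """Sequence of fixed-length epoch labels with a Zeitgeber-time origin.

    ``zt0_s`` is the recording time (s) at which ZT0 (lights on) occurred;
    recordings that start at lights-on have ``zt0_s = 0``.
    """

    labels: np.ndarray
    epoch_s: float = 4.0
    zt0_s: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype="<U1")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels {sorted(bad)}; allowed {STATES}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def epoch_times(self) -> np.ndarray:
        """Start time (s) of each epoch."""
        return np.arange(self.n_epochs) * self.epoch_s

    def zt_hours(self) -> np.ndarray:
        """Zeitgeber time (h) at each epoch start."""
        return (self.epoch_times() - self.zt0_s) / 3600.0

    def state_at(self, t: float) -> str:
        idx = int(t // self.epoch_s)
        if not 0 <= idx < self.n_epochs:
            raise IndexError(f"time {t} s outside recording")
        return self.labels[idx]

    def sample_labels(self, fs: float, n_samples: int | None = None) -> np.ndarray:
        """Per-sample labels at sampling rate ``fs``."""
        per = int(round(self.epoch_s * fs))
        out = np.repeat(self.labels, per)
        if n_samples is not None:
            if n_samples > len(out):
                out = np.concatenate([out, np.full(n_samples - len(out), out[-1])])
            out = out[:n_samples]
        return out

    def runs(self) -> pd.DataFrame:
        """Maximal runs of one label: columns state, start_epoch, n_epochs."""
        labels = self.labels
        if len(labels) == 0:
            return pd.DataFrame(columns=["state", "start_epoch", "n_epochs"])
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(labels)]])
        return pd.DataFrame(
            {
                "state": labels[starts],
                "start_epoch": starts,
                "n_epochs": ends - starts,
            }
        )

    def copy(self) -> "Hypnogram":
        return replace(self, labels=self.labels.copy())


def state_runs_samples(
    hyp: Hypnogram, fs: float, n_samples: int, states: tuple[str, ...]
) -> list[tuple[int, int]]:
    """Contiguous sample ranges ``(start, stop)`` whose label is in ``states``."""
    lab = hyp.sample_labels(fs, n_samples)
    mask = np.isin(lab, states)
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(n_samples)
    return list(zip(starts, stops))
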