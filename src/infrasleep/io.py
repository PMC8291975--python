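"""EDF and CSV import/export.

Signals go to a single EDF (one channel per role, 16-bit physical scaling);
the hypnogram and event tables go to CSV with documented columns:

- ``hypnogram.csv``: ``epoch_index, zt_seconds, state``
- ``events.csv``: ``onset_s, duration_s, type, channel``

The EDF writer/reader here implement the plain EDF spec (256-byte header,
256 bytes per channel, little-endian int16 records); channel roles are
encoded in the EDF label as ``"<name> <role>"``.  Round trips reproduce
labels exactly and signals to within one 16-bit quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Recording, EVENT_COLUMNS, make_event_table

_EDF_HEADER = 256


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii", "replace")
    return b + b" " * (width - len(b))


def write_edf(path, rec: Recording) -> None:
    """Write ``rec`` as plain EDF with 1-s data records."""
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    n_rec = int(np.ceil(rec.n_samples / spr))
    nch = len(rec.channels)

    data = np.zeros((nch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    phys_min, phys_max, digital = [], [], []
    dmin, dmax = -32768.0, 32767.0
    for row in data:
        m = max(1e-6, float(np.abs(row).max()))
        # physical extrema as *written* (8-char ASCII, 6 significant
        # digits), slightly inflated so rounding can never clip; encode
        # with the exact inverse of the standard EDF decode map
        m = float(f"{m * 1.001:.6g}"[:8])
        phys_min.append(-m)
        phys_max.append(m)
        gain = 2.0 * m / (dmax - dmin)
        dig = np.clip(np.round((row + m) / gain + dmin), dmin, dmax).astype("<i2")
        digital.append(dig)

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))  # patient id
        f.write(_pad("Startdate X X X X", 80))  # recording id
        f.write(_pad("01.01.01", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(_EDF_HEADER * (1 + nch)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))  # record duration, s
        f.write(_pad(str(nch), 4))
        labels = [f"{name} {rec.roles.get(name, '')}".strip() for name in rec.channels]
        for lab in labels:
            f.write(_pad(lab, 16))
        for _ in range(nch):
            f.write(_pad("", 80))  # transducer
        for _ in range(nch):
            f.write(_pad("uV", 8))
        for v in phys_min:
            f.write(_pad(f"{v:.6g}", 8))
        for v in phys_max:
            f.write(_pad(f"{v:.6g}", 8))
        for _ in range(nch):
            f.write(_pad("-32768", 8))
        for _ in range(nch):
            f.write(_pad("32767", 8))
        for _ in range(nch):
            f.write(_pad("", 80))  # prefiltering
        for _ in range(nch):
            f.write(_pad(str(spr), 8))
        for _ in range(nch):
            f.write(_pad("", 32))
        for r in range(n_rec):
            for ch in range(nch):
                f.write(digital[ch][r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF written by :func:`write_edf` (plain EDF, int16)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def s(lo, hi):
        return raw[lo:hi].decode("ascii", "replace").strip()

    if s(0, 8) != "0":
        raise ValueError(f"{path}: malformed EDF (bad version field {s(0, 8)!r})")
    header_bytes = int(s(184, 192))
    n_rec = int(s(236, 244))
    rec_dur = float(s(244, 252))
    nch = int(s(252, 256))
    if header_bytes != _EDF_HEADER * (1 + nch):
        raise ValueError(f"{path}: malformed EDF (header size mismatch)")

    off = _EDF_HEADER

    def col(width):
        nonlocal off
        vals = [s(off + i * width, off + (i + 1) * width) for i in range(nch)]
        off += nch * width
        return vals

    labels = col(16)
    col(80)  # transducer
    col(8)  # unit
    pmin = [float(v) for v in col(8)]
    pmax = [float(v) for v in col(8)]
    dmin = [float(v) for v in col(8)]
    dmax = [float(v) for v in col(8)]
    col(80)  # prefiltering
    spr = [int(v) for v in col(8)]
    col(32)

    body = np.frombuffer(raw[header_bytes:], dtype="<i2")
    rec_len = sum(spr)
    if body.size < n_rec * rec_len:
        raise ValueError(f"{path}: malformed EDF (truncated data records)")
    body = body[: n_rec * rec_len].reshape(n_rec, rec_len)

    channels, roles, rows = [], {}, []
    pos = 0
    for ch in range(nch):
        dig = body[:, pos : pos + spr[ch]].reshape(-1).astype(float)
        pos += spr[ch]
        gain = (pmax[ch] - pmin[ch]) / (dmax[ch] - dmin[ch])
        rows.append(pmin[ch] + (dig - dmin[ch]) * gain)
        parts = labels[ch].split()
        name = parts[0] if parts else f"ch{ch}"
        role = parts[1] if len(parts) > 1 else ""
        channels.append(name)
        roles[name] = role
    fs = spr[0] / rec_dur
    if any(v != spr[0] for v in spr):
        raise ValueError(f"{path}: mixed per-channel rates are not supported")
    return Recording(np.vstack(rows), fs, channels, roles)


def write_hypnogram_csv(path, hyp: Hypnogram) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "zt_seconds": hyp.epoch_times() - hyp.zt0_s,
            "state": hyp.labels,
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path, epoch_s: float = 4.0) -> Hypnogram:
    df = pd.read_csv(path)
    zt0 = -float(df["zt_seconds"].iloc[0]) if len(df) else 0.0
    return Hypnogram(df["state"].to_numpy(dtype="<U1"), epoch_s=epoch_s, zt0_s=zt0)


def export_recording(rec: Recording, hyp: Hypnogram, events: pd.DataFrame, out_dir) -> dict:
    """Write signals.edf / hypnogram.csv / events.csv into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out_dir / "signals.edf",
        "hypnogram": out_dir / "hypnogram.csv",
        "events": out_dir / "events.csv",
    }
    write_edf(paths["edf"], rec)
    write_hypnogram_csv(paths["hypnogram"], hyp)
    events[EVENT_COLUMNS].to_csv(paths["events"], index=False)
    return paths


def import_recording(in_dir, epoch_s: float = 4.0, require_emg: bool = True):
    """Read back an exported session; returns ``(rec, hyp, events)``.

    Raises ``ValueError`` when an EMG-role channel is required but absent.
    """
    in_dir = Path(in_dir)
    rec = read_edf(in_dir / "signals.edf")
    if require_emg and not rec.channels_with_role("emg"):
        raise ValueError("imported recording has no EMG-role channel")
    hyp = read_hypnogram_csv(in_dir / "hypnogram.csv", epoch_s=epoch_s)
    ev_path = in_dir / "events.csv"
    if ev_path.exists():
        events = pd.read_csv(ev_path)
        if len(events) == 0:
            events = make_event_table()
        else:
            events["channel"] = events["channel"].fillna("")
    else:
        events = make_event_table()
    return rec, hyp, events
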