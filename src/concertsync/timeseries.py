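"""Core time-series containers and physiological preprocessing.

The pipeline works on regularly sampled per-participant signals: heart
rate (HR), respiration rate (RR) and phasic skin-conductance response
(SCR) at 1 Hz, the raw respiration-belt signal (RESP) at 10 Hz, and
motion energy (MOVE) at 15 Hz.  Upstream event-like signals (e.g.
instantaneous heart rate at beat times) are converted to uniform series
by linear interpolation.  Missing samples are explicit: they are stored
as NaN and propagate conservatively through every aggregation step.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "Channel",
    "UniformSeries",
    "EventSeries",
    "SessionLayout",
    "interpolate_events_to_uniform",
    "preprocess_resp",
    "downsample_mean",
    "read_channel_csv",
    "write_channel_csv",
]


class Channel(str, enum.Enum):
    """Signal channels with their conventional sampling rates."""

    HR = "HR"      # heart rate, bpm, 1 Hz
    RR = "RR"      # respiration rate, breaths/min, 1 Hz
    SCR = "SCR"    # phasic skin conductance response, µS, 1 Hz
    RESP = "RESP"  # respiration belt signal, a.u., 10 Hz
    MOVE = "MOVE"  # motion energy, pixel counts, 15 Hz

    @property
    def default_rate(self) -> float:
        return {"HR": 1.0, "RR": 1.0, "SCR": 1.0, "RESP": 10.0, "MOVE": 15.0}[self.value]


@dataclass
class UniformSeries:
    """One participant-channel sampled on a regular grid.

    Sample ``k`` represents time ``t0 + k / rate`` (0-based grid).
    Missing samples are NaN.
    """

    participant_id: str
    channel: Channel
    rate: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel = Channel(self.channel)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.rate

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def slice_window(self, start_s: float, end_s: float) -> "UniformSeries":
        """Samples whose grid time lies in [start_s, end_s)."""
        i0 = int(math.ceil((start_s - self.t0) * self.rate - 1e-9))
        i1 = int(math.ceil((end_s - self.t0) * self.rate - 1e-9))
        i0, i1 = max(i0, 0), min(i1, len(self.values))
        return UniformSeries(
            self.participant_id,
            self.channel,
            self.rate,
            self.values[i0:i1].copy(),
            t0=self.t0 + i0 / self.rate,
        )


@dataclass
class EventSeries:
    """Irregular (time, value) events, e.g. instantaneous HR at beats."""

    participant_id: str
    channel: Channel
    events: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        t = np.asarray([e[0] for e in self.events], dtype=float)
        v = np.asarray([e[1] for e in self.events], dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        if len(v) and not np.all(np.isfinite(v)):
            raise ValueError("event values must be finite")
        self._t, self._v = t, v

    @property
    def times(self) -> np.ndarray:
        return self._t

    @property
    def values(self) -> np.ndarray:
        return self._v


@dataclass
class SessionLayout:
    """Concert programme: ordered, non-overlapping pieces."""

    concert_id: str
    pieces: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for label, start, end in self.pieces:
            if end <= start:
                raise ValueError(f"piece {label!r}: end must exceed start")
            if start < prev_end:
                raise ValueError(f"piece {label!r} overlaps previous piece")
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.pieces]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "concert_id": self.concert_id,
            "pieces": [
                {"label": l, "start_s": s, "end_s": e} for l, s, e in self.pieces
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionLayout":
        obj = json.loads(Path(path).read_text())
        pieces = [(p["label"], float(p["start_s"]), float(p["end_s"])) for p in obj["pieces"]]
        return cls(concert_id=obj["concert_id"], pieces=pieces)


def interpolate_events_to_uniform(ev: EventSeries, rate: float) -> UniformSeries:
    """Convert an event series to a uniform grid by linear interpolation.

    Grid points outside the event support [first, last] are missing.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(ev.times) < 2:
        raise ValueError("insufficient events")
    t0 = 0.0
    n = int(math.floor(ev.times[-1] * rate)) + 1
    grid = t0 + np.arange(n) / rate
    out = np.interp(grid, ev.times, ev.values)
    out[(grid < ev.times[0]) | (grid > ev.times[-1])] = np.nan
    return UniformSeries(ev.participant_id, ev.channel, rate, out, t0=t0)


def _butter_lowpass_zero_phase(x: np.ndarray, rate: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    sos = _signal.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    # pad by several filter time constants to suppress edge transients
    padlen = min(len(x) - 1, int(5 * rate / cutoff_hz))
    return _signal.sosfiltfilt(sos, x, padlen=padlen)


def preprocess_resp(
    raw: UniformSeries, cutoff_hz: float = 0.6, target_rate: float = 10.0, order: int = 4
) -> UniformSeries:
    """Respiration-belt preprocessing: low-pass, demean, downsample.

    A zero-phase (forward-backward) Butterworth low-pass at ``cutoff_hz``
    is applied, the filtered signal is demeaned, and the result is
    bin-averaged to ``target_rate``.  Zero phase matters here: any phase
    shift would masquerade as a synchrony lag downstream.
    """
    if raw.rate < 20:
        raise ValueError("raw respiration must be sampled at >= 20 samples/s")
    x = raw.values
    miss = np.isnan(x)
    if miss.all():
        raise ValueError("all samples missing")
    # filter over the observed support; gaps stay missing
    filled = x.copy()
    if miss.any():
        idx = np.arange(len(x))
        filled[miss] = np.interp(idx[miss], idx[~miss], x[~miss])
    y = _butter_lowpass_zero_phase(filled, raw.rate, cutoff_hz, order)
    y = y - np.nanmean(y[~miss]) if miss.any() else y - y.mean()
    y[miss] = np.nan
    filtered = UniformSeries(raw.participant_id, raw.channel, raw.rate, y, t0=raw.t0)
    out = downsample_mean(filtered, target_rate)
    good = ~np.isnan(out.values)
    if good.any():
        out.values[good] -= out.values[good].mean()
    return out


def downsample_mean(s: UniformSeries, target_rate: float) -> UniformSeries:
    """Bin-average to a lower rate; a bin with any missing sample is missing."""
    ratio = s.rate / target_rate
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("incompatible rates")
    if k == 1:
        return UniformSeries(s.participant_id, s.channel, target_rate, s.values.copy(), t0=s.t0)
    n_bins = len(s.values) // k
    binned = s.values[: n_bins * k].reshape(n_bins, k)
    out = binned.mean(axis=1)  # NaN poisons its bin
    return UniformSeries(s.participant_id, s.channel, target_rate, out, t0=s.t0)


# ---------------------------------------------------------------------------
# CSV I/O — wide dialect: `time_s` column plus one column per participant.

def write_channel_csv(series: Iterable[UniformSeries], path: str | Path) -> None:
    series = list(series)
    if not series:
        raise ValueError("no series to write")
    rates = {s.rate for s in series}
    t0s = {s.t0 for s in series}
    if len(rates) > 1 or len(t0s) > 1:
        raise ValueError("all series must share rate and t0")
    ids = [s.participant_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")
    n = max(len(s) for s in series)
    rate, t0 = rates.pop(), t0s.pop()
    data = {"time_s": t0 + np.arange(n) / rate}
    for s in series:
        col = np.full(n, np.nan)
        col[: len(s)] = s.values
        data[s.participant_id] = col
    # default str() formatting = shortest round-trip repr of each float
    pd.DataFrame(data).to_csv(path, index=False)


def read_channel_csv(path: str | Path, channel: Channel | str) -> list[UniformSeries]:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if not header or header[0] != "time_s":
        raise ValueError("malformed header: first column must be 'time_s'")
    cols = header[1:]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate participant columns")
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = header
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two rows to infer the rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-monotone time column")
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 1e-6 * max(step, 1.0):
        raise ValueError("time column is not uniformly spaced")
    rate = 1.0 / step
    if abs(rate - round(rate)) < 1e-6:  # snap float noise on integer rates
        rate = float(round(rate))
    channel = Channel(channel)
    return [
        UniformSeries(c, channel, rate, df[c].to_numpy(dtype=float), t0=float(t[0]))
        for c in cols
    ]
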