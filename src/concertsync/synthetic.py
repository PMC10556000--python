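"""Synthetic concert audiences with known ground truth.

The generator emulates induction synchrony: a single shared
stimulus-driven component (the "zeitgeber", standing in for the music)
drives every participant's channels through an individual coupling gain
g_i and an individual response lag τ_i, on top of autocorrelated
individual noise:

    x_i(t) = g_i · z(t − τ_i) + sqrt(1 − g_i²) · ε_i(t),

where z and ε_i are standardized, so channel variance is constant in
g_i and differences in measured synchrony reflect coupling, not
amplitude.  Channels are then affinely mapped into physiological ranges
(HR ≈ 50–110 bpm, RR ≈ 8–24 breaths/min, SCR ≥ 0 µS via softplus,
RESP zero-mean a.u., MOVE ≥ 0 pixel counts via softplus).

The respiration-belt channel is generated uncoupled by default
(coupling multiplier 0), emulating a stimulus that entrains breathing
rate but not breathing behavior; all other channels couple fully.
Missing samples are inserted as contiguous blocks (sensor dropouts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motion_energy import ROI, FrameStack
from .timeseries import Channel, SessionLayout, UniformSeries

__all__ = [
    "AudienceSpec",
    "generate_zeitgeber",
    "generate_audience",
    "generate_traits",
    "generate_frames",
]

BASE_RATE = 30.0  # Hz; common multiple of all channel rates

CHANNEL_RATES = {
    Channel.HR: 1.0,
    Channel.RR: 1.0,
    Channel.SCR: 1.0,
    Channel.RESP: 10.0,
    Channel.MOVE: 15.0,
}

# channel-level coupling multipliers applied on top of g_i; RESP is
# uncoupled, emulating non-synchronized breathing behavior
DEFAULT_CHANNEL_COUPLING = {
    Channel.HR: 1.0,
    Channel.RR: 1.0,
    Channel.SCR: 1.0,
    Channel.RESP: 0.0,
    Channel.MOVE: 1.0,
}

# affine maps into physiological ranges: value = offset + scale * x
CHANNEL_AFFINE = {
    Channel.HR: (80.0, 10.0),
    Channel.RR: (16.0, 3.0),
    Channel.RESP: (0.0, 1.0),
}


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class AudienceSpec:
    """Ground-truth description of one synthetic audience."""

    m: int = 10
    duration_s: float = 300.0
    seed: int = 0
    layout: SessionLayout | None = None
    channels: tuple[Channel, ...] = (
        Channel.HR, Channel.RR, Channel.SCR, Channel.RESP, Channel.MOVE,
    )
    gains: np.ndarray | None = None          # default U(0.3, 0.9)
    lags_s: np.ndarray | None = None         # default U(-2, 2) s
    noise_ar1: np.ndarray | None = None      # default U(0.3, 0.7)
    gain_range: tuple[float, float] = (0.3, 0.9)
    lag_range_s: tuple[float, float] = (-2.0, 2.0)
    ar1_range: tuple[float, float] = (0.3, 0.7)
    missing_rate: float = 0.0
    missing_block_s: float = 10.0
    channel_coupling: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_COUPLING))

    def __post_init__(self) -> None:
        if self.duration_s < 60:
            raise ValueError("duration must be at least 60 s")
        if self.layout is not None:
            for _, start, end in self.layout.pieces:
                if start < 0 or end > self.duration_s:
                    raise ValueError("piece boundaries outside duration")
        if self.gains is not None and np.any(np.abs(np.asarray(self.gains)) > 1):
            raise ValueError("gains must lie in [-1, 1]")

    def resolve(self) -> "AudienceSpec":
        """Draw any unspecified per-participant parameters (seeded)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xA0D]))
        if self.gains is None:
            self.gains = rng.uniform(*self.gain_range, size=self.m)
        else:
            self.gains = np.asarray(self.gains, dtype=float)
        if self.lags_s is None:
            self.lags_s = rng.uniform(*self.lag_range_s, size=self.m)
        else:
            self.lags_s = np.asarray(self.lags_s, dtype=float)
        if self.noise_ar1 is None:
            self.noise_ar1 = rng.uniform(*self.ar1_range, size=self.m)
        else:
            self.noise_ar1 = np.asarray(self.noise_ar1, dtype=float)
        return self


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    innov = rng.standard_normal(n)
    innov[0] /= np.sqrt(max(1 - phi**2, 1e-12))  # stationary start
    x = lfilter([1.0], [1.0, -phi], innov)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_zeitgeber(
    duration_s: float, rate: float = BASE_RATE, seed: int = 0
) -> UniformSeries:
    """Smooth band-limited stimulus: AR(1) with 0.95 autocorrelation per
    second plus two incommensurate slow sinusoids, standardized to zero
    mean and unit variance."""
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2E17]))
    phi = 0.95 ** (1.0 / rate)  # lag-1s autocorrelation 0.95
    ar = _ar1(n, phi, rng)
    t = np.arange(n) / rate
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    s1 = np.sin(2 * np.pi * 0.08 * t + phase1)
    s2 = np.sin(2 * np.pi * 0.08 * np.sqrt(2) * t + phase2)
    x = 0.7 * ar + 0.5 * s1 + 0.5 * s2
    x = (x - x.mean()) / x.std()
    return UniformSeries("zeitgeber", Channel.MOVE, rate, x)


def _bin_mean(x: np.ndarray, k: int) -> np.ndarray:
    n = len(x) // k
    return x[: n * k].reshape(n, k).mean(axis=1)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _insert_missing_blocks(
    values: np.ndarray, rate: float, missing_rate: float, block_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if missing_rate <= 0:
        return values
    n = len(values)
    block = max(1, int(round(block_s * rate)))
    n_missing = int(round(missing_rate * n))
    out = values.copy()
    placed = 0
    guard = 0
    while placed < n_missing and guard < 10 * n:
        start = rng.integers(0, max(n - block, 1))
        end = min(start + block, n)
        placed += int(np.sum(~np.isnan(out[start:end])))
        out[start:end] = np.nan
        guard += 1
    return out


def generate_audience(
    spec: AudienceSpec,
) -> tuple[dict[Channel, list[UniformSeries]], pd.DataFrame]:
    """Simulate every channel of every participant.

    Returns (channel -> list of UniformSeries, ground-truth table with
    participant_id, gain, lag_s, noise_ar1).
    """
    spec.resolve()
    pad = 8.0  # seconds of zeitgeber padding to realize lags by slicing
    z_full = generate_zeitgeber(spec.duration_s + 2 * pad, BASE_RATE, spec.seed).values
    n_base = int(round(spec.duration_s * BASE_RATE))

    master = np.random.SeedSequence([spec.seed, 0xC0FFEE])
    part_seeds = master.spawn(spec.m)

    ids = [f"P{i:03d}" for i in range(spec.m)]
    out: dict[Channel, list[UniformSeries]] = {ch: [] for ch in spec.channels}
    for i in range(spec.m):
        g = float(spec.gains[i])
        tau = float(spec.lags_s[i])
        phi = float(spec.noise_ar1[i])
        start = int(round((pad - tau) * BASE_RATE))
        z_i = z_full[start : start + n_base]
        ch_seeds = part_seeds[i].spawn(len(spec.channels))
        for ch, ch_ss in zip(spec.channels, ch_seeds):
            rng = np.random.default_rng(ch_ss)
            rate = CHANNEL_RATES[ch]
            k = int(round(BASE_RATE / rate))
            g_ch = g * spec.channel_coupling.get(ch, 1.0)
            noise = _ar1(n_base, phi, rng)
            # mix after downsampling so the variance budget holds at the
            # channel rate regardless of how binning attenuates each part
            z_ds = _standardize(_bin_mean(z_i, k))
            e_ds = _standardize(_bin_mean(noise, k))
            x = g_ch * z_ds + np.sqrt(max(1 - g_ch**2, 0.0)) * e_ds
            if ch is Channel.SCR:
                vals = _softplus(x)
            elif ch is Channel.MOVE:
                vals = 20.0 * _softplus(x)
            else:
                off, scale = CHANNEL_AFFINE[ch]
                vals = off + scale * x
            vals = _insert_missing_blocks(
                vals, rate, spec.missing_rate, spec.missing_block_s, rng
            )
            out[ch].append(UniformSeries(ids[i], ch, rate, vals))
    truth = pd.DataFrame(
        {"participant_id": ids, "gain": spec.gains, "lag_s": spec.lags_s,
         "noise_ar1": spec.noise_ar1}
    )
    return out, truth


TRAIT_COLUMNS = [
    "extraversion", "agreeableness", "conscientiousness", "neuroticism", "openness",
]
AFFECT_COLUMNS = ["positive_activation", "negative_activation", "valence"]


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Monotone min-max map into [lo, hi]; preserves rank order exactly."""
    rng_ = x.max() - x.min()
    if rng_ == 0:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (hi - lo) * (x - x.min()) / rng_


def generate_traits(
    gains: np.ndarray,
    target_r: float = 0.4,
    seed: int = 0,
    coupled_column: str = "openness",
) -> pd.DataFrame:
    """Trait/affect table with one trait tied to the true coupling gains.

    ``coupled_column`` = target_r · standardized(g) + sqrt(1−r²) · noise,
    then monotonically rescaled to the 1–5 Likert range; the remaining
    traits and the three affect scales (1–7) are independent noise.
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    g = np.asarray(gains, dtype=float)
    m = len(g)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EA7]))
    zg = _standardize(g)
    table = {"participant_id": [f"P{i:03d}" for i in range(m)]}
    for col in TRAIT_COLUMNS:
        if col == coupled_column:
            raw = target_r * zg + np.sqrt(1 - target_r**2) * rng.standard_normal(m)
        else:
            raw = rng.standard_normal(m)
        table[col] = _rescale(raw, 1.0, 5.0)
    for col in AFFECT_COLUMNS:
        table[col] = _rescale(rng.standard_normal(m), 1.0, 7.0)
    return pd.DataFrame(table)


def generate_frames(
    move_series: list[UniformSeries],
    rois: list[ROI],
    image_size: tuple[int, int] = (120, 160),
    seed: int = 0,
    background_level: int = 30,
) -> FrameStack:
    """Video fixture: one bright blob per ROI whose frame-to-frame
    displacement is proportional to that participant's MOVE signal.

    For a square blob, a horizontal displacement of d pixels changes
    2·h·d pixels, so the recovered motion energy tracks the input.
    """
    if len(move_series) != len(rois):
        raise ValueError("need one MOVE series per ROI")
    for i, r in enumerate(rois):
        for other in rois[i + 1 :]:
            if r.overlaps(other):
                raise ValueError("overlapping ROIs")
    h, w = image_size
    n_frames = min(len(s.values) for s in move_series) + 1
    frames = np.full((n_frames, h, w), background_level, dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1A9]))
    fps = move_series[0].rate
    for s, roi in zip(move_series, rois):
        rw, rh = roi.x1 - roi.x0, roi.y1 - roi.y0
        blob = max(3, min(rw, rh) // 3)
        max_off = rw - blob - 1
        move = np.nan_to_num(s.values[: n_frames - 1])
        peak = move.max() if move.max() > 0 else 1.0
        step = np.round(move / peak * max(1, max_off // 2)).astype(int)
        x_off = 0
        direction = 1
        y = roi.y0 + (rh - blob) // 2
        for k in range(n_frames):
            frames[k, y : y + blob, roi.x0 + x_off : roi.x0 + x_off + blob] = 220
            if k < n_frames - 1:
                d = step[k]
                if x_off + direction * d > max_off or x_off + direction * d < 0:
                    direction = -direction
                x_off += direction * d
    _ = rng  # reserved for future noise injection; keeps signature stable
    return FrameStack(frames=frames, fps=fps)


def write_audience(
    out_dir: str | Path,
    spec: AudienceSpec,
    traits_target_r: float = 0.4,
) -> dict[str, Path]:
    """Simulate and write channel CSVs, traits CSV, layout JSON, truth CSV."""
    from .timeseries import write_channel_csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels, truth = generate_audience(spec)
    paths: dict[str, Path] = {}
    for ch, series in channels.items():
        p = out_dir / f"{ch.value.lower()}.csv"
        write_channel_csv(series, p)
        paths[ch.value] = p
    truth_path = out_dir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False, float_format="%.17g")
    paths["ground_truth"] = truth_path
    traits = generate_traits(np.asarray(spec.gains), traits_target_r, seed=spec.seed)
    traits_path = out_dir / "traits.csv"
    traits.to_csv(traits_path, index=False, float_format="%.17g")
    paths["traits"] = traits_path
    layout = spec.layout or SessionLayout("concert", [("all", 0.0, spec.duration_s)])
    layout_path = out_dir / "layout.json"
    layout.to_json(layout_path)
    paths["layout"] = layout_path
    return paths
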