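"""Bivariate surrogate synchrony (SUSY).

Two time series are cut into non-overlapping segments (default 30 s).
Within each aligned segment pair, Pearson cross-correlations are computed
at every integer-sample lag in ±max_lag (default ±5 s, so the
cross-correlation range is 10 s), Fisher-Z transformed and averaged —
without taking absolute values, so in-phase coupling gives Z > 0 and
anti-phase coupling Z < 0.  The "real" synchrony is the mean segment Z
over aligned pairs (i, i).

The null is built by segment shuffling: every misaligned pairing (i, j),
i ≠ j, of one series' segments with the other's is a surrogate that
preserves means, distributions and within-segment autocorrelation while
destroying the temporal alignment; n segments yield n(n−1) surrogates.
The effect size is

    ES = (Z_real − mean Z_surr) / sd Z_surr,

a signed z-score of observed synchrony against its own surrogate null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .timeseries import SessionLayout, UniformSeries

__all__ = [
    "SusyConfig",
    "DyadSynchrony",
    "Segment",
    "segment_series",
    "segment_cross_z",
    "susy_dyad",
    "audience_susy",
]


@dataclass(frozen=True)
class SusyConfig:
    segment_s: float = 30.0
    max_lag_s: float = 5.0
    fisher_clip_eps: float = 1e-6
    surrogate_mode: str = "exhaustive"  # or "sampled"
    n_surrogates: int = 500             # used in sampled mode
    seed: int = 0                       # used in sampled mode
    min_valid_segments: int = 2
    min_surrogate_pairs: int = 10

    def __post_init__(self) -> None:
        if not self.segment_s > 2 * self.max_lag_s:
            raise ValueError("segment_s must exceed 2 * max_lag_s")
        if not (0 < self.fisher_clip_eps < 0.1):
            raise ValueError("fisher_clip_eps must lie in (0, 0.1)")
        if self.surrogate_mode not in ("exhaustive", "sampled"):
            raise ValueError("surrogate_mode must be 'exhaustive' or 'sampled'")


@dataclass
class DyadSynchrony:
    ids: tuple[str, str]
    z_real: float
    z_surr_mean: float
    z_surr_sd: float
    es: float
    n_segments: int
    n_valid_segments: int
    missing: bool = False


@dataclass
class Segment:
    values: np.ndarray
    valid: bool
    index: int


def segment_series(s: UniformSeries, segment_s: float) -> list[Segment]:
    """Cut into consecutive segments of exactly ``segment_s``; a trailing
    partial segment is dropped; segments containing missing samples are
    flagged invalid."""
    seg_len_f = segment_s * s.rate
    seg_len = int(round(seg_len_f))
    if abs(seg_len_f - seg_len) > 1e-9:
        raise ValueError("segment_s * rate must be an integer")
    if len(s.values) < seg_len:
        raise ValueError("series shorter than one segment")
    n = len(s.values) // seg_len
    out = []
    for i in range(n):
        v = s.values[i * seg_len : (i + 1) * seg_len]
        out.append(Segment(values=v, valid=not np.isnan(v).any(), index=i))
    return out


def _lagged_views(seg_matrix: np.ndarray, max_lag: int):
    """For each lag, the trimmed column slices (a_sl for the first member,
    b_sl for the second).  Lag τ compares a(t) with b(t + τ)."""
    L = seg_matrix.shape[-1] if seg_matrix.ndim > 1 else len(seg_matrix)
    for tau in range(-max_lag, max_lag + 1):
        if tau >= 0:
            yield tau, slice(0, L - tau), slice(tau, L)
        else:
            yield tau, slice(-tau, L), slice(0, L + tau)


def _standardize_rows(x: np.ndarray):
    """Row-wise z-scores and a validity mask (rows with ~zero variance)."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    sd = np.sqrt((xc * xc).mean(axis=1, keepdims=True))
    scale = np.linalg.norm(x, axis=1, keepdims=True) + 1.0
    ok = sd[:, 0] > 1e-13 * scale[:, 0]
    safe = np.where(sd > 0, sd, 1.0)
    return xc / safe, ok


def all_pair_z(
    segs_a: np.ndarray, segs_b: np.ndarray, max_lag: int, clip_eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-over-lags Fisher Z for every segment pairing.

    Parameters are (n_a, L) and (n_b, L) arrays of segment values.
    Returns (Z, valid): (n_a, n_b) matrices; a pairing is invalid when
    either member has zero variance over some lag overlap.
    """
    n_a, L = segs_a.shape
    n_b = segs_b.shape[0]
    if segs_b.shape[1] != L:
        raise ValueError("segment lengths differ")
    if L - max_lag < 3:
        raise ValueError("segments too short for the requested lag range")
    z_sum = np.zeros((n_a, n_b))
    valid = np.ones((n_a, n_b), dtype=bool)
    n_lags = 0
    for _tau, sl_a, sl_b in _lagged_views(segs_a, max_lag):
        xa, ok_a = _standardize_rows(segs_a[:, sl_a])
        xb, ok_b = _standardize_rows(segs_b[:, sl_b])
        m = xa.shape[1]
        r = (xa @ xb.T) / m
        np.clip(r, -(1 - clip_eps), 1 - clip_eps, out=r)
        z_sum += np.arctanh(r)
        valid &= ok_a[:, None] & ok_b[None, :]
        n_lags += 1
    return z_sum / n_lags, valid


def segment_cross_z(
    seg_a: Sequence[float], seg_b: Sequence[float], max_lag_samples: int,
    clip_eps: float = 1e-6,
) -> float:
    """Mean Fisher Z over all lags in ±max_lag for one segment pair.

    Returns NaN when some lag overlap has zero variance (the pair is
    excluded from aggregation rather than raising).
    """
    a = np.asarray(seg_a, dtype=float)[None, :]
    b = np.asarray(seg_b, dtype=float)[None, :]
    z, ok = all_pair_z(a, b, max_lag_samples, clip_eps)
    return float(z[0, 0]) if ok[0, 0] else float("nan")


def _surrogate_indices(n: int, cfg: SusyConfig) -> np.ndarray:
    """Off-diagonal (i, j) index pairs for the surrogate null."""
    pairs = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
    if cfg.surrogate_mode == "sampled" and len(pairs) > cfg.n_surrogates:
        rng = np.random.default_rng(cfg.seed)
        pairs = pairs[rng.choice(len(pairs), size=cfg.n_surrogates, replace=False)]
    return pairs


def susy_from_segments(
    segs_a: list[Segment], segs_b: list[Segment], rate: float,
    cfg: SusyConfig, ids: tuple[str, str],
) -> DyadSynchrony:
    """SUSY on pre-cut segment lists (shared grid for both members)."""
    n = min(len(segs_a), len(segs_b))
    segs_a, segs_b = segs_a[:n], segs_b[:n]
    max_lag = int(round(cfg.max_lag_s * rate))

    def _missing() -> DyadSynchrony:
        return DyadSynchrony(ids, np.nan, np.nan, np.nan, np.nan, n, 0, missing=True)

    both_valid = np.array([sa.valid and sb.valid for sa, sb in zip(segs_a, segs_b)])
    if n == 0 or both_valid.sum() < cfg.min_valid_segments:
        return _missing()
    A = np.stack([s.values for s in segs_a])
    B = np.stack([s.values for s in segs_b])
    z, ok = all_pair_z(A, B, max_lag, cfg.fisher_clip_eps)
    valid_a = np.array([s.valid for s in segs_a])
    valid_b = np.array([s.valid for s in segs_b])
    ok &= valid_a[:, None] & valid_b[None, :]

    diag_ok = np.diag(ok)
    if diag_ok.sum() < cfg.min_valid_segments:
        return _missing()
    z_real = float(np.diag(z)[diag_ok].mean())

    pairs = _surrogate_indices(n, cfg)
    keep = ok[pairs[:, 0], pairs[:, 1]] if len(pairs) else np.zeros(0, dtype=bool)
    surr = z[pairs[keep, 0], pairs[keep, 1]] if keep.any() else np.array([])
    if len(surr) < cfg.min_surrogate_pairs:
        return _missing()
    surr_mean = float(surr.mean())
    surr_sd = float(surr.std(ddof=1))
    if surr_sd == 0:
        return _missing()
    es = (z_real - surr_mean) / surr_sd
    return DyadSynchrony(
        ids, z_real, surr_mean, surr_sd, es,
        n_segments=n, n_valid_segments=int(diag_ok.sum()),
    )


def susy_dyad(a: UniformSeries, b: UniformSeries, cfg: SusyConfig | None = None) -> DyadSynchrony:
    """SUSY effect size for one dyad."""
    cfg = cfg or SusyConfig()
    if a.rate != b.rate:
        raise ValueError("series rates differ")
    if a.t0 != b.t0:
        raise ValueError("series cover different windows")
    segs_a = segment_series(a, cfg.segment_s)
    segs_b = segment_series(b, cfg.segment_s)
    return susy_from_segments(segs_a, segs_b, a.rate, cfg, (a.participant_id, b.participant_id))


def _piece_segments(
    s: UniformSeries, layout: SessionLayout, segment_s: float
) -> dict[str, list[Segment]]:
    """Segments fully inside each piece, keyed by piece label."""
    out: dict[str, list[Segment]] = {}
    for label, start, end in layout.pieces:
        win = s.slice_window(start, end)
        if len(win.values) < segment_s * s.rate:
            out[label] = []
        else:
            out[label] = segment_series(win, segment_s)
    return out


def audience_susy(
    series: Sequence[UniformSeries],
    cfg: SusyConfig | None = None,
    layout: SessionLayout | None = None,
) -> dict[str, dict[tuple[str, str], DyadSynchrony]]:
    """All dyadic SUSY values, per piece and pooled per concert.

    Returns a mapping scope -> {(id_A, id_B): DyadSynchrony} with scopes
    the piece labels plus ``"concert"`` (all piece segments pooled).
    Matrices are symmetric; each unordered pair is stored once with
    ids sorted.
    """
    cfg = cfg or SusyConfig()
    series = list(series)
    if len(series) < 2:
        raise ValueError("need at least two participants")
    rate = series[0].rate
    if any(s.rate != rate for s in series):
        raise ValueError("all series must share a rate")
    if layout is None:
        dur = min(s.duration_s for s in series)
        layout = SessionLayout("concert", [("all", 0.0, dur)])

    per_piece = {s.participant_id: _piece_segments(s, layout, cfg.segment_s) for s in series}
    ids = [s.participant_id for s in series]
    result: dict[str, dict[tuple[str, str], DyadSynchrony]] = {}
    scopes = list(layout.labels) + ["concert"]
    for scope in scopes:
        result[scope] = {}
        for ia, ib in itertools.combinations(sorted(ids), 2):
            if scope == "concert":
                segs_a = [sg for lbl in layout.labels for sg in per_piece[ia][lbl]]
                segs_b = [sg for lbl in layout.labels for sg in per_piece[ib][lbl]]
            else:
                segs_a, segs_b = per_piece[ia][scope], per_piece[ib][scope]
            result[scope][(ia, ib)] = susy_from_segments(segs_a, segs_b, rate, cfg, (ia, ib))
    return result


def dyad_es_matrix(
    dyads: dict[tuple[str, str], DyadSynchrony], ids: Sequence[str]
) -> np.ndarray:
    """Symmetric ES matrix (NaN diagonal and NaN for missing dyads)."""
    idx = {p: i for i, p in enumerate(ids)}
    m = np.full((len(ids), len(ids)), np.nan)
    for (a, b), d in dyads.items():
        if a in idx and b in idx:
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = d.es
    return m
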