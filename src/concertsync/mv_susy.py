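"""Multivariate surrogate synchrony (mv-SUSY) via the largest eigenvalue.

All m series of an audience are cut into short non-overlapping segments
(default 5 s).  Within each segment the m × m Pearson correlation matrix
between the series is eigendecomposed; its largest eigenvalue λmax
measures how much of the segment's joint variance is carried by one
common mode (λmax = m when all series are identical, λmax = 1 when they
are mutually uncorrelated).  Empirical synchrony is the mean segment
λmax over valid segments.

The null shuffles segment order independently within every series
(default 1000 permutations), destroying cross-series alignment while
preserving each series' marginal distribution and within-segment
autocorrelation.  ES = (λmax − mean λmax_surr) / sd λmax_surr.

``lambda_mode="raw"`` reports the largest eigenvalue itself (range
[1, m]); ``"ratio"`` divides by the eigenvalue sum (= m), giving
[1/m, 1].

Implementation note: segment values are z-scored once per (series,
segment); every correlation any permutation can need is an inner
product of two such unit rows, so the full cross-segment Gram tensor is
precomputed and permutations reduce to index gathers followed by one
batched eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .timeseries import SessionLayout, UniformSeries
from .susy import Segment, segment_series

__all__ = ["MvConfig", "MvSynchrony", "segment_lambda_max", "mv_susy", "mv_susy_concert"]


@dataclass(frozen=True)
class MvConfig:
    segment_s: float = 5.0
    n_perm: int = 1000
    seed: int = 0
    lambda_mode: str = "raw"  # or "ratio"
    max_missing_fraction: float = 0.5  # participant exclusion threshold

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.lambda_mode not in ("raw", "ratio"):
            raise ValueError("lambda_mode must be 'raw' or 'ratio'")


@dataclass
class MvSynchrony:
    lambda_max: float
    lambda_surr: np.ndarray
    lambda_surr_mean: float
    lambda_surr_sd: float
    es: float
    m: int
    n_segments: int
    missing: bool = False


def segment_lambda_max(segment_matrix: np.ndarray, mode: str = "raw") -> float:
    """λmax of the correlation matrix between the rows of an (m, s) segment.

    Raises on zero-variance rows; callers drop such segments beforehand.
    """
    x = np.asarray(segment_matrix, dtype=float)
    m, s = x.shape
    if s < 3:
        raise ValueError("segment too short (need >= 3 samples)")
    sd = x.std(axis=1)
    if np.any(sd <= 1e-13 * (np.abs(x).mean(axis=1) + 1.0)):
        raise ValueError("zero-variance row in segment")
    c = np.corrcoef(x)
    lam = float(np.linalg.eigvalsh(c)[-1])
    return lam / m if mode == "ratio" else lam


def _standardized_segments(
    series: Sequence[UniformSeries], segment_s: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack z-scored segments: (m, n_seg, s_len) plus validity (m, n_seg)."""
    seg_lists = [segment_series(s, segment_s) for s in series]
    n_seg = min(len(sl) for sl in seg_lists)
    s_len = len(seg_lists[0][0].values)
    m = len(series)
    z = np.zeros((m, n_seg, s_len))
    valid = np.zeros((m, n_seg), dtype=bool)
    for i, sl in enumerate(seg_lists):
        for j in range(n_seg):
            v = sl[j].values
            if not sl[j].valid:
                continue
            sd = v.std()
            if sd <= 1e-13 * (np.abs(v).mean() + 1.0):
                continue
            z[i, j] = (v - v.mean()) / (sd * np.sqrt(s_len))
            valid[i, j] = True
    return z, valid, [s.participant_id for s in series]


class GramAudience:
    """Precomputed cross-segment Gram tensor for one audience/one window.

    ``gram[i, a, j, b]`` is the Pearson correlation between series i's
    segment a and series j's segment b.  Leave-one-out audiences are
    index subsets, so contribution analysis reuses one tensor.
    """

    def __init__(self, series: Sequence[UniformSeries], segment_s: float):
        z, valid, ids = _standardized_segments(series, segment_s)
        m, n_seg, s_len = z.shape
        flat = z.reshape(m * n_seg, s_len)
        g = flat @ flat.T
        self.gram = g.reshape(m, n_seg, m, n_seg)
        self.valid = valid
        self.ids = ids
        self.m = m
        self.n_seg = n_seg

    def subset(self, keep: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        keep = np.asarray(keep)
        return self.gram[np.ix_(keep, np.arange(self.n_seg), keep, np.arange(self.n_seg))], self.valid[keep]


def _mv_from_gram(
    gram: np.ndarray, valid: np.ndarray, cfg: MvConfig,
    keys: Sequence[int] | None = None,
) -> MvSynchrony:
    """Compute MvSynchrony from a precomputed Gram tensor.

    ``keys`` are stable per-series identities used to seed the surrogate
    shuffles.  Passing the same keys for the shared series of a full and
    a leave-one-out run makes their surrogate draws coincide on those
    series, so Monte-Carlo noise cancels in contribution differences.
    """
    m, n_seg = valid.shape
    if keys is None:
        keys = list(range(m))
    if m < 3:
        raise ValueError("mv-SUSY needs at least 3 series")
    # listwise segment validity: all series valid in that segment
    seg_ok = valid.all(axis=0)
    good = np.flatnonzero(seg_ok)
    if len(good) < 2:
        return MvSynchrony(np.nan, np.array([]), np.nan, np.nan, np.nan, m, int(len(good)), missing=True)
    n_good = len(good)
    idx = np.arange(m)

    def mean_lambda(perm_cols: np.ndarray) -> float:
        # perm_cols: (m, n_good) segment index per series per output slot
        mats = gram[idx[:, None, None], perm_cols[:, None, :], idx[None, :, None], perm_cols[None, :, :]]
        mats = np.moveaxis(mats, -1, 0)  # (n_good, m, m)
        lam = np.linalg.eigvalsh(mats)[:, -1]
        return float(lam.mean())

    aligned = np.tile(good, (m, 1))
    lam_emp = mean_lambda(aligned)

    # counter-based per-(permutation, series) streams: independent of
    # iteration order and of which other series are present
    all_cols = np.empty((cfg.n_perm, m, n_good), dtype=np.intp)
    for i, key in enumerate(keys):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, int(key)]))
        for k in range(cfg.n_perm):
            all_cols[k, i] = good[rng.permutation(n_good)]
    big = gram[
        idx[None, :, None, None],
        all_cols[:, :, None, :],
        idx[None, None, :, None],
        all_cols[:, None, :, :],
    ]  # (n_perm, m, m, n_good)
    big = np.moveaxis(big, -1, 1).reshape(cfg.n_perm * n_good, m, m)
    lam = np.linalg.eigvalsh(big)[:, -1].reshape(cfg.n_perm, n_good)
    surr = lam.mean(axis=1)

    if cfg.lambda_mode == "ratio":
        lam_emp /= m
        surr = surr / m
    surr_mean = float(surr.mean())
    surr_sd = float(surr.std(ddof=1))
    es = (lam_emp - surr_mean) / surr_sd if surr_sd > 0 else np.nan
    return MvSynchrony(lam_emp, surr, surr_mean, surr_sd, es, m, n_good,
                       missing=not np.isfinite(es))


def mv_susy_concert(series: Sequence[UniformSeries], cfg: MvConfig | None = None) -> MvSynchrony:
    """mv-SUSY over one continuous window (no piece structure)."""
    cfg = cfg or MvConfig()
    series = _exclude_sparse(list(series), cfg)
    if len(series) < 3:
        raise ValueError("mv-SUSY needs at least 3 series")
    ga = GramAudience(series, cfg.segment_s)
    return _mv_from_gram(ga.gram, ga.valid, cfg)


def _exclude_sparse(series: list[UniformSeries], cfg: MvConfig) -> list[UniformSeries]:
    out = []
    for s in series:
        frac = float(np.isnan(s.values).mean())
        if frac <= cfg.max_missing_fraction:
            out.append(s)
    return out


def mv_susy(
    series: Sequence[UniformSeries],
    cfg: MvConfig | None = None,
    layout: SessionLayout | None = None,
) -> dict[str, MvSynchrony]:
    """mv-SUSY per piece and pooled per concert.

    Returns scope -> MvSynchrony with scopes the piece labels plus
    ``"concert"``.
    """
    cfg = cfg or MvConfig()
    series = _exclude_sparse(list(series), cfg)
    if len(series) < 3:
        raise ValueError("mv-SUSY needs at least 3 series")
    rate = series[0].rate
    if any(s.rate != rate for s in series):
        raise ValueError("all series must share a rate")
    if layout is None:
        dur = min(s.duration_s for s in series)
        layout = SessionLayout("concert", [("all", 0.0, dur)])

    out: dict[str, MvSynchrony] = {}
    m = len(series)
    for label, start, end in layout.pieces:
        windows = [s.slice_window(start, end) for s in series]
        ga = GramAudience(windows, cfg.segment_s)
        out[label] = _mv_from_gram(ga.gram, ga.valid, cfg)
    # pooled concert: concatenate the per-piece segments of every series
    pooled_segments: list[list[Segment]] = []
    for s in series:
        segs: list[Segment] = []
        for label, start, end in layout.pieces:
            win = s.slice_window(start, end)
            if len(win.values) >= cfg.segment_s * rate:
                segs.extend(segment_series(win, cfg.segment_s))
        pooled_segments.append(segs)
    n_seg = min(len(sl) for sl in pooled_segments)
    if n_seg >= 2:
        pooled_series = []
        for s, segs in zip(series, pooled_segments):
            vals = np.concatenate([sg.values for sg in segs[:n_seg]])
            pooled_series.append(UniformSeries(s.participant_id, s.channel, rate, vals))
        ga = GramAudience(pooled_series, cfg.segment_s)
        out["concert"] = _mv_from_gram(ga.gram, ga.valid, cfg)
    else:
        out["concert"] = MvSynchrony(np.nan, np.array([]), np.nan, np.nan, np.nan, m, 0, missing=True)
    return out
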