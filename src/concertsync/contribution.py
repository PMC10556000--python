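"""Per-participant synchrony contribution.

Audience synchrony is a group-level quantity; self-report is individual.
The contribution statistic bridges the two levels:

* dyad-mean (SUSY channels): participant X's contribution is the mean
  effect size of all dyads containing X.  Averaging the contributions
  over the audience recovers the grand mean dyadic ES exactly, because
  each dyad enters exactly two row means.
* leave-one-out (mv-SUSY): contribution(X) = ES_total − ES_without_X,
  both computed with the same permutation seed and segment grid so the
  Monte-Carlo noise of the surrogate null cancels in the difference.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .mv_susy import GramAudience, MvConfig, _mv_from_gram
from .susy import DyadSynchrony
from .timeseries import UniformSeries

__all__ = ["susy_contribution", "mv_contribution", "contribution_frame"]


def susy_contribution(
    dyads: dict[tuple[str, str], DyadSynchrony] | np.ndarray,
    ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Dyad-mean contributions from a symmetric ES matrix or a dyad dict.

    Participants with no finite dyad get NaN.
    """
    if isinstance(dyads, np.ndarray):
        mat = np.asarray(dyads, dtype=float)
        if mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
            raise ValueError("need a symmetric matrix for >= 2 participants")
        off = ~np.eye(mat.shape[0], dtype=bool)
        if not np.allclose(mat[off][np.isfinite(mat[off])],
                           mat.T[off][np.isfinite(mat.T[off])]):
            raise ValueError("ES matrix must be symmetric")
        if ids is None:
            ids = [str(i) for i in range(mat.shape[0])]
    else:
        all_ids = sorted({p for pair in dyads for p in pair})
        if ids is None:
            ids = all_ids
        idx = {p: i for i, p in enumerate(ids)}
        mat = np.full((len(ids), len(ids)), np.nan)
        for (a, b), d in dyads.items():
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d.es
    if len(ids) < 2:
        raise ValueError("need at least two participants")
    out: dict[str, float] = {}
    for i, pid in enumerate(ids):
        row = np.delete(mat[i], i)
        finite = row[np.isfinite(row)]
        out[pid] = float(finite.mean()) if len(finite) else float("nan")
    return out


def mv_contribution(
    series: Sequence[UniformSeries], cfg: MvConfig | None = None
) -> dict[str, float]:
    """Leave-one-out contributions ES_total − ES_total−X for every X.

    The full-audience and every reduced-audience run share the segment
    grid and the permutation seed.
    """
    cfg = cfg or MvConfig()
    series = list(series)
    m = len(series)
    if m < 4:
        raise ValueError("leave-one-out contribution needs at least 4 series")
    ga = GramAudience(series, cfg.segment_s)
    total = _mv_from_gram(ga.gram, ga.valid, cfg)
    out: dict[str, float] = {}
    for x in range(m):
        keep = [i for i in range(m) if i != x]
        gram_x, valid_x = ga.subset(keep)
        # keys = original indices: shared series reuse their shuffles
        reduced = _mv_from_gram(gram_x, valid_x, cfg, keys=keep)
        out[ga.ids[x]] = float(total.es - reduced.es)
    return out


def contribution_frame(
    per_scope: dict[str, dict[str, float]], channel: str, method: str
) -> pd.DataFrame:
    """Long-format table: participant_id, channel, scope, method, contribution."""
    rows = [
        {"participant_id": pid, "channel": channel, "scope": scope,
         "method": method, "contribution": val}
        for scope, contribs in per_scope.items()
        for pid, val in contribs.items()
    ]
    return pd.DataFrame(rows, columns=["participant_id", "channel", "scope", "method", "contribution"])
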