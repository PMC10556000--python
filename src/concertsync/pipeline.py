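"""End-to-end study replica: preprocess → synchrony → tests → contributions → regressions.

The run consumes a directory of channel CSVs (wide format), a session
layout JSON, and a traits CSV, and emits tables mirroring the study
report: per-piece/per-concert dyadic synchrony tests for the
physiological channels, multivariate movement synchrony, per-participant
contributions, and stepwise regressions of contributions on traits.
All randomness flows from one seed; reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contribution import contribution_frame, mv_contribution, susy_contribution
from .inference import (
    mv_significance,
    significance_stars,
    stepwise_backward_aic,
    t_test_vs_zero,
)
from .mv_susy import MvConfig, mv_susy
from .susy import SusyConfig, audience_susy
from .synthetic import TRAIT_COLUMNS
from .timeseries import Channel, SessionLayout, read_channel_csv

__all__ = ["RunConfig", "run_pipeline"]

SUSY_CHANNELS = (Channel.HR, Channel.RR, Channel.SCR, Channel.RESP)
MV_CHANNEL = Channel.MOVE


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    channels: tuple[str, ...] = ("HR", "RR", "SCR", "RESP", "MOVE")
    segment_s: float = 30.0
    max_lag_s: float = 5.0
    mv_segment_s: float = 5.0
    n_perm: int = 1000
    test_unit: str = "dyad"  # or "participant"
    alpha: float = 0.05
    trait_columns: tuple[str, ...] = tuple(TRAIT_COLUMNS)

    def validate(self) -> None:
        for ch in self.channels:
            Channel(ch)  # raises on unknown channel names
        if self.test_unit not in ("dyad", "participant"):
            raise ValueError("test_unit must be 'dyad' or 'participant'")
        p = Path(self.input_dir)
        if not p.is_dir():
            raise FileNotFoundError(f"input dir {p} does not exist")

    def analysis_params(self) -> dict:
        """Config minus file locations: what determines the numbers."""
        d = dataclasses.asdict(self)
        d.pop("input_dir")
        d.pop("output_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    in_dir = Path(cfg.input_dir)
    layout_path = in_dir / "layout.json"
    layout = SessionLayout.from_json(layout_path) if layout_path.exists() else None
    channels = {}
    for ch_name in cfg.channels:
        ch = Channel(ch_name)
        path = in_dir / f"{ch.value.lower()}.csv"
        if path.exists():
            channels[ch] = read_channel_csv(path, ch)
    traits_path = in_dir / "traits.csv"
    traits = pd.read_csv(traits_path) if traits_path.exists() else None
    return layout, channels, traits


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    cfg.validate()
    layout, channels, traits = _load_inputs(cfg)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    susy_cfg = SusyConfig(segment_s=cfg.segment_s, max_lag_s=cfg.max_lag_s)
    mv_cfg = MvConfig(segment_s=cfg.mv_segment_s, n_perm=cfg.n_perm, seed=cfg.seed)
    paths: dict[str, Path] = {}

    # --- dyadic synchrony + significance for physiological channels
    test_rows = []
    contrib_frames = []
    for ch in SUSY_CHANNELS:
        if ch not in channels:
            continue
        dyads = audience_susy(channels[ch], susy_cfg, layout)
        per_scope_contrib = {}
        for scope, mat in dyads.items():
            es = np.array([d.es for d in mat.values() if not d.missing])
            contribs = susy_contribution(mat)
            per_scope_contrib[scope] = contribs
            sample = (
                es if cfg.test_unit == "dyad"
                else np.array([v for v in contribs.values() if np.isfinite(v)])
            )
            row = {"channel": ch.value, "scope": scope, "n": len(sample)}
            if len(sample) >= 2 and np.std(sample, ddof=1) > 0:
                tt = t_test_vs_zero(sample)
                row.update(mean_es=tt.mean, sd_es=tt.sd, t=tt.t, df=tt.df,
                           p=tt.p, stars=significance_stars(tt.p))
            else:
                row.update(mean_es=np.nan, sd_es=np.nan, t=np.nan, df=np.nan,
                           p=np.nan, stars="")
            test_rows.append(row)
        contrib_frames.append(contribution_frame(per_scope_contrib, ch.value, "dyad_mean"))
    susy_table = pd.DataFrame(test_rows)
    paths["synchrony_tests"] = out_dir / "synchrony_tests.csv"
    susy_table.to_csv(paths["synchrony_tests"], index=False, float_format="%.10g")

    # --- multivariate movement synchrony
    mv_rows = []
    if MV_CHANNEL in channels and len(channels[MV_CHANNEL]) >= 3:
        mv_res = mv_susy(channels[MV_CHANNEL], mv_cfg, layout)
        for scope, res in mv_res.items():
            row = {"channel": MV_CHANNEL.value, "scope": scope, "m": res.m,
                   "n_segments": res.n_segments}
            if not res.missing:
                tt = mv_significance(res)
                row.update(lambda_max=res.lambda_max,
                           lambda_surr=res.lambda_surr_mean,
                           es=res.es, t=tt.t, p=tt.p,
                           stars=significance_stars(tt.p))
            else:
                row.update(lambda_max=np.nan, lambda_surr=np.nan, es=np.nan,
                           t=np.nan, p=np.nan, stars="")
            mv_rows.append(row)
        loo = mv_contribution(channels[MV_CHANNEL], mv_cfg)
        contrib_frames.append(
            contribution_frame({"concert": loo}, MV_CHANNEL.value, "leave_one_out")
        )
    mv_table = pd.DataFrame(mv_rows)
    paths["mv_synchrony"] = out_dir / "mv_synchrony.csv"
    mv_table.to_csv(paths["mv_synchrony"], index=False, float_format="%.10g")

    # --- contributions
    contributions = (
        pd.concat(contrib_frames, ignore_index=True) if contrib_frames else pd.DataFrame()
    )
    paths["contributions"] = out_dir / "contributions.csv"
    contributions.to_csv(paths["contributions"], index=False, float_format="%.10g")

    # --- regressions: concert-scope contribution ~ traits
    reg_rows = []
    if traits is not None and not contributions.empty:
        preds = [c for c in cfg.trait_columns if c in traits.columns]
        concert = contributions[contributions["scope"] == "concert"]
        for (ch_name, method), grp in concert.groupby(["channel", "method"]):
            merged = traits.merge(
                grp[["participant_id", "contribution"]], on="participant_id"
            )
            if len(merged.dropna()) <= len(preds) + 2:
                continue
            model = stepwise_backward_aic(merged, "contribution", preds, alpha=cfg.alpha)
            for name, (est, t, p) in model.predictors.items():
                reg_rows.append({"channel": ch_name, "method": method,
                                 "predictor": name, "estimate": est, "t": t,
                                 "p": p, "stars": significance_stars(p),
                                 "n": model.n, "r_square": model.r_square})
            if not model.predictors:
                reg_rows.append({"channel": ch_name, "method": method,
                                 "predictor": "(null model)",
                                 "estimate": model.intercept[0],
                                 "t": model.intercept[1], "p": model.intercept[2],
                                 "stars": "", "n": model.n, "r_square": 0.0})
    reg_table = pd.DataFrame(reg_rows)
    paths["regressions"] = out_dir / "regressions.csv"
    reg_table.to_csv(paths["regressions"], index=False, float_format="%.10g")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.analysis_params(),
        "stages": sorted(k for k in paths),
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
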