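"""Evaluation statistics for striatal SPECT quantification.

All statistics derive from the voxelwise specific uptake ratio

    SUR(x) = (value(x) - bg_mean) / bg_mean

computed over the two striatal VOIs, with bg_mean the mean reconstructed
value in the background VOI.  Per VOI v, phantom measurement p,
reconstruction method r and smoothing kernel s, the mean SUR_mean(v,p,r,s)
and sample standard deviation SUR_SD(v,p,r,s) are recorded.  Aggregates:

    AR(r,s)     = 100 / (n_p n_v) * sum_{v,p} SUR_mean(v,p,r,s) / REF(v,p)
    RMSCOV(r,s) = 100 * sqrt( 1/(n_p n_v) * sum_{v,p} (SUR_SD/SUR_mean)^2 )
    aSUR(r,s)   = 1 / (n_p n_v) * sum_{v,p} SUR_mean(v,p,r,s)

AR measures bias (100% = unbiased) against the known true SUR values REF;
RMSCOV measures voxel-level noise; aSUR is the truth-free surrogate for AR
used for patient-like data.  Sweeping the post-smoothing kernel s traces a
"bias-noise" curve per reconstruction method, and methods are compared at
matched noise levels by interpolating bias along those curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phantom import VoiSet

__all__ = [
    "VoiStats",
    "BiasNoiseCurve",
    "voxel_sur",
    "voi_stats",
    "stats_frame",
    "average_recovery",
    "rmscov",
    "average_sur",
    "bias_noise_curve",
    "matched_noise_compare",
    "percent_variation",
]

VOI_COLUMNS = ["v", "p", "r", "s", "sur_mean", "sur_sd", "n_voxels"]


@dataclass(frozen=True)
class VoiStats:
    """Per-VOI summary of the voxelwise SUR field for one volume."""

    v: str
    p: str | int
    r: str
    s: float
    sur_mean: float
    sur_sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("empty VOI")
        if self.sur_sd < 0 or not np.isfinite(self.sur_mean):
            raise ValueError("invalid VOI statistics")


@dataclass
class BiasNoiseCurve:
    """Ordered (smoothing -> bias, noise) points for one reconstruction.

    ``detail`` optionally carries the per-(v,p) values behind each point so
    matched-noise comparisons can emit per-measurement tables.
    """

    r: str
    metric: str  # "AR" or "aSUR"
    smoothing: np.ndarray
    bias: np.ndarray
    noise: np.ndarray
    n_p: int
    n_v: int
    detail: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.smoothing = np.asarray(self.smoothing, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.noise = np.asarray(self.noise, dtype=float)
        if len(self.smoothing) != len(self.bias) or len(self.bias) != len(self.noise):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.smoothing) <= 0):
            raise ValueError("smoothing levels must be strictly increasing")
        if not (np.isfinite(self.bias).all() and np.isfinite(self.noise).all()):
            raise ValueError("curve points must be finite")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "s": self.smoothing,
                             "metric": self.metric, "bias": self.bias,
                             "noise": self.noise})


def voxel_sur(values: np.ndarray, vois: VoiSet) -> Tuple[Dict[str, np.ndarray], float]:
    """Voxelwise SUR over the striatal VOIs.

    Returns ({voi name -> 1-D SUR array}, background mean).  A nonpositive
    background mean flags a failed reconstruction and raises.
    """
    bg_mean = float(values[vois.background].mean())
    if bg_mean <= 0:
        raise ValueError("nonpositive background mean; reconstruction failed")
    sur = {
        "left_striatum": (values[vois.left_striatum] - bg_mean) / bg_mean,
        "right_striatum": (values[vois.right_striatum] - bg_mean) / bg_mean,
    }
    return sur, bg_mean


def voi_stats(values: np.ndarray, vois: VoiSet, p: str | int, r: str,
              s: float) -> List[VoiStats]:
    """SUR_mean / SUR_SD (sample SD, ddof=1) per striatal VOI."""
    sur, _ = voxel_sur(values, vois)
    out = []
    for name, arr in sur.items():
        if arr.size == 0:
            raise ValueError(f"VOI {name} is empty")
        out.append(VoiStats(v=name, p=p, r=r, s=float(s),
                            sur_mean=float(arr.mean()),
                            sur_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                            n_voxels=int(arr.size)))
    return out


def stats_frame(stats: Iterable[VoiStats]) -> pd.DataFrame:
    df = pd.DataFrame([vars(st) for st in stats], columns=VOI_COLUMNS)
    return df


def _as_frame(stats) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        return stats
    return stats_frame(stats)


def _check_single_cell(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("empty statistics collection")
    if df["r"].nunique() > 1 or df["s"].nunique() > 1:
        raise ValueError("statistics mix multiple (r, s) cells")


def average_recovery(stats, refs: Dict[Tuple[str, str | int], float]) -> float:
    """AR in percent for one (r, s) cell; errors on incomplete coverage."""
    df = _as_frame(stats)
    _check_single_cell(df)
    keys = list(zip(df["v"], df["p"]))
    missing = [k for k in keys if k not in refs]
    if missing:
        raise ValueError(f"missing reference SUR for {missing[:3]}")
    ref = np.array([refs[k] for k in keys], dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference SUR values must be positive")
    return float(100.0 * np.mean(df["sur_mean"].to_numpy() / ref))


def rmscov(stats) -> float:
    """RMSCOV in percent for one (r, s) cell."""
    df = _as_frame(stats)
    _check_single_cell(df)
    mean = df["sur_mean"].to_numpy(dtype=float)
    if np.any(mean == 0):
        raise ValueError("zero SUR_mean; coefficient of variation undefined")
    cov = df["sur_sd"].to_numpy(dtype=float) / mean
    return float(100.0 * np.sqrt(np.mean(cov**2)))


def average_sur(stats) -> float:
    """aSUR for one (r, s) cell (truth-free surrogate for AR)."""
    df = _as_frame(stats)
    _check_single_cell(df)
    return float(df["sur_mean"].mean())


def bias_noise_curve(stats, refs: Optional[Dict] = None,
                     metric: str = "AR") -> BiasNoiseCurve:
    """Bias-noise curve for one reconstruction method r from a table of
    VoiStats covering >= 2 smoothing levels including 0 (unsmoothed).

    ``metric='AR'`` requires ``refs``; ``metric='aSUR'`` is truth-free.
    """
    df = _as_frame(stats)
    if df.empty:
        raise ValueError("empty statistics collection")
    if df["r"].nunique() != 1:
        raise ValueError("curve requires a single reconstruction method")
    if metric not in ("AR", "aSUR"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "AR" and refs is None:
        raise ValueError("metric 'AR' requires reference SUR values")

    levels = np.sort(df["s"].unique())
    if len(levels) < 2 or levels[0] != 0.0:
        raise ValueError("need >= 2 smoothing levels including 0")
    vp_ref = None
    bias, noise, detail_rows = [], [], []
    for s in levels:
        cell = df[df["s"] == s]
        vp = set(zip(cell["v"], cell["p"]))
        if vp_ref is None:
            vp_ref = vp
        elif vp != vp_ref:
            raise ValueError("inconsistent VOI/measurement sets across smoothing levels")
        if metric == "AR":
            bias.append(average_recovery(cell, refs))
            per = 100.0 * cell["sur_mean"].to_numpy() / np.array(
                [refs[k] for k in zip(cell["v"], cell["p"])])
        else:
            bias.append(average_sur(cell))
            per = cell["sur_mean"].to_numpy()
        noise.append(rmscov(cell))
        detail_rows.append(pd.DataFrame({"v": cell["v"], "p": cell["p"],
                                         "s": s, "value": per}))
    n_v = df["v"].nunique()
    n_p = df["p"].nunique()
    return BiasNoiseCurve(r=str(df["r"].iloc[0]), metric=metric,
                          smoothing=levels, bias=np.array(bias),
                          noise=np.array(noise), n_p=n_p, n_v=n_v,
                          detail=pd.concat(detail_rows, ignore_index=True))


def _interp_on_curve(curve: BiasNoiseCurve, noise_target: float):
    """Linear interpolation of bias (and smoothing) in noise along a curve.

    Returns (bias, smoothing, extrapolated).  Outside the curve's noise
    range the nearest endpoint is used and flagged.
    """
    order = np.argsort(curve.noise)
    nn = curve.noise[order]
    bb = curve.bias[order]
    ss = curve.smoothing[order]
    extrapolated = not (nn[0] <= noise_target <= nn[-1])
    b = float(np.interp(noise_target, nn, bb))
    s = float(np.interp(noise_target, nn, ss))
    return b, s, extrapolated


def matched_noise_compare(curves: Sequence[BiasNoiseCurve],
                          reference: Optional[str] = None
                          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Compare reconstructions at a common noise level.

    The reference point is the unsmoothed point of the curve with the best
    (largest) unsmoothed bias metric — the minimal-bias reconstruction —
    unless ``reference`` names a method explicitly.  Every curve's bias is
    linearly interpolated in noise at the reference noise level.

    Returns (summary, per_measurement): the summary has one row per method
    with the matched bias; per_measurement carries the interpolated
    per-(v, p) values that a downstream repeated-measures analysis would
    consume.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to compare")
    kinds = {c.metric for c in curves}
    if len(kinds) != 1:
        raise ValueError("curves mix AR and aSUR metrics")

    def unsmoothed_bias(c: BiasNoiseCurve) -> float:
        return float(c.bias[np.argmin(c.smoothing)])

    if reference is None:
        ref_curve = max(curves, key=unsmoothed_bias)
    else:
        matches = [c for c in curves if c.r == reference]
        if not matches:
            raise ValueError(f"no curve named {reference!r}")
        ref_curve = matches[0]
    ref_noise = float(ref_curve.noise[np.argmin(ref_curve.smoothing)])

    rows, per_rows = [], []
    for c in curves:
        b, s_at, extr = _interp_on_curve(c, ref_noise)
        rows.append({"r": c.r, "metric": c.metric, "matched_bias": b,
                     "matched_smoothing": s_at, "ref_noise": ref_noise,
                     "reference": ref_curve.r, "extrapolated": extr})
        if c.detail is not None:
            # interpolate each (v, p) value between the bracketing smoothing
            # levels of the matched point
            lo = c.smoothing[c.smoothing <= s_at].max() if np.any(
                c.smoothing <= s_at) else c.smoothing.min()
            hi = c.smoothing[c.smoothing >= s_at].min() if np.any(
                c.smoothing >= s_at) else c.smoothing.max()
            w = 0.0 if hi == lo else (s_at - lo) / (hi - lo)
            dlo = c.detail[c.detail["s"] == lo].set_index(["v", "p"])["value"]
            dhi = c.detail[c.detail["s"] == hi].set_index(["v", "p"])["value"]
            vals = (1 - w) * dlo + w * dhi
            for (v, p), val in vals.items():
                per_rows.append({"r": c.r, "v": v, "p": p,
                                 "matched_value": float(val)})
    return pd.DataFrame(rows), pd.DataFrame(per_rows)


def percent_variation(values: Sequence[float]) -> float:
    """Maximum spread of *values* as a percentage of the smallest one."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    lo, hi = float(arr.min()), float(arr.max())
    if lo <= 0:
        raise ValueError("values must be positive")
    return 100.0 * (hi - lo) / lo
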