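"""Displacement and MSD analytics for 2D single-particle trajectories.

MSD follows the 2D free-diffusion convention ``MSD = 4 D dt``; an
isotropic 3D estimate is obtained by multiplying the 2D value by 1.5
(4 D dt -> 6 D dt). Time averages use all overlapping start times t0
within a track, then tracks are pooled (time-and-ensemble average); when
a ``cell`` column is present, per-cell curves are retained so the
mean +/- SD among cells can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking_io import StepTable, TrajectorySet

__all__ = [
    "MSDCurve",
    "compute_steps",
    "compute_msd",
    "fit_diffusion",
    "localization_precision",
]

DIM_FACTOR = {"2d": 4.0, "3d": 6.0}  # MSD = factor * D * dt
THREE_D_SCALE = 1.5  # isotropic 2D -> 3D conversion of MSD values


@dataclass
class MSDCurve:
    """A lag-time / MSD curve with optional per-cell dispersion.

    ``msd`` is in um^2 using the stated ``dimension`` convention
    ('2d' native, '3d' = 1.5x the 2D value). ``n`` counts the squared
    displacements averaged at each lag; ``sd_cells`` is the standard
    deviation among per-cell curves where cells are annotated.
    """

    lags: np.ndarray
    msd: np.ndarray
    n: np.ndarray
    dimension: str = "2d"
    sd_cells: np.ndarray | None = None
    per_cell: pd.DataFrame | None = None
    D: float = np.nan
    alpha: float = np.nan

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag times must be strictly increasing")
        finite = np.isfinite(self.msd)
        if np.any(self.msd[finite] < 0):
            raise ValueError("MSD values must be non-negative")


def compute_steps(ts: TrajectorySet, lag_frames: int = 1) -> StepTable:
    """All same-track displacement pairs separated by exactly ``lag_frames``.

    Overlapping windows are included (every start frame t0 for which
    t0 + lag exists in the track). Ground-truth or annotated per-step
    state labels are propagated for lag 1 only, where a step corresponds
    to a single frame interval.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    df = ts.data.sort_values(["track", "frame"], kind="stable")
    left = df.rename(columns={"x": "x0", "y": "y0"})
    right = df[["track", "frame", "x", "y"]].copy()
    right["frame"] = right["frame"] - lag_frames
    merged = left.merge(
        right.rename(columns={"x": "x1", "y": "y1"}),
        on=["track", "frame"],
        how="inner",
    )
    dx = merged["x1"] - merged["x0"]
    dy = merged["y1"] - merged["y0"]
    out = pd.DataFrame(
        {
            "track": merged["track"],
            "start_frame": merged["frame"].astype(int),
            "lag": lag_frames * ts.frame_interval,
            "dx": dx,
            "dy": dy,
            "r": np.hypot(dx, dy),
            "mx": 0.5 * (merged["x0"] + merged["x1"]),
            "my": 0.5 * (merged["y0"] + merged["y1"]),
        }
    )
    if "state" in merged.columns and lag_frames == 1:
        out["state"] = merged["state"].to_numpy()
    if "cell" in merged.columns:
        out["cell"] = merged["cell"].to_numpy()
    return StepTable(out, lag=lag_frames * ts.frame_interval)


def compute_msd(
    ts: TrajectorySet,
    lags: np.ndarray,
    dimension: str = "2d",
) -> MSDCurve:
    """Time- and ensemble-averaged MSD at the given lag times (seconds).

    Lags must be integer multiples of the frame interval. A lag that
    exceeds every track length yields NaN at that lag (flagged via the
    ``n == 0`` count), never a silent zero. In '3d' mode the 2D values
    are multiplied by 1.5.
    """
    dimension = dimension.lower()
    if dimension not in DIM_FACTOR:
        raise ValueError("dimension must be '2d' or '3d'")
    lags = np.asarray(lags, float)
    ratios = lags / ts.frame_interval
    lag_frames = np.rint(ratios).astype(int)
    if np.any(np.abs(ratios - lag_frames) > 1e-6) or np.any(lag_frames < 1):
        raise ValueError("lags must be positive integer multiples of the frame interval")

    has_cells = "cell" in ts.data.columns
    msd = np.full(len(lags), np.nan)
    n = np.zeros(len(lags), dtype=int)
    cell_rows = []
    for i, lf in enumerate(lag_frames):
        steps = compute_steps(ts, int(lf))
        if len(steps) == 0:
            continue
        r2 = steps.r**2
        msd[i] = float(np.mean(r2))
        n[i] = len(r2)
        if has_cells:
            per = steps.data.assign(r2=r2).groupby("cell")["r2"].mean()
            for cell, val in per.items():
                cell_rows.append({"cell": cell, "lag": lags[i], "msd": val})

    scale = THREE_D_SCALE if dimension == "3d" else 1.0
    msd = msd * scale
    per_cell = None
    sd_cells = None
    if cell_rows:
        per_cell = pd.DataFrame(cell_rows)
        per_cell["msd"] *= scale
        sd_cells = (
            per_cell.groupby("lag")["msd"].std(ddof=1).reindex(lags).to_numpy()
        )
    return MSDCurve(
        lags=lags, msd=msd, n=n, dimension=dimension, sd_cells=sd_cells, per_cell=per_cell
    )


def fit_diffusion(
    curve: MSDCurve,
    fit_range: tuple[float, float] = (0.05, 1.0),
) -> tuple[float, float]:
    """Fit D and the anomaly exponent alpha over a lag-time range.

    D comes from unweighted least squares of ``MSD = 4 D dt`` (2D curves;
    ``6 D dt`` for 3D curves) through the origin over the range; alpha is
    the slope of log MSD versus log dt (log-log least squares). Updates
    ``curve.D``/``curve.alpha`` and returns ``(D, alpha)``. Non-positive
    MSD anywhere in the range makes alpha undefined (NaN).
    """
    lo, hi = fit_range
    sel = (curve.lags >= lo - 1e-12) & (curve.lags <= hi + 1e-12) & np.isfinite(curve.msd)
    if sel.sum() < 2:
        raise ValueError("need at least 2 finite lags in the fit range")
    t = curve.lags[sel]
    m = curve.msd[sel]
    factor = DIM_FACTOR[curve.dimension]
    D = float(np.dot(t, m) / np.dot(t, t) / factor)
    if np.any(m <= 0):
        alpha = np.nan
    else:
        slope, _, _, _, _ = stats.linregress(np.log(t), np.log(m))
        alpha = float(slope)
    curve.D, curve.alpha = D, alpha
    return D, alpha


def localization_precision(fixed: TrajectorySet) -> float:
    """Position-determination accuracy from fixed-emitter trajectories, nm.

    Deviations of each observed position from its track centroid are
    pooled per axis across tracks; a Gaussian is fitted to each axis and
    the mean of the x and y standard deviations is returned in nm. Tracks
    with fewer than 2 points are excluded (the data model already enforces
    this).
    """
    devs_x, devs_y = [], []
    for _, sub in fixed.tracks():
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        if len(x) < 2:
            continue
        devs_x.append(x - x.mean())
        devs_y.append(y - y.mean())
    if not devs_x:
        raise ValueError("no usable tracks for precision estimation")
    dx = np.concatenate(devs_x)
    dy = np.concatenate(devs_y)
    _, sd_x = stats.norm.fit(dx)
    _, sd_y = stats.norm.fit(dy)
    return float(0.5 * (sd_x + sd_y) * 1e3)
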