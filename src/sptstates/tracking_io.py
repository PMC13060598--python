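"""Trajectory and localization table I/O and the core tracking data model.

Internal units are micrometres and seconds everywhere; nanometres appear
only at localization-table I/O (the convention of super-resolution
localization software). Frames are 0-based integers; coordinates are
Cartesian with the origin at the window corner and y increasing upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySet",
    "LocalizationTable",
    "StepTable",
    "FormatError",
    "read_trajectories",
    "write_trajectories",
    "read_localizations",
    "write_localizations",
    "filter_tracks",
]

#: columns of the native trajectory CSV dialect
TRACK_COLUMNS = ["track", "frame", "x", "y"]
#: columns of the TrackMate export dialect (positions in um)
TRACKMATE_COLUMNS = {
    "TRACK_ID": "track",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
}
#: columns of the ThunderSTORM export dialect (positions in nm)
THUNDERSTORM_COLUMNS = {"x [nm]": "x_nm", "y [nm]": "y_nm", "frame": "frame"}


class FormatError(ValueError):
    """A table file does not conform to the declared dialect."""


@dataclass
class TrajectorySet:
    """A set of 2D single-particle trajectories.

    Parameters
    ----------
    data
        Long-format table with columns ``track`` (id), ``frame`` (int >= 0),
        ``t`` (s), ``x``, ``y`` (um) and optionally ``state`` (per-step
        label attached to the step *starting* at this point; NaN on the last
        point of each track) and ``cell`` (provenance/dataset id).
    frame_interval
        Acquisition frame interval in seconds; ``t = frame * frame_interval``.
    cell
        Optional provenance tag for the whole set (dataset / cell index).
    """

    data: pd.DataFrame
    frame_interval: float
    cell: str | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        required = {"track", "frame", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing trajectory columns: {sorted(missing)}")
        if "t" not in self.data.columns:
            self.data = self.data.assign(t=self.data["frame"] * self.frame_interval)
        self._validate()

    def _validate(self) -> None:
        if len(self.data) == 0:
            return
        if (self.data["frame"] < 0).any():
            raise ValueError("negative frame index")
        by = self.data.groupby("track", sort=False)
        sizes = by.size()
        if (sizes < 2).any():
            bad = sizes.index[sizes < 2].tolist()
            raise ValueError(f"tracks with fewer than 2 points: {bad[:5]}")
        frames_increasing = by["frame"].apply(lambda f: bool(np.all(np.diff(f.to_numpy()) > 0)))
        if not frames_increasing.all():
            bad = frames_increasing.index[~frames_increasing].tolist()
            raise ValueError(f"frames not strictly increasing in tracks: {bad[:5]}")

    @property
    def n_tracks(self) -> int:
        return self.data["track"].nunique()

    @property
    def n_points(self) -> int:
        return len(self.data)

    def track_lengths(self) -> pd.Series:
        """Number of detected points per track."""
        return self.data.groupby("track", sort=False).size()

    def tracks(self):
        """Iterate ``(track_id, frame-sorted sub-table)`` pairs."""
        yield from self.data.groupby("track", sort=False)

    def copy(self) -> "TrajectorySet":
        return replace(self, data=self.data.copy())


@dataclass
class LocalizationTable:
    """Super-resolution localizations: ``x_nm``, ``y_nm``, ``frame``
    and optional ``intensity`` columns (coordinates in nanometres)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"x_nm", "y_nm", "frame"} - set(self.data.columns)
        if missing:
            raise ValueError(f"missing localization columns: {sorted(missing)}")
        xy = self.data[["x_nm", "y_nm"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates in localization table")
        if (self.data["frame"] < 0).any():
            raise ValueError("negative frame index")

    def __len__(self) -> int:
        return len(self.data)

    def xy_um(self) -> np.ndarray:
        """Coordinates as an (N, 2) array in micrometres."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float) * 1e-3


@dataclass
class StepTable:
    """Per-step displacements at a single lag.

    Columns: ``track``, ``start_frame``, ``lag`` (s), ``dx``, ``dy``, ``r``
    (um, ``r = sqrt(dx**2 + dy**2)``), ``mx``, ``my`` (step midpoint, um)
    and optionally ``state``.
    """

    data: pd.DataFrame
    lag: float = field(default=np.nan)

    def __post_init__(self) -> None:
        missing = {"track", "start_frame", "lag", "dx", "dy", "r", "mx", "my"} - set(
            self.data.columns
        )
        if missing:
            raise ValueError(f"missing step columns: {sorted(missing)}")
        if len(self.data) and np.isnan(self.lag):
            lags = self.data["lag"].unique()
            self.lag = float(lags[0]) if len(lags) == 1 else np.nan

    def __len__(self) -> int:
        return len(self.data)

    @property
    def r(self) -> np.ndarray:
        return self.data["r"].to_numpy(float)


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc


def read_trajectories(path, dialect: str = "native", frame_interval: float = 0.05) -> TrajectorySet:
    """Read a trajectory table.

    ``dialect='native'`` expects columns ``track,frame,x,y`` (+ optional
    ``state``, ``cell``) with positions in um. ``dialect='trackmate'``
    expects the TrackMate CSV export columns ``TRACK_ID, POSITION_X,
    POSITION_Y, FRAME`` (positions in um — TrackMate exports must be
    calibrated; no silent unit guessing is done here).

    Rows may arrive in any order; tracks are regrouped and frame-sorted.
    Duplicate (track, frame) pairs are rejected with the offending row index.
    """
    df = _read_csv(path)
    if dialect == "native":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"native trajectory file missing columns {missing}")
        keep = [c for c in [*TRACK_COLUMNS, "state", "cell"] if c in df.columns]
        df = df[keep]
    elif dialect == "trackmate":
        missing = [c for c in TRACKMATE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trackmate file missing columns {missing}")
        df = df[list(TRACKMATE_COLUMNS)].rename(columns=TRACKMATE_COLUMNS)
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")

    df = df.astype({"frame": int}).sort_values(["track", "frame"], kind="stable")
    dup = df.duplicated(subset=["track", "frame"])
    if dup.any():
        raise FormatError(f"duplicate (track, frame) at row index {df.index[dup][0]}")
    return TrajectorySet(df.reset_index(drop=True), frame_interval=frame_interval)


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write a trajectory table in the native CSV dialect (6 decimals in um)."""
    cols = [c for c in ["track", "frame", "x", "y", "state", "cell"] if c in ts.data.columns]
    ts.data[cols].to_csv(path, index=False, float_format="%.6f")


def read_localizations(path, dialect: str = "native") -> LocalizationTable:
    """Read a localization table (``native``: ``x_nm,y_nm,frame``;
    ``thunderstorm``: ``x [nm], y [nm], frame``). Coordinates stay in nm."""
    df = _read_csv(path)
    if dialect == "native":
        missing = [c for c in ("x_nm", "y_nm", "frame") if c not in df.columns]
        if missing:
            raise FormatError(f"native localization file missing columns {missing}")
        keep = [c for c in ("x_nm", "y_nm", "frame", "intensity") if c in df.columns]
        df = df[keep]
    elif dialect == "thunderstorm":
        missing = [c for c in THUNDERSTORM_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"thunderstorm file missing columns {missing}")
        rename = dict(THUNDERSTORM_COLUMNS)
        if "intensity [photon]" in df.columns:
            rename["intensity [photon]"] = "intensity"
        df = df[list(rename)].rename(columns=rename)
    else:
        raise ValueError(f"unknown localization dialect {dialect!r}")
    return LocalizationTable(df.astype({"frame": int}).reset_index(drop=True))


def write_localizations(loc: LocalizationTable, path, dialect: str = "native") -> None:
    if dialect == "native":
        loc.data.to_csv(path, index=False, float_format="%.3f")
    elif dialect == "thunderstorm":
        inv = {v: k for k, v in THUNDERSTORM_COLUMNS.items()}
        loc.data.rename(columns=inv).to_csv(path, index=False, float_format="%.3f")
    else:
        raise ValueError(f"unknown localization dialect {dialect!r}")


def filter_tracks(ts: TrajectorySet, min_points: int = 5) -> TrajectorySet:
    """Keep only tracks with at least ``min_points`` detected points.

    The default of 5 implements the "longer than four frames" input rule
    for the HMM classifier, read strictly (>4 detected points).
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    sizes = ts.data.groupby("track", sort=False)["frame"].transform("size")
    kept = ts.data[sizes >= min_points].reset_index(drop=True)
    out = replace(ts, data=kept)
    logger.info(
        "filter_tracks(min_points=%d): kept %d of %d tracks",
        min_points, out.n_tracks, ts.n_tracks,
    )
    return out
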