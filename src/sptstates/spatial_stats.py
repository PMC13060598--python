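"""PALM-style density maps, quartile density classes, step enrichment,
and Ripley's K / L cluster statistics.

The density map reproduces the super-resolution rendering convention of
32.5-nm pixels with a central crop (220 px for nuclear-interior analyses);
pixels are ranked into four equal-occupancy intensity classes, and
trajectory-step midpoints are assigned to classes to measure the
enrichment of each diffusive state in dense versus sparse chromatin
(0.25 per class = spatially random reference).

Ripley's K follows the uncorrected estimator

    K(r) = (S / (N - 1)) * (1/N) * sum_i sum_{j != i} 1[d_ij <= r],

with L(r) = sqrt(K(r) / pi). No edge correction is applied, matching the
printed estimator; K is biased low at r comparable to the window size, so
interpretation (and the test suite) is restricted to small r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracking_io import LocalizationTable, StepTable

__all__ = [
    "DensityMap",
    "EnrichmentResult",
    "RipleyResult",
    "render_density",
    "classify_density",
    "step_enrichment",
    "average_enrichment",
    "ripley_k",
    "l_function",
]

DEFAULT_PIXEL_NM = 32.5
DEFAULT_CROP_PX = 220


@dataclass
class DensityMap:
    """Pixelized localization density with optional quartile classes.

    ``counts`` is indexed ``[iy, ix]``; ``origin`` is the (x, y) position
    of the map's lower-left corner in um; ``classes`` (same shape) holds
    intensity-quartile labels 1 (sparsest) .. 4 (densest) after
    :func:`classify_density`.
    """

    counts: np.ndarray
    pixel_nm: float = DEFAULT_PIXEL_NM
    origin: tuple[float, float] = (0.0, 0.0)
    classes: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def pixel_um(self) -> float:
        return self.pixel_nm * 1e-3

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def pixel_of(self, x_um: np.ndarray, y_um: np.ndarray):
        """Map um coordinates to (iy, ix); out-of-map points get -1."""
        ix = np.floor((np.asarray(x_um) - self.origin[0]) / self.pixel_um).astype(int)
        iy = np.floor((np.asarray(y_um) - self.origin[1]) / self.pixel_um).astype(int)
        ny, nx = self.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return np.where(ok, iy, -1), np.where(ok, ix, -1)


@dataclass
class EnrichmentResult:
    """Per-state, per-density-class step fractions.

    ``table`` has columns ``state``, ``class``, ``fraction`` (and ``n``);
    fractions for each state sum to 1 over the four classes. 0.25 in every
    class is the spatially random reference.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def fractions(self, state: int) -> np.ndarray:
        sub = self.table[self.table["state"] == state].sort_values("class")
        return sub["fraction"].to_numpy()


@dataclass
class RipleyResult:
    """K and L statistics on an r grid (um; K in um^2)."""

    r: np.ndarray
    K: np.ndarray
    S: float
    N: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.K = np.asarray(self.K, float)
        if np.any(np.diff(self.K) < 0):
            raise ValueError("K must be non-decreasing in r")

    @property
    def L(self) -> np.ndarray:
        return np.sqrt(self.K / np.pi)

    @property
    def L_minus_r(self) -> np.ndarray:
        return self.L - self.r


def render_density(
    loc: LocalizationTable,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    crop_px: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
) -> DensityMap:
    """Bin localizations into a per-pixel count map.

    The full extent is binned at ``pixel_nm`` starting from ``origin``
    (um); with ``crop_px`` a centered square crop of that many pixels is
    taken (the nuclear-interior convention). ``shape`` (ny, nx) fixes the
    full grid explicitly; otherwise it is inferred from the data extent.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    xy = loc.xy_um()
    px = pixel_nm * 1e-3
    if shape is None:
        if len(xy) == 0:
            raise ValueError("cannot infer map shape from an empty table")
        nx = int(np.ceil((xy[:, 0].max() - origin[0]) / px)) or 1
        ny = int(np.ceil((xy[:, 1].max() - origin[1]) / px)) or 1
    else:
        ny, nx = shape
    ix = np.floor((xy[:, 0] - origin[0]) / px).astype(int)
    iy = np.floor((xy[:, 1] - origin[1]) / px).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(counts, (iy[ok], ix[ok]), 1)

    map_origin = origin
    if crop_px is not None:
        if crop_px <= 0 or crop_px > min(ny, nx):
            raise ValueError("crop exceeds map extent or is empty")
        y0 = (ny - crop_px) // 2
        x0 = (nx - crop_px) // 2
        counts = counts[y0 : y0 + crop_px, x0 : x0 + crop_px]
        map_origin = (origin[0] + x0 * px, origin[1] + y0 * px)
    return DensityMap(counts=counts, pixel_nm=pixel_nm, origin=map_origin)


def classify_density(dmap: DensityMap) -> DensityMap:
    """Assign intensity-quartile classes 1..4 to every pixel.

    Pixels are ranked by intensity with a stable tie-break (row-major
    order), so class occupancies are equal to within one pixel even with
    many tied values (e.g. empty pixels). A constant map is classified the
    same way but flagged ``degenerate``.
    """
    flat = dmap.counts.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(flat.size)
    classes = (ranks * 4) // flat.size + 1
    dmap.classes = classes.reshape(dmap.shape).astype(np.int8)
    dmap.degenerate = bool(flat.max() == flat.min())
    return dmap


def step_enrichment(dmap: DensityMap, steps: StepTable) -> EnrichmentResult:
    """Fraction of each state's step midpoints in each density class.

    Steps whose midpoint falls outside the (cropped) map are dropped and
    counted in ``n_dropped``. States with zero in-map steps are flagged by
    NaN fractions.
    """
    if dmap.classes is None:
        raise ValueError("density map has no class grid; run classify_density first")
    df = steps.data
    if "state" not in df.columns:
        df = df.assign(state=1)
    iy, ix = dmap.pixel_of(df["mx"].to_numpy(), df["my"].to_numpy())
    inside = iy >= 0
    n_dropped = int((~inside).sum())
    cls = np.zeros(len(df), dtype=int)
    cls[inside] = dmap.classes[iy[inside], ix[inside]]

    rows = []
    sub = df[inside].copy()
    sub["cls"] = cls[inside]
    sub = sub.dropna(subset=["state"])
    for state, grp in sub.groupby("state", sort=True):
        total = len(grp)
        for c in (1, 2, 3, 4):
            n_c = int((grp["cls"] == c).sum())
            rows.append(
                {
                    "state": int(state),
                    "class": c,
                    "n": n_c,
                    "fraction": n_c / total if total else np.nan,
                }
            )
    return EnrichmentResult(table=pd.DataFrame(rows), n_dropped=n_dropped)


def average_enrichment(results: list[EnrichmentResult]) -> EnrichmentResult:
    """Average per-state per-class fractions across datasets (cells)."""
    if not results:
        raise ValueError("no enrichment results to average")
    cat = pd.concat([r.table for r in results], ignore_index=True)
    mean = (
        cat.groupby(["state", "class"], as_index=False)
        .agg(fraction=("fraction", "mean"), n=("n", "sum"))
    )
    return EnrichmentResult(table=mean, n_dropped=sum(r.n_dropped for r in results))


def ripley_k(points: np.ndarray, area_S: float, r_grid: np.ndarray) -> RipleyResult:
    """Uncorrected Ripley's K on an r grid.

    ``points`` is (N, 2) in um; ``area_S`` the observation area in um^2.
    K(r) = (S/(N-1)) * (1/N) * #(ordered pairs with d <= r), evaluated by
    a KD-tree pair count (exactly equal to the naive double loop).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    N = len(pts)
    if N < 2:
        raise ValueError("Ripley's K needs at least 2 points")
    if area_S <= 0:
        raise ValueError("area must be positive")
    r_grid = np.asarray(r_grid, float)
    tree = cKDTree(pts)
    # count_neighbors counts ordered pairs including the N self-pairs
    pair_counts = tree.count_neighbors(tree, r_grid) - N
    K = (area_S / (N - 1)) * (pair_counts / N)
    return RipleyResult(r=r_grid, K=K, S=float(area_S), N=N)


def l_function(kr: RipleyResult) -> pd.DataFrame:
    """L(r) = sqrt(K(r)/pi) and L(r) - r as a tidy table."""
    return pd.DataFrame(
        {"r": kr.r, "K": kr.K, "L": kr.L, "L_minus_r": kr.L_minus_r}
    )
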