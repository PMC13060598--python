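"""Synthetic trajectory, point-pattern and fixed-emitter generators.

These generators produce data with the statistical structure the analysis
stages assume: 2D multi-state Brownian trajectories with Markov switching
at frame boundaries, additive white Gaussian localization error, geometric
track-length attrition, and clustered versus completely-spatially-random
(CSR) localization patterns for PALM-style spatial statistics.

Reference state models for interphase (three states: bound, liquid-like,
dissociated) and metaphase (two states) linker-histone data are provided
with the published apparent diffusion coefficients and steady-state
occupancies; the per-frame transition matrices are constructed by detailed
balance around those occupancies (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state_hmm import StateModel, stationary_distribution
from .tracking_io import LocalizationTable, TrajectorySet

__all__ = [
    "SimulationSpec",
    "PointPatternSpec",
    "simulate_tracks",
    "simulate_point_pattern",
    "simulate_fixed_emitters",
    "simulate_colocalized_tracks",
    "interphase_h1_model",
    "metaphase_h1_model",
]


def interphase_h1_model(frame_interval: float = 0.05) -> StateModel:
    """Three-state interphase model: bound / liquid-like / dissociated.

    Apparent D = 0.0354, 0.114 and 1.85 um^2/s with stationary occupancies
    0.30 / 0.60 / 0.10. The per-frame transition matrix satisfies detailed
    balance at those occupancies, with the liquid-like <-> dissociated
    exchange carrying the largest flux.
    """
    T = np.array(
        [
            [0.89, 0.10, 0.01],
            [0.05, 0.89, 0.06],
            [0.03, 0.36, 0.61],
        ]
    )
    return StateModel(D=[0.0354, 0.114, 1.85], transmat=T, frame_interval=frame_interval)


def metaphase_h1_model(frame_interval: float = 0.05) -> StateModel:
    """Two-state metaphase model: bound / liquid-like.

    Apparent D = 0.0463 and 0.125 um^2/s, occupancies 0.30 / 0.70; no
    dissociated state is present in mitotic-chromosome data.
    """
    T = np.array([[0.93, 0.07], [0.03, 0.97]])
    return StateModel(D=[0.0463, 0.125], transmat=T, frame_interval=frame_interval)


@dataclass
class SimulationSpec:
    """Conditions for a multi-state Brownian trajectory simulation.

    Parameters
    ----------
    model
        The generating :class:`~sptstates.state_hmm.StateModel`.
    n_tracks
        Number of trajectories.
    mean_track_length
        Mean number of detected points per track; lengths are
        2 + Geometric (attrition by photobleaching/defocus), minimum 2.
    frame_interval
        Seconds per frame (default 0.05 s, the live-cell recording rate).
    loc_sd
        Localization error standard deviation per axis, um
        (default 0.009 um = 9 nm, the fixed-cell precision scale).
    window
        (width, height) of the field of view in um; track starts are
        uniform in the window and diffusion is not confined to it.
    seed
        Seed for the generator; a fixed seed gives bit-reproducible output.
    """

    model: StateModel
    n_tracks: int = 1000
    mean_track_length: float = 20.0
    frame_interval: float = 0.05
    loc_sd: float = 0.009
    window: tuple[float, float] = (10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.loc_sd < 0:
            raise ValueError("loc_sd must be >= 0")
        if self.mean_track_length < 2:
            raise ValueError("mean_track_length must be >= 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.window[0] <= 0 or self.window[1] <= 0:
            raise ValueError("window must have positive extent")
        if self.model.n_states < 1:
            raise ValueError("state model must have >= 1 state")


@dataclass
class PointPatternSpec:
    """Conditions for a synthetic 2D localization point pattern.

    ``kind='csr'`` draws a homogeneous Poisson pattern with the given
    expected count. ``kind='thomas-cluster'`` draws a Thomas process:
    Poisson parents at ``parent_intensity`` per um^2, each with a
    Poisson(``mean_offspring``) number of offspring scattered with an
    isotropic Gaussian of ``cluster_sd`` um; offspring outside the window
    are discarded.
    """

    kind: str
    window: tuple[float, float]
    seed: int = 0
    expected_count: float | None = None
    parent_intensity: float | None = None
    cluster_sd: float | None = None
    mean_offspring: float | None = None

    def __post_init__(self) -> None:
        if self.window[0] <= 0 or self.window[1] <= 0:
            raise ValueError("window must have positive area")
        cluster_args = (self.parent_intensity, self.cluster_sd, self.mean_offspring)
        if self.kind == "csr":
            if self.expected_count is None or self.expected_count < 0:
                raise ValueError("csr pattern requires expected_count >= 0")
            if any(a is not None for a in cluster_args):
                raise ValueError("cluster parameters are only valid for thomas-cluster")
        elif self.kind == "thomas-cluster":
            if any(a is None for a in cluster_args):
                raise ValueError(
                    "thomas-cluster requires parent_intensity, cluster_sd, mean_offspring"
                )
            if self.parent_intensity <= 0 or self.cluster_sd < 0 or self.mean_offspring <= 0:
                raise ValueError("invalid cluster parameters")
            area = self.window[0] * self.window[1]
            if self.expected_count is None:
                self.expected_count = self.parent_intensity * area * self.mean_offspring
        else:
            raise ValueError(f"unknown pattern kind {self.kind!r}")


def _track_lengths(rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    """Geometric attrition: lengths 2 + Geometric0(p) with the given mean."""
    extra = spec.mean_track_length - 2.0
    if extra <= 0:
        return np.full(spec.n_tracks, 2, dtype=int)
    p = 1.0 / (extra + 1.0)
    # numpy geometric counts trials (support 1, 2, ...); failures = draws - 1
    return 2 + rng.geometric(p, size=spec.n_tracks) - 1


def _markov_states(
    rng: np.random.Generator, model: StateModel, lengths: np.ndarray
) -> np.ndarray:
    """Padded (n_tracks, max_steps) per-step state sequence, -1 past the end.

    The initial state of each track is drawn from the stationary
    distribution of the per-frame transition matrix; switching occurs at
    frame boundaries only.
    """
    n_steps = lengths - 1
    n, L = len(lengths), int(n_steps.max())
    k = model.n_states
    pi = stationary_distribution(model.transmat)
    cum_T = np.cumsum(model.transmat, axis=1)
    states = np.full((n, L), -1, dtype=int)
    u = rng.random((n, L))
    states[:, 0] = np.searchsorted(np.cumsum(pi), u[:, 0], side="right")
    for t in range(1, L):
        prev = states[:, t - 1]
        # vectorized row-wise inverse-CDF draw from T[prev]
        states[:, t] = (u[:, t, None] > cum_T[prev]).sum(axis=1)
    states[np.arange(L)[None, :] >= n_steps[:, None]] = -1
    return np.clip(states, -1, k - 1)


def simulate_tracks(spec: SimulationSpec) -> TrajectorySet:
    """Simulate 2D multi-state Brownian trajectories with Markov switching.

    Each per-frame step, in the state active during that frame, has
    independent Gaussian axis increments of variance ``2 * D_s * dt``;
    observed positions carry additive Gaussian localization noise of
    ``loc_sd`` per axis. Ground-truth per-step state labels (1-based,
    sorted by ascending D) are stored in the ``state`` column.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    dt = spec.frame_interval
    lengths = _track_lengths(rng, spec)
    n_steps = lengths - 1
    L = int(n_steps.max())
    states = _markov_states(rng, model, lengths)

    sigma = np.sqrt(2.0 * model.D * dt)  # per-axis step sd by state
    step_sd = np.where(states >= 0, sigma[np.clip(states, 0, None)], 0.0)
    incr = rng.standard_normal((len(lengths), L, 2)) * step_sd[:, :, None]
    starts = rng.uniform((0.0, 0.0), spec.window, size=(len(lengths), 2))
    true_pos = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(incr, axis=1)], axis=1
    )
    obs = true_pos
    if spec.loc_sd > 0:
        obs = true_pos + rng.normal(0.0, spec.loc_sd, size=true_pos.shape)

    rows = []
    for i, n_pts in enumerate(lengths):
        frames = np.arange(n_pts)
        st = np.full(n_pts, np.nan)
        st[:-1] = states[i, : n_pts - 1] + 1
        rows.append(
            pd.DataFrame(
                {
                    "track": i,
                    "frame": frames,
                    "x": obs[i, :n_pts, 0],
                    "y": obs[i, :n_pts, 1],
                    "state": st,
                }
            )
        )
    data = pd.concat(rows, ignore_index=True)
    data["t"] = data["frame"] * dt
    return TrajectorySet(data=data, frame_interval=dt)


def simulate_point_pattern(spec: PointPatternSpec) -> LocalizationTable:
    """Draw a CSR or Thomas-cluster localization pattern (output in nm)."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.window
    if spec.kind == "csr":
        n = rng.poisson(spec.expected_count)
        xy = rng.uniform((0.0, 0.0), (w, h), size=(n, 2))
    else:  # thomas-cluster
        n_parents = rng.poisson(spec.parent_intensity * w * h)
        parents = rng.uniform((0.0, 0.0), (w, h), size=(n_parents, 2))
        counts = rng.poisson(spec.mean_offspring, size=n_parents)
        centers = np.repeat(parents, counts, axis=0)
        xy = centers + rng.normal(0.0, spec.cluster_sd, size=centers.shape)
        inside = (
            (xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)
        )
        xy = xy[inside]
    df = pd.DataFrame(
        {"x_nm": xy[:, 0] * 1e3, "y_nm": xy[:, 1] * 1e3, "frame": np.arange(len(xy))}
    )
    return LocalizationTable(df)


def simulate_fixed_emitters(
    n: int,
    sd: float,
    frames: int,
    seed: int = 0,
    window: tuple[float, float] = (5.0, 5.0),
    frame_interval: float = 0.05,
) -> TrajectorySet:
    """Static emitters observed with Gaussian localization error.

    Emulates the fixed-cell precision experiment: each of ``n`` emitters is
    immobile and observed for ``frames`` frames with independent Gaussian
    error of ``sd`` um per axis around its true position.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if frames < 2:
        raise ValueError("frames must be >= 2")
    rng = np.random.default_rng(seed)
    truth = rng.uniform((0.0, 0.0), window, size=(n, 2))
    noise = (
        rng.normal(0.0, sd, size=(n, frames, 2)) if sd > 0 else np.zeros((n, frames, 2))
    )
    obs = truth[:, None, :] + noise
    data = pd.DataFrame(
        {
            "track": np.repeat(np.arange(n), frames),
            "frame": np.tile(np.arange(frames), n),
            "x": obs[:, :, 0].ravel(),
            "y": obs[:, :, 1].ravel(),
        }
    )
    return TrajectorySet(data=data, frame_interval=frame_interval)


def simulate_colocalized_tracks(
    density_map,
    spec: SimulationSpec,
    coupling: np.ndarray,
) -> TrajectorySet:
    """Simulate tracks whose start positions prefer dense map pixels.

    For each track the dominant (most frequent ground-truth) state s sets
    a placement weight: the start pixel is drawn with probability
    proportional to ``pixel density ** coupling[s]`` (with 0**0 = 1). A
    coupling of 0 for every state gives spatially uniform starts, the
    random-reference condition in which each density-quartile class
    captures 25% of steps.
    """
    coupling = np.asarray(coupling, float)
    if coupling.shape != (spec.model.n_states,):
        raise ValueError("one coupling weight per model state is required")
    if np.any(coupling < 0):
        raise ValueError("coupling weights must be >= 0")

    ts = simulate_tracks(spec)
    rng = np.random.default_rng([spec.seed, 1])

    counts = density_map.counts.astype(float)
    ny, nx = counts.shape
    px = density_map.pixel_nm * 1e-3  # um
    ox, oy = density_map.origin

    data = ts.data.copy()
    for track, sub in data.groupby("track", sort=False):
        st = sub["state"].dropna().to_numpy(int)
        dominant = np.bincount(st - 1, minlength=spec.model.n_states).argmax()
        wgt = counts ** coupling[dominant]
        p = (wgt / wgt.sum()).ravel()
        pix = rng.choice(counts.size, p=p)
        iy, ix = divmod(pix, nx)
        start = np.array(
            [ox + (ix + rng.random()) * px, oy + (iy + rng.random()) * px]
        )
        idx = sub.index
        shift = start - sub[["x", "y"]].iloc[0].to_numpy()
        data.loc[idx, ["x", "y"]] = sub[["x", "y"]].to_numpy() + shift
    return TrajectorySet(data=data, frame_interval=spec.frame_interval)
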