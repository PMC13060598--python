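"""Hidden-Markov classification of trajectories into diffusive states.

Each trajectory step (displacement between consecutive frames) is modelled
as a zero-mean isotropic 2D Gaussian whose per-axis variance is 2*D_s*dt
for the hidden state s active during that frame. States switch at frame
boundaries following a row-stochastic per-frame transition matrix.
Parameters are estimated by maximum-likelihood Baum-Welch EM with
multi-start, and the number of states is chosen by BIC. This mirrors the
input/output contract of variational-Bayes SPT classifiers (trajectory
tables in, per-state D, per-frame transition percentages and per-step
annotations out) with a maximum-likelihood backend.

States are always reported sorted by ascending D, so for linker-histone
data the ordering bound < liquid-like < dissociated is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking_io import TrajectorySet

__all__ = [
    "StateModel",
    "StateAnnotation",
    "fit_state_model",
    "select_n_states",
    "annotate_states",
    "split_by_state",
    "stationary_distribution",
]

_TINY = 1e-300


def stationary_distribution(transmat: np.ndarray) -> np.ndarray:
    """Stationary row vector pi with pi @ T = pi, by eigen-decomposition."""
    T = np.asarray(transmat, float)
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class StateModel:
    """A fitted (or specified) multi-state free-diffusion model.

    Attributes
    ----------
    D
        Per-state diffusion coefficients, um^2/s, ascending.
    transmat
        Row-stochastic per-frame transition matrix; ``transmat[i, j]`` is
        the probability of switching from state i to state j in one frame.
    frame_interval
        Frame interval dt in seconds.
    occupancy
        Stationary distribution of ``transmat`` (computed if omitted).
    startprob
        Initial-state distribution (defaults to the stationary one).
    """

    D: np.ndarray
    transmat: np.ndarray
    frame_interval: float
    occupancy: np.ndarray | None = None
    startprob: np.ndarray | None = None
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = True
    seed: int | None = None
    bic: float = np.nan

    def __post_init__(self) -> None:
        self.D = np.atleast_1d(np.asarray(self.D, float))
        self.transmat = np.atleast_2d(np.asarray(self.transmat, float))
        k = len(self.D)
        if self.transmat.shape != (k, k):
            raise ValueError("transition matrix shape does not match state count")
        if np.any(self.D < 0):
            raise ValueError("negative diffusion coefficient")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.any(self.transmat < 0) or not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.occupancy is None:
            self.occupancy = stationary_distribution(self.transmat)
        else:
            self.occupancy = np.asarray(self.occupancy, float)
        if self.startprob is None:
            self.startprob = self.occupancy.copy()
        else:
            self.startprob = np.asarray(self.startprob, float)

    @property
    def n_states(self) -> int:
        return len(self.D)

    def step_variance(self) -> np.ndarray:
        """Per-axis Gaussian step variance 2*D*dt for each state, um^2."""
        return 2.0 * self.D * self.frame_interval

    def summary(self) -> dict:
        return {
            "n_states": self.n_states,
            "D_um2_per_s": self.D.tolist(),
            "transition_percent_per_frame": (100.0 * self.transmat).tolist(),
            "occupancy": self.occupancy.tolist(),
            "frame_interval_s": self.frame_interval,
            "log_likelihood": float(self.log_likelihood),
            "bic": float(self.bic),
            "converged": bool(self.converged),
        }


@dataclass
class StateAnnotation:
    """Viterbi state labels and posteriors for every step of a TrajectorySet.

    ``steps`` has one row per step: ``track``, ``start_frame``, ``state``
    (1-based most-probable label) and ``p1..pk`` posterior columns.

    ``occupancy_fractions`` is the posterior-expected fraction of steps in
    each state (mean of the per-step posteriors), the standard occupancy
    estimator: hard most-probable-path shares (``viterbi_fractions``)
    systematically overcount the dominant state when emissions overlap,
    by several percentage points for state D ratios around 3.
    """

    steps: pd.DataFrame
    n_states: int
    occupancy_fractions: np.ndarray = field(init=False)
    viterbi_fractions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.bincount(self.steps["state"].to_numpy(int) - 1, minlength=self.n_states)
        total = max(counts.sum(), 1)
        self.viterbi_fractions = counts / total
        post_cols = [f"p{s + 1}" for s in range(self.n_states)]
        if all(c in self.steps.columns for c in post_cols):
            self.occupancy_fractions = self.steps[post_cols].to_numpy().mean(axis=0)
        else:
            self.occupancy_fractions = self.viterbi_fractions.copy()

    @property
    def state_counts(self) -> np.ndarray:
        return np.bincount(self.steps["state"].to_numpy(int) - 1, minlength=self.n_states)


# ---------------------------------------------------------------------------
# packed step representation


def _pack_steps(ts: TrajectorySet):
    """Pack per-track squared step lengths into a padded (n_tracks, L) array.

    Only consecutive-frame steps enter the likelihood; a gap in the frame
    numbering splits a track into separate segments.
    """
    df = ts.data.sort_values(["track", "frame"], kind="stable")
    track = df["track"].to_numpy()
    frame = df["frame"].to_numpy(int)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    same = track[1:] == track[:-1]
    consec = same & (np.diff(frame) == 1)
    dx = np.diff(x)[consec]
    dy = np.diff(y)[consec]
    r2 = dx * dx + dy * dy

    # segment boundaries: start a new segment wherever consec is False
    seg_id = np.concatenate([[0], np.cumsum(~consec)])[:-1][consec]
    # relabel to consecutive ids
    _, seg = np.unique(seg_id, return_inverse=True)
    n_seg = seg.max() + 1 if len(seg) else 0
    lengths = np.bincount(seg, minlength=n_seg)
    L = lengths.max() if n_seg else 0
    packed = np.zeros((n_seg, L))
    pos = np.concatenate([[0], np.cumsum(lengths)])
    # steps arrive in segment order, so the within-segment index is just
    # the global index minus the segment's start offset
    col = np.arange(len(seg)) - pos[seg]
    packed[seg, col] = r2
    mask = np.zeros((n_seg, L), bool)
    mask[seg, col] = True
    meta = pd.DataFrame(
        {
            "track": track[:-1][consec],
            "start_frame": frame[:-1][consec],
            "segment": seg,
            "pos": col,
        }
    )
    return packed, mask, meta


def _log_emission(r2: np.ndarray, mask: np.ndarray, D: np.ndarray, dt: float) -> np.ndarray:
    """log p(step | state) for packed squared displacements.

    p(dx, dy | s) = exp(-r^2 / (4 D_s dt)) / (4 pi D_s dt).
    """
    var = np.maximum(4.0 * D * dt, 1e-12)  # = 2 sigma^2 per axis pair
    ll = -(r2[..., None] / var) - np.log(np.pi * var)
    ll[~mask] = 0.0  # padding contributes nothing
    return ll


def _forward_backward(logB, mask, startprob, transmat):
    """Scaled batch forward-backward over padded segments.

    Returns (gamma, xi_sum, loglik). ``gamma`` is (n_seg, L, k) posteriors,
    ``xi_sum`` the (k, k) expected transition counts summed over all
    segments and times, ``loglik`` the total log-likelihood.
    """
    n_seg, L, k = logB.shape
    B = np.exp(logB - logB.max(axis=2, keepdims=True))
    logBmax = logB.max(axis=2)
    logBmax[~mask] = 0.0
    alpha = np.zeros((n_seg, L, k))
    c = np.ones((n_seg, L))  # scaling factors
    a = startprob * B[:, 0, :]
    c[:, 0] = a.sum(axis=1) + _TINY
    alpha[:, 0, :] = a / c[:, 0, None]
    for t in range(1, L):
        a = (alpha[:, t - 1, :] @ transmat) * B[:, t, :]
        live = mask[:, t]
        c[live, t] = a[live].sum(axis=1) + _TINY
        alpha[:, t, :] = np.where(live[:, None], a / c[:, t, None], alpha[:, t - 1, :])
    beta = np.zeros((n_seg, L, k))
    lengths = mask.sum(axis=1)
    beta[np.arange(n_seg), lengths - 1, :] = 1.0
    for t in range(L - 2, -1, -1):
        live = mask[:, t + 1]
        b = (beta[:, t + 1, :] * B[:, t + 1, :]) @ transmat.T / c[:, t + 1, None]
        beta[:, t, :] = np.where(live[:, None], b, beta[:, t, :])
        # positions at the end of shorter segments keep their initialized value

    gamma = alpha * beta
    gamma[~mask] = 0.0
    norm = gamma.sum(axis=2, keepdims=True)
    np.divide(gamma, norm, out=gamma, where=norm > 0)

    # xi_sum[i, j] = sum_t alpha_t(i) T_ij B_{t+1}(j) beta_{t+1}(j) / c_{t+1}
    xi_sum = np.zeros((k, k))
    for t in range(L - 1):
        live = mask[:, t + 1]
        if not live.any():
            break
        left = alpha[live, t, :]
        right = (B[live, t + 1, :] * beta[live, t + 1, :]) / c[live, t + 1, None]
        xi_sum += (left[:, :, None] * transmat[None, :, :] * right[:, None, :]).sum(axis=0)

    loglik = float(np.log(c[mask]).sum() + logBmax[mask].sum())
    return gamma, xi_sum, loglik


def _em_once(r2, mask, k, dt, rng, max_iter, tol):
    """One EM run from a random start; returns (D, T, pi0, loglik, n_iter, conv, history)."""
    vals = r2[mask]
    # initialize D from jittered quantiles of r^2/(4 dt)
    qs = np.quantile(vals, (np.arange(k) + 0.5) / k)
    D = np.maximum(qs / (4.0 * dt) * rng.uniform(0.5, 2.0, size=k), 1e-8)
    D.sort()
    T = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(T, 0.9)
    T = T * rng.uniform(0.8, 1.2, size=(k, k))
    T /= T.sum(axis=1, keepdims=True)
    pi0 = np.full(k, 1.0 / k)

    prev = -np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logB = _log_emission(r2, mask, D, dt)
        gamma, xi_sum, loglik = _forward_backward(logB, mask, pi0, T)
        history.append(loglik)
        if loglik - prev < tol * (1 + abs(loglik)) and it > 1:
            converged = True
            break
        prev = loglik
        # M-step
        w = gamma[mask]  # (n_steps, k)
        denom = w.sum(axis=0) + _TINY
        D = (w * vals[:, None]).sum(axis=0) / (4.0 * dt * denom)
        D = np.maximum(D, 1e-10)
        rows = xi_sum.sum(axis=1, keepdims=True)
        T = np.where(rows > 0, xi_sum / (rows + _TINY), T)
        T /= T.sum(axis=1, keepdims=True)
        first = gamma[:, 0, :][mask[:, 0]]
        pi0 = first.sum(axis=0) / (first.sum() + _TINY)
    return D, T, pi0, history[-1], it, converged, history


def fit_state_model(
    ts: TrajectorySet,
    n_states: int,
    dt: float | None = None,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
    n_restarts: int = 10,
) -> StateModel:
    """Fit an ``n_states`` free-diffusion HMM to trajectory steps by EM.

    Runs ``n_restarts`` seeded EM starts and keeps the best log-likelihood
    (ties broken by lowest restart index). The returned model has states
    sorted by ascending D; ``occupancy`` is the stationary distribution of
    the fitted per-frame transition matrix.

    Localization noise is not an emission parameter: the fitted D values
    are apparent diffusion coefficients.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    dt = ts.frame_interval if dt is None else dt
    r2, mask, _ = _pack_steps(ts)
    if mask.sum() == 0:
        raise ValueError("no consecutive-frame steps in trajectory set")

    best = None
    for j in range(n_restarts):
        rng = np.random.default_rng([seed, j])
        out = _em_once(r2, mask, n_states, dt, rng, max_iter, tol)
        if best is None or out[3] > best[3]:
            best = out
    D, T, pi0, loglik, n_iter, converged, _ = best

    order = np.argsort(D)
    D = D[order]
    T = T[np.ix_(order, order)]
    pi0 = pi0[order]
    n_steps = int(mask.sum())
    n_params = (n_states - 1) + n_states * (n_states - 1) + n_states
    bic = n_params * np.log(max(n_steps, 1)) - 2.0 * loglik
    return StateModel(
        D=D,
        transmat=T,
        frame_interval=dt,
        startprob=pi0,
        log_likelihood=loglik,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        bic=bic,
    )


def select_n_states(
    ts: TrajectorySet,
    max_states: int = 3,
    dt: float | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    **kwargs,
) -> StateModel:
    """Fit 1..max_states models and return the BIC-best one.

    ``max_states`` plays the role of the analysis state cap (3 for
    interphase, 2 for metaphase data). All candidate scores are attached
    to the returned model as ``candidate_bic``.
    """
    if not 1 <= max_states <= 6:
        raise ValueError("max_states must be in 1..6")
    candidates = [
        fit_state_model(ts, k, dt=dt, seed=seed, n_restarts=n_restarts, **kwargs)
        for k in range(1, max_states + 1)
    ]
    scores = [m.bic for m in candidates]
    best = candidates[int(np.argmin(scores))]
    best.candidate_bic = {m.n_states: m.bic for m in candidates}
    return best


def annotate_states(model: StateModel, ts: TrajectorySet, dt: float | None = None) -> StateAnnotation:
    """Viterbi-decode the most probable state path for every step.

    Returns 1-based labels (1 = slowest state) together with the
    forward-backward posterior probability of each state per step.
    """
    dt = ts.frame_interval if dt is None else dt
    if not np.isclose(dt, model.frame_interval):
        raise ValueError(
            f"frame interval mismatch: model {model.frame_interval} s vs data {dt} s"
        )
    r2, mask, meta = _pack_steps(ts)
    k = model.n_states
    logB = _log_emission(r2, mask, model.D, dt)
    logT = np.log(model.transmat + _TINY)
    logpi = np.log(model.startprob + _TINY)

    n_seg, L, _ = logB.shape
    delta = np.full((n_seg, L, k), -np.inf)
    psi = np.zeros((n_seg, L, k), dtype=np.int64)
    delta[:, 0, :] = logpi + logB[:, 0, :]
    for t in range(1, L):
        cand = delta[:, t - 1, :, None] + logT[None, :, :]
        psi[:, t, :] = cand.argmax(axis=1)
        step = cand.max(axis=1) + logB[:, t, :]
        live = mask[:, t]
        delta[:, t, :] = np.where(live[:, None], step, delta[:, t - 1, :])
        psi[:, t, :] = np.where(live[:, None], psi[:, t, :], np.arange(k)[None, :])

    lengths = mask.sum(axis=1)
    path = np.zeros((n_seg, L), dtype=np.int64)
    last = lengths - 1
    path[np.arange(n_seg), last] = delta[np.arange(n_seg), last, :].argmax(axis=1)
    for t in range(L - 2, -1, -1):
        nxt = path[:, t + 1]
        back = psi[np.arange(n_seg), t + 1, nxt]
        use = t + 1 <= last  # only backtrack inside the segment
        path[:, t] = np.where(use, back, path[:, t])

    gamma, _, _ = _forward_backward(logB, mask, model.startprob, model.transmat)
    seg, pos = meta["segment"].to_numpy(), meta["pos"].to_numpy()
    steps = meta[["track", "start_frame"]].copy()
    steps["state"] = path[seg, pos] + 1
    post = gamma[seg, pos, :]
    for s in range(k):
        steps[f"p{s + 1}"] = post[:, s]
    return StateAnnotation(steps=steps.reset_index(drop=True), n_states=k)


def split_by_state(
    ts: TrajectorySet,
    ann: StateAnnotation,
    min_points: int = 2,
    msd_lags: np.ndarray | None = None,
):
    """Split trajectories into per-state sub-tracks and per-state MSD curves.

    Maximal runs of consecutive steps sharing one Viterbi label, spanning
    at least ``min_points`` positions, become sub-tracks of that state.
    Returns ``(per_state_sets, per_state_msd)`` dicts keyed by 1-based
    state; states with no surviving sub-track map to ``None`` (flagged by
    absence rather than an empty set). MSD defaults to lags 0.05-0.5 s,
    the per-state analysis range.
    """
    from .msd_analysis import compute_msd

    sets: dict[int, TrajectorySet | None] = {}
    rows = {s: [] for s in range(1, ann.n_states + 1)}
    df = ts.data.sort_values(["track", "frame"], kind="stable").reset_index(drop=True)
    lab = dict(
        zip(
            zip(ann.steps["track"], ann.steps["start_frame"]),
            ann.steps["state"],
        )
    )

    sub_id = 0
    for track, sub in df.groupby("track", sort=False):
        frames = sub["frame"].to_numpy()
        states = np.array(
            [lab.get((track, f), -1) for f in frames[:-1]], dtype=int
        )  # -1 where the step was not annotated (frame gap)
        # run boundaries
        start = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[start]:
                s = states[start]
                n_pts = i - start + 1
                if s > 0 and n_pts >= min_points:
                    piece = sub.iloc[start : i + 1].copy()
                    piece["track"] = f"{track}/s{s}/{sub_id}"
                    rows[int(s)].append(piece)
                    sub_id += 1
                start = i

    msds: dict[int, object] = {}
    dt = ts.frame_interval
    if msd_lags is None:
        msd_lags = np.arange(1, 11) * dt  # 0.05-0.5 s at 50-ms frames
        msd_lags = msd_lags[msd_lags <= 0.5 + 1e-9]
    for s, pieces in rows.items():
        if not pieces:
            sets[s] = None
            msds[s] = None
            continue
        sets[s] = TrajectorySet(
            pd.concat(pieces, ignore_index=True), frame_interval=dt, cell=ts.cell
        )
        msds[s] = compute_msd(sets[s], lags=msd_lags)
    return sets, msds
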