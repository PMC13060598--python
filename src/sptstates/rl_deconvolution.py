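"""Richardson-Lucy deconvolution of displacement distributions.

The self-part of the van Hove correlation of 2D displacements at lag dt,
Gs(r, dt), is a superposition of Gaussian displacement kernels

    q(r, M) = exp(-r^2 / M) / (pi * M),

one per single-molecule 2D MSD value M = 4 D dt. The multiplicative RL
iteration inverts this superposition to recover the distribution P(M):

    P_{n+1}(M) = P_n(M) * int 2 pi r q(r, M) Gs(r) / Gs_n(r) dr,
    Gs_n(r)    = int q(r, M) P_n(M) dM,

with P_{n+1} >= 0 and int P_{n+1} dM = 1 enforced at every iterate. Both
Gs and Gs_n are represented as planar (2D) densities so the ratio in the
update is convention-consistent. The number of diffusive states is then
read off by fitting a Gaussian mixture over log10 M and counting
well-separated components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .tracking_io import StepTable

__all__ = [
    "VanHoveCurve",
    "MSDDistribution",
    "StateMixture",
    "build_van_hove",
    "rl_deconvolve",
    "fit_log_mixture",
    "count_states",
    "displacement_kernel",
]


def displacement_kernel(r: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Planar displacement kernel q(r, M) = exp(-r^2/M) / (pi M).

    For 2D Brownian steps with single-molecule MSD M, the displacement
    magnitude is Rayleigh; q is the corresponding planar (per-unit-area)
    density, normalized as int q 2 pi r dr = 1.
    """
    r = np.asarray(r, float)[:, None]
    M = np.asarray(M, float)[None, :]
    return np.exp(-(r**2) / M) / (np.pi * M)


@dataclass
class VanHoveCurve:
    """Binned van Hove self-correlation at a single lag.

    ``gs`` is the planar density per bin: counts / (N * 2 pi r_c dr),
    normalized so that sum(gs * 2 pi r_c dr) = 1.
    """

    lag: float
    r_edges: np.ndarray
    gs: np.ndarray
    n_steps: int

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, float)
        self.gs = np.asarray(self.gs, float)
        if np.any(self.gs < 0):
            raise ValueError("Gs must be non-negative")
        if abs(self.normalization() - 1.0) > 1e-6:
            raise ValueError("Gs planar normalization violated")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def bin_measure(self) -> np.ndarray:
        """Radial integration measure 2 pi r_c dr per bin."""
        return 2.0 * np.pi * self.r_centers * np.diff(self.r_edges)

    def normalization(self) -> float:
        return float(np.sum(self.gs * self.bin_measure))


@dataclass
class MSDDistribution:
    """RL output: density P over the single-molecule 2D MSD variable M."""

    M: np.ndarray
    P: np.ndarray
    M0: float
    n_iter: int
    converged: bool
    kl_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, float)
        self.P = np.asarray(self.P, float)
        if np.any(self.P < 0):
            raise ValueError("P must be non-negative")
        if abs(self.integral() - 1.0) > 1e-6:
            raise ValueError("P must integrate to 1 on its grid")

    def quadrature_weights(self) -> np.ndarray:
        return trapezoid_weights(self.M)

    def integral(self) -> float:
        return float(np.sum(self.P * trapezoid_weights(self.M)))


@dataclass
class StateMixture:
    """Gaussian mixture over log10 M fitted to an MSD distribution."""

    weights: np.ndarray
    means: np.ndarray  # log10 M
    sds: np.ndarray  # log10 M
    scores: dict[int, float]  # BIC per candidate k

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be a distribution")
        if self.k < 1:
            raise ValueError("mixture needs at least one component")

    @property
    def k(self) -> int:
        return len(self.weights)


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights on an arbitrary (e.g. log-spaced) grid."""
    x = np.asarray(x, float)
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += 0.5 * dx
    w[1:] += 0.5 * dx
    return w


def build_van_hove(
    steps: StepTable, dt: float | None = None, r_max: float | None = None, n_bins: int = 200
) -> VanHoveCurve:
    """Histogram step magnitudes into a planar van Hove density.

    Linear bins on [0, r_max]; each bin's density is
    count / (N * 2 pi r_c dr) with N the number of steps retained
    (steps beyond ``r_max`` are dropped and N adjusted, keeping the
    normalization invariant exact).
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if len(steps) == 0:
        raise ValueError("no steps to histogram")
    if dt is not None and not np.isnan(steps.lag) and not np.isclose(dt, steps.lag):
        raise ValueError(f"steps are at lag {steps.lag} s, not {dt} s")
    lag = steps.lag if dt is None else dt
    r = steps.r
    if r_max is None:
        r_max = float(r.max()) * 1.0001 + 1e-12
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    n_used = int(counts.sum())
    if n_used == 0:
        raise ValueError("all steps fall outside [0, r_max]")
    r_c = 0.5 * (edges[1:] + edges[:-1])
    dr = np.diff(edges)
    gs = counts / (n_used * 2.0 * np.pi * r_c * dr)
    return VanHoveCurve(lag=lag, r_edges=edges, gs=gs, n_steps=n_used)


def forward_model(vh_r: np.ndarray, M: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Gs_n(r) = int q(r, M) P(M) dM on the given grids (planar density)."""
    Q = displacement_kernel(vh_r, M)
    return Q @ (P * trapezoid_weights(M))


def rl_deconvolve(
    vh: VanHoveCurve,
    M_grid: np.ndarray | None = None,
    M0: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 20000,
    P_init: np.ndarray | None = None,
) -> MSDDistribution:
    """Recover P(M) from a van Hove curve by Richardson-Lucy iteration.

    Starts from the exponential initial estimate P0(M) = exp(-M/M0)/M0
    (results are insensitive to M0 over decades); iterates the
    multiplicative update with the discrete kernel column-normalized so
    that an exact forward model is an exact fixed point; renormalizes and
    clips every iterate; stops when the quadrature L1 difference between
    successive iterates falls below ``tol``. RL sharpens slowly once the
    peak positions are settled, so the iteration cap (20000) is usually
    what terminates it on real-size data; the ``converged`` flag records
    which happened.

    The default M grid is log-spaced, 120 points over [1e-5, 10] um^2,
    wide enough for peaks spanning several decades of M = 4 D dt.
    """
    if M_grid is None:
        M_grid = np.geomspace(1e-5, 10.0, 120)
    M = np.asarray(M_grid, float)
    if np.any(M <= 0):
        raise ValueError("M grid must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")

    wM = trapezoid_weights(M)
    r_c = vh.r_centers
    u = vh.bin_measure  # 2 pi r dr
    Q = displacement_kernel(r_c, M)  # (n_r, n_M)
    # discrete column normalization: c_j = int 2 pi r q(r, M_j) dr ~ 1
    c = u @ Q
    if np.any(c <= 0):
        raise ValueError("r grid does not cover the kernel support for some M")

    if P_init is None:
        P = np.exp(-M / M0) / M0
    else:
        P = np.asarray(P_init, float).copy()
        if P.shape != M.shape or np.any(P < 0):
            raise ValueError("P_init must be a non-negative density on the M grid")
    P = P / np.sum(P * wM)
    gs = vh.gs
    pos = gs > 0

    kl_history = []
    converged = False
    n_done = max_iter
    for it in range(1, max_iter + 1):
        gs_n = Q @ (P * wM)
        if np.any(gs_n[pos] <= 0):
            raise ValueError(
                "model density vanished where data is positive; widen the M grid"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            kl = float(np.sum(u[pos] * gs[pos] * np.log(gs[pos] / gs_n[pos])))
        kl_history.append(kl)
        ratio = np.where(pos, gs / np.where(gs_n > 0, gs_n, 1.0), 0.0)
        mult = (u * ratio) @ Q / c
        P_new = np.clip(P * mult, 0.0, None)
        total = np.sum(P_new * wM)
        if total <= 0:
            raise ValueError("RL iterate lost all mass; check inputs")
        P_new /= total
        l1 = float(np.sum(np.abs(P_new - P) * wM))
        P = P_new
        if l1 < tol:
            converged = True
            n_done = it
            break
    return MSDDistribution(
        M=M, P=P, M0=M0, n_iter=n_done, converged=converged,
        kl_history=np.asarray(kl_history),
    )


def fit_log_mixture(
    dist: MSDDistribution,
    k_max: int = 4,
    seed: int = 0,
    n_samples: int = 20000,
) -> StateMixture:
    """Fit a Gaussian mixture over log10 M to the deconvolved P(M).

    The grid density is converted to a seeded weighted resample of
    ``n_samples`` log10 M values (with uniform within-cell jitter), and
    mixtures with 1..k_max components are fitted; the BIC-best one is
    returned. Deterministic for a fixed seed.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    w = dist.P * dist.quadrature_weights()
    support = w > 0
    if support.sum() <= 1:
        # degenerate single-point distribution: one component, zero width
        m = float(np.log10(dist.M[np.argmax(w)]))
        return StateMixture(
            weights=np.array([1.0]), means=np.array([m]),
            sds=np.array([0.0]), scores={1: np.nan},
        )
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(dist.M), size=n_samples, p=p)
    logM = np.log10(dist.M)
    # jitter uniformly within each grid cell (log-spaced -> uniform in log10)
    cell = np.gradient(logM)
    samples = logM[idx] + rng.uniform(-0.5, 0.5, size=n_samples) * cell[idx]
    X = samples[:, None]

    fits = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=int(rng.integers(2**31 - 1)),
            n_init=3,
            reg_covar=1e-6,
        ).fit(X)
        fits[k] = (gm.bic(X), gm)
    best_k = min(fits, key=lambda k: fits[k][0])
    gm = fits[best_k][1]
    order = np.argsort(gm.means_.ravel())
    return StateMixture(
        weights=gm.weights_.ravel()[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        scores={k: v[0] for k, v in fits.items()},
    )


def count_states(
    mix: StateMixture, min_separation: float = 0.15, min_weight: float = 0.02
) -> int:
    """Number of distinct diffusive states in a fitted mixture.

    Components carrying less than ``min_weight`` of the mass are ignored
    (a vanishing-weight component fitted to an empty tail is not a
    state), then components whose log10 M means differ by less than
    ``min_separation`` decades are merged (single-linkage along the
    sorted means), so near-duplicate components fitted to one peak do
    not inflate the count.
    """
    keep = mix.weights >= min_weight
    means = np.sort(mix.means[keep]) if keep.any() else np.sort(mix.means)
    if len(means) == 1:
        return 1
    gaps = np.diff(means)
    return int(1 + np.sum(gaps >= min_separation))
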