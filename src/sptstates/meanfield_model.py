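"""Mean-field lattice model of linker-histone (H1) / nucleosome binding.

A Flory-Huggins-style lattice of N0 sites carries N nucleosomes arranged
in chains of K; an H1 molecule is either stably bound at a nucleosome
dyad (count n, binding energy -(eps + delta)), dynamically bound near the
dyad (count m, energy -eps, plus a multivalent coupling -J to neighboring
nucleosomes), or free (chemical potential mu). All energies are in kB*T
units (kB*T = 1 internally). The mean-field energy is

    E(m, n; N) = -J m [1 - (1 - N/N0)^z] - (mu + eps) m - (mu + eps + delta) n

and the entropy S = S_nucl-chain + S_H1 + S_multivalent comes from the
Stirling forms of the lattice multiplicities (0 log 0 := 0):

    S_nucl-chain = -[N0 (1 - N/N0) log(1 - N/N0) + (N/K) log(N/N0)]
    S_H1         = -[m log(m/N0) + n log(n/N0)
                     + (N - m - n) log((N - m - n)/N0)]
    S_multivalent = m log(z N / N0)

S_H1 references each species' count to the lattice size N0 (dilute-mixing
convention); it equals the Stirling form of log[N!/(n! m! (N-m-n)!)] plus
N log(N0/N), a term independent of (m, n) at fixed N, so the choice of
reference shifts f by a constant and leaves the landscape minimizer
unchanged.

The free energy per lattice site is f = (E - T S) / N0. The landscape is
examined over the binding ratio b = (n + m)/N and the mobile fraction
x = m/(n + m); under nucleosome-dense conditions with the reference
parameter set (K = 1000, z = 6, delta = 1.5, eps = mu = J = 1) the
minimizer has x* > 0.5: the majority of bound H1 is in the dynamic
(mobile, liquid-like) mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

__all__ = [
    "MeanFieldParams",
    "MeanFieldState",
    "FreeEnergyLandscape",
    "mf_energy",
    "mf_entropy",
    "mf_free_energy",
    "mf_landscape",
    "PAPER_PARAMS",
]


@dataclass(frozen=True)
class MeanFieldParams:
    """Lattice-model constants; all energies in kB*T.

    K: nucleosomes per chromatin chain; z: neighbor coordination number;
    J: multivalent coupling; eps: dynamic binding energy; delta: extra
    stabilization of dyad binding; mu: chemical potential of free H1.
    """

    K: int = 1000
    z: int = 6
    J: float = 1.0
    eps: float = 1.0
    delta: float = 1.5
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1 or int(self.K) != self.K:
            raise ValueError("K must be a positive integer")
        if self.z < 1 or int(self.z) != self.z:
            raise ValueError("z must be a positive integer")
        if self.J < 0 or self.eps < 0 or self.delta < 0:
            raise ValueError("J, eps, delta must be >= 0")


#: the reference parameter set of the free-energy analysis
PAPER_PARAMS = MeanFieldParams()


@dataclass
class MeanFieldState:
    """Occupation numbers: N0 lattice sites, N nucleosomes, m dynamically
    bound H1, n stably (dyad-)bound H1. Continuous values are allowed for
    the relaxed landscape; invariants 0 <= N <= N0, m, n >= 0, m + n <= N."""

    N0: float
    N: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if not (0 <= self.N <= self.N0):
            raise ValueError("need 0 <= N <= N0")
        if self.m < 0 or self.n < 0:
            raise ValueError("m and n must be >= 0")
        if self.m + self.n > self.N * (1 + 1e-12):
            raise ValueError("m + n cannot exceed N")

    @property
    def rho(self) -> float:
        return self.N / self.N0


def mf_energy(state: MeanFieldState, params: MeanFieldParams) -> float:
    """Mean-field energy E(m, n; N), kB*T."""
    rho = state.rho
    multivalent = -params.J * state.m * (1.0 - (1.0 - rho) ** params.z)
    return float(
        multivalent
        - (params.mu + params.eps) * state.m
        - (params.mu + params.eps + params.delta) * state.n
    )


def mf_entropy(state: MeanFieldState, params: MeanFieldParams) -> tuple[float, float, float]:
    """The three entropy components (S_nucl-chain, S_H1, S_multivalent), kB.

    Stirling forms with the 0 log 0 := 0 convention (handled by xlogy);
    at N = N0 the (1 - rho) log(1 - rho) chain term vanishes by that
    convention.
    """
    N0, N, m, n = state.N0, state.N, state.m, state.n
    rho = state.rho
    s_nucl_chain = -(N0 * xlogy(1.0 - rho, 1.0 - rho) + (N / params.K) * np.log(rho)) if N > 0 else 0.0
    free_sites = N - m - n
    s_h1 = -(
        xlogy(m, m / N0) + xlogy(n, n / N0) + xlogy(free_sites, free_sites / N0)
    )
    s_multi = m * np.log(params.z * rho) if m > 0 else 0.0
    return float(s_nucl_chain), float(s_h1), float(s_multi)


def mf_free_energy(state: MeanFieldState, params: MeanFieldParams) -> float:
    """Free energy per lattice site f = (E - T*S)/N0 with kB*T = 1."""
    E = mf_energy(state, params)
    S = sum(mf_entropy(state, params))
    return float((E - S) / state.N0)


@dataclass
class FreeEnergyLandscape:
    """f(b, x) over binding ratio b = (n+m)/N and mobile fraction x = m/(n+m).

    ``f`` is indexed ``[i_b, i_x]``; the argmin ``(b_star, x_star)`` is
    refined off-grid; ``on_boundary`` flags a minimizer on the grid edge.
    """

    b: np.ndarray
    x: np.ndarray
    f: np.ndarray
    rho: float
    params: MeanFieldParams
    b_star: float
    x_star: float
    f_star: float
    on_boundary: bool


def _intensive_f(b: np.ndarray, x: np.ndarray, rho: float, p: MeanFieldParams):
    """f per site as a function of (b, x) at nucleosome density rho.

    Uses the intensive densities mt = m/N0 = b*x*rho, nt = n/N0; every
    term of E and S is proportional to N0 in the Stirling forms, so f per
    site is independent of N0.
    """
    mt = b * x * rho
    nt = b * (1.0 - x) * rho
    # unbound-nucleosome density (N - m - n)/N0; clip the float-roundoff
    # negatives that appear at b = 1 where it vanishes exactly
    ft = np.maximum(rho - mt - nt, 0.0)
    e = (
        -p.J * mt * (1.0 - (1.0 - rho) ** p.z)
        - (p.mu + p.eps) * mt
        - (p.mu + p.eps + p.delta) * nt
    )
    s_nucl_chain = -(xlogy(1.0 - rho, 1.0 - rho) + (rho / p.K) * np.log(rho))
    s_h1 = -(xlogy(mt, mt) + xlogy(nt, nt) + xlogy(ft, ft))
    s_multi = mt * np.log(p.z * rho)
    return e - (s_nucl_chain + s_h1 + s_multi)


def mf_landscape(
    params: MeanFieldParams,
    rho: float,
    resolution: int = 200,
) -> FreeEnergyLandscape:
    """Evaluate f on a (b, x) grid and locate the global minimum.

    ``b`` spans (0, 1] and ``x`` spans [0, 1] at the given resolution
    (>= 50). The minimizer is found by exhaustive grid scan followed by
    local Nelder-Mead refinement (the landscape can be multi-modal near
    phase boundaries, so purely local descent is not trusted).
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    b = np.linspace(1.0 / resolution, 1.0, resolution)
    x = np.linspace(0.0, 1.0, resolution)
    B, X = np.meshgrid(b, x, indexing="ij")
    F = _intensive_f(B, X, rho, params)

    i, j = np.unravel_index(np.argmin(F), F.shape)
    b0, x0 = b[i], x[j]

    def obj(v):
        bb = np.clip(v[0], 1e-9, 1.0)
        xx = np.clip(v[1], 0.0, 1.0)
        return float(_intensive_f(np.asarray(bb), np.asarray(xx), rho, params))

    res = minimize(obj, [b0, x0], method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    b_star = float(np.clip(res.x[0], 1e-9, 1.0))
    x_star = float(np.clip(res.x[1], 0.0, 1.0))
    f_star = obj([b_star, x_star])
    eps_edge = 1e-6
    on_boundary = (
        b_star <= b[0] + eps_edge
        or b_star >= 1.0 - eps_edge
        or x_star <= eps_edge
        or x_star >= 1.0 - eps_edge
    )
    return FreeEnergyLandscape(
        b=b, x=x, f=F, rho=rho, params=params,
        b_star=b_star, x_star=x_star, f_star=f_star, on_boundary=on_boundary,
    )
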