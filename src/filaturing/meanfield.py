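"""Mean-field (deterministic) limit of the heterocyst-regulator model.

Three regulators live in each cell of the chain: the activator HetR
(concentration φ), which does not diffuse, and the two inhibitors PatS (ψ)
and HetN (η), which hop between neighbouring cells.  The rate equations per
cell read

    φ̇_i = α_R − k_R φ_i + β_R h(φ_i) − 2 μ_S φ_i² ψ_i − 2 μ_N φ_i² η_i
    ψ̇_i = α_S − k_S ψ_i + β_S h(φ_i) − μ_S φ_i² ψ_i + D_S Σ_j Δ_ij ψ_j
    η̇_i = α_N − k_N η_i            − μ_N φ_i² η_i + D_N Σ_j Δ_ij η_j

with the dimeric Hill response h(φ) = φ²/(K² + φ²).  The trimolecular terms
describe complex formation of an inhibitor with a HetR dimer followed by
degradation, hence the factor 2 in the activator equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .lattice import ChainLattice

__all__ = [
    "ModelParams",
    "HomogeneousEquilibrium",
    "Trajectory",
    "hill",
    "hill_deriv",
    "rhs_deterministic",
    "find_equilibrium",
    "integrate_deterministic",
    "pattern_metrics",
    "NoEquilibriumError",
]

SPECIES = ("hetR", "patS", "hetN")


class NoEquilibriumError(RuntimeError):
    """No admissible homogeneous fixed point exists for the parameters."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and transport parameters of the three-regulator model.

    All quantities are dimensionless, as in the reaction scheme: production
    rates ``alpha_*`` (concentration/time), degradation rates ``k_*``
    (1/time), activation strengths ``beta_*`` (concentration/time), Hill
    scale ``K`` (concentration), trimolecular complex-degradation rates
    ``mu_*`` (1/(concentration²·time)), and inhibitor hop rates ``D_S``,
    ``D_N`` (1/time).  HetR has no hop rate: the activator is immobile.
    """

    alpha_R: float = 0.2
    alpha_S: float = 0.1
    alpha_N: float = 0.3
    beta_R: float = 6.5
    beta_S: float = 3.7
    K: float = 2.0
    k_R: float = 0.2
    k_S: float = 0.1
    k_N: float = 0.7
    mu_S: float = 0.1
    mu_N: float = 3.0
    D_S: float = 3.0
    D_N: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")

    def replace(self, **changes) -> "ModelParams":
        d = asdict(self)
        d.update(changes)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HomogeneousEquilibrium:
    """A spatially uniform fixed point (φ*, ψ*, η*) of the rate equations."""

    phi: float
    psi: float
    eta: float
    residual: float
    stable_homogeneous: bool

    @property
    def state(self) -> np.ndarray:
        return np.array([self.phi, self.psi, self.eta])


@dataclass
class Trajectory:
    """Time-resolved state of a filament run.

    ``fields`` has shape (T, Ω, 3) in species order (HetR, PatS, HetN):
    concentrations for deterministic runs, integer molecule counts for
    stochastic runs (with the cell volume recorded in ``volume``).  Growth
    runs carry the cell-count series ``n_cells`` and a division event log.
    """

    times: np.ndarray
    fields: np.ndarray
    mode: str  # "deterministic" | "ssa" | "continuum-growth"
    volume: float | None = None
    params: ModelParams | None = None
    seed: int | None = None
    n_cells: np.ndarray | None = None
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fields = np.asarray(self.fields)
        if self.n_cells is None:
            self.n_cells = np.full(self.times.shape, self.fields.shape[1])

    def concentrations(self) -> np.ndarray:
        """Fields on the concentration scale (counts divided by V for SSA)."""
        if self.mode == "ssa":
            return self.fields / float(self.volume)
        return self.fields

    def to_table(self):
        """Long-format (tau, cell, species, value) DataFrame."""
        import pandas as pd

        t_idx, c_idx, s_idx = np.meshgrid(
            np.arange(len(self.times)),
            np.arange(self.fields.shape[1]),
            np.arange(3),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "tau": self.times[t_idx.ravel()],
                "cell": c_idx.ravel(),
                "species": np.array(SPECIES)[s_idx.ravel()],
                "value": self.fields.reshape(-1),
            }
        )


def hill(phi: np.ndarray | float, K: float) -> np.ndarray | float:
    """Dimeric Hill activation h(φ) = φ²/(K² + φ²)."""
    return phi**2 / (K**2 + phi**2)


def hill_deriv(phi: np.ndarray | float, K: float) -> np.ndarray | float:
    """h'(φ) = 2 K² φ / (K² + φ²)²."""
    return 2.0 * K**2 * phi / (K**2 + phi**2) ** 2


def reaction_rhs(state: np.ndarray, p: ModelParams) -> np.ndarray:
    """Reaction part of the rate equations (no diffusion), shape (..., 3)."""
    phi = state[..., 0]
    psi = state[..., 1]
    eta = state[..., 2]
    h = hill(phi, p.K)
    dphi = p.alpha_R - p.k_R * phi + p.beta_R * h \
        - 2.0 * p.mu_S * phi**2 * psi - 2.0 * p.mu_N * phi**2 * eta
    dpsi = p.alpha_S - p.k_S * psi + p.beta_S * h - p.mu_S * phi**2 * psi
    deta = p.alpha_N - p.k_N * eta - p.mu_N * phi**2 * eta
    return np.stack([dphi, dpsi, deta], axis=-1)


def rhs_deterministic(
    state: np.ndarray, params: ModelParams, lattice: ChainLattice
) -> np.ndarray:
    """Full deterministic time-derivative on the chain.

    Parameters
    ----------
    state : (Ω, 3) ndarray
        Non-negative concentrations (HetR, PatS, HetN) per cell.
    params : ModelParams
    lattice : ChainLattice

    Returns
    -------
    (Ω, 3) ndarray
        Reaction terms plus Laplacian diffusion for the two inhibitors only.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (lattice.n_cells, 3):
        raise ValueError(
            f"state shape {state.shape} incompatible with Ω={lattice.n_cells}"
        )
    if np.any(~np.isfinite(state)) or np.any(state < 0):
        raise ValueError("state must be finite and non-negative")
    deriv = reaction_rhs(state, params)
    deriv[:, 1] += params.D_S * (lattice.laplacian @ state[:, 1])
    deriv[:, 2] += params.D_N * (lattice.laplacian @ state[:, 2])
    return deriv


def psi_of_phi(phi, p: ModelParams):
    """Closed-form PatS branch ψ*(φ) = (α_S + β_S h(φ)) / (k_S + μ_S φ²)."""
    return (p.alpha_S + p.beta_S * hill(phi, p.K)) / (p.k_S + p.mu_S * phi**2)


def eta_of_phi(phi, p: ModelParams):
    """Closed-form HetN branch η*(φ) = α_N / (k_N + μ_N φ²)."""
    return p.alpha_N / (p.k_N + p.mu_N * phi**2)


def _scalar_balance(phi, p: ModelParams):
    return (
        p.alpha_R
        - p.k_R * phi
        + p.beta_R * hill(phi, p.K)
        - 2.0 * p.mu_S * phi**2 * psi_of_phi(phi, p)
        - 2.0 * p.mu_N * phi**2 * eta_of_phi(phi, p)
    )


def _homogeneous_jacobian(phi, psi, eta, p: ModelParams) -> np.ndarray:
    # local import to avoid a cycle: turing.jacobian is the public face
    from .turing import reaction_jacobian

    return reaction_jacobian(phi, psi, eta, p)


def find_equilibrium(
    params: ModelParams, n_grid: int = 2000
) -> list[HomogeneousEquilibrium]:
    """Locate all homogeneous fixed points of the rate equations.

    Substituting the closed forms ψ*(φ) and η*(φ) into φ̇ = 0 reduces the
    fixed-point condition to a scalar equation in φ, which is bracketed on a
    grid over [0, (α_R + β_R)/k_R] (an upper bound since the Hill response
    is ≤ 1) and refined by bisection.

    Returns
    -------
    list of HomogeneousEquilibrium
        Sorted by ascending φ*; each carries the max-norm residual of the
        rate equations and a homogeneous-stability flag (all eigenvalues of
        the non-spatial Jacobian in the left half-plane).

    Raises
    ------
    NoEquilibriumError
        If no non-negative root exists.
    """
    if params.k_R <= 0:
        raise ValueError("k_R must be positive to bound the root search")
    phi_max = (params.alpha_R + params.beta_R) / params.k_R
    grid = np.linspace(0.0, phi_max * (1 + 1e-9), n_grid + 1)
    vals = _scalar_balance(grid, params)
    roots: list[float] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(brentq(lambda x: _scalar_balance(x, params), a, b, xtol=1e-13))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        raise NoEquilibriumError(
            "no non-negative homogeneous equilibrium found for these parameters"
        )
    out = []
    for phi in roots:
        psi = float(psi_of_phi(phi, params))
        eta = float(eta_of_phi(phi, params))
        res = float(np.max(np.abs(reaction_rhs(np.array([phi, psi, eta]), params))))
        j0 = _homogeneous_jacobian(phi, psi, eta, params)
        stable = bool(np.max(np.linalg.eigvals(j0).real) < 0)
        out.append(HomogeneousEquilibrium(phi, psi, eta, res, stable))
    return sorted(out, key=lambda e: e.phi)


def reference_equilibrium(params: ModelParams) -> HomogeneousEquilibrium:
    """The base state for Turing analysis: the stable homogeneous root.

    Among stable roots the one with the largest φ* is chosen; a warning is
    emitted if several are stable.

    Raises
    ------
    NoEquilibriumError
        If no homogeneously stable root exists.
    """
    eqs = find_equilibrium(params)
    stable = [e for e in eqs if e.stable_homogeneous]
    if not stable:
        raise NoEquilibriumError(
            "no homogeneously stable equilibrium: Turing analysis has no base state"
        )
    if len(stable) > 1:
        warnings.warn(
            f"{len(stable)} stable homogeneous equilibria; using largest φ*",
            stacklevel=2,
        )
    return max(stable, key=lambda e: e.phi)


def integrate_deterministic(
    params: ModelParams,
    lattice: ChainLattice,
    init: np.ndarray,
    tau_end: float,
    n_samples: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the deterministic rate equations on the chain.

    Uses a stiff solver (LSODA) — the trimolecular degradation terms make
    the system stiff near patterned states.  Concentrations are clipped at
    zero only in the returned trajectory, never inside the right-hand side.

    Parameters
    ----------
    init : (Ω, 3) ndarray
        Non-negative initial concentrations.
    tau_end : float
        Integration horizon in dimensionless time.
    n_samples : int
        Output grid size (uniform on [0, tau_end]).
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (lattice.n_cells, 3):
        raise ValueError(f"init shape {init.shape} incompatible with lattice")
    if np.any(init < 0):
        raise ValueError("initial concentrations must be non-negative")

    lap = lattice.laplacian

    def rhs_flat(_t, y):
        state = y.reshape(lattice.n_cells, 3)
        deriv = reaction_rhs(state, params)
        deriv[:, 1] += params.D_S * (lap @ state[:, 1])
        deriv[:, 2] += params.D_N * (lap @ state[:, 2])
        return deriv.ravel()

    t_eval = np.linspace(0.0, tau_end, n_samples)
    sol = solve_ivp(
        rhs_flat,
        (0.0, tau_end),
        init.ravel(),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"deterministic integration failed: {sol.message}")
    fields = sol.y.T.reshape(-1, lattice.n_cells, 3)
    if fields.min() < -1e-6:
        raise RuntimeError(
            f"persistent negative concentrations (min {fields.min():.3e})"
        )
    return Trajectory(
        times=sol.t,
        fields=np.clip(fields, 0.0, None),
        mode="deterministic",
        params=params,
    )


def pattern_metrics(
    field: Sequence[float], prominence: float | None = None
) -> dict:
    """Quantify a spatial profile: peaks, inter-peak spacings, amplitude.

    Parameters
    ----------
    field : (Ω,) array-like, Ω ≥ 3
    prominence : float, optional
        Minimum peak prominence; defaults to 5% of the field range.

    Returns
    -------
    dict with keys ``peaks`` (cell indices), ``spacings`` (cells between
    adjacent peaks), ``amplitude`` (max − min).
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 1 or field.size < 3:
        raise ValueError("field must be a 1-D array of length >= 3")
    amplitude = float(field.max() - field.min())
    if prominence is None:
        prominence = 0.05 * amplitude if amplitude > 0 else np.inf
    if amplitude == 0.0:
        return {"peaks": np.array([], dtype=int), "spacings": np.array([]), "amplitude": 0.0}
    peaks, _ = find_peaks(field, prominence=prominence)
    return {
        "peaks": peaks,
        "spacings": np.diff(peaks).astype(float),
        "amplitude": amplitude,
    }
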