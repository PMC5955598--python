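"""Linear stability of the homogeneous state and Turing-instability scans.

Perturbations about a homogeneous fixed point (φ*, ψ*, η*) are expanded on
the Laplacian eigenbasis; each mode α evolves under the 3×3 matrix

    Q(Λ^(α)) = J0 + diag(0, D_S, D_N) Λ^(α)

where J0 is the Jacobian of the reaction terms at the fixed point.  The
leading real eigenvalue λ_max(Λ) is the dispersion relation; a diffusion
driven (Turing) instability requires a homogeneously stable state
(λ_max(0) < 0) that some non-uniform mode (Λ < 0) nevertheless destabilises.
The continuum dispersion follows by the substitution Λ → −k².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import ChainLattice
from .meanfield import (
    HomogeneousEquilibrium,
    ModelParams,
    NoEquilibriumError,
    hill_deriv,
    reference_equilibrium,
)

__all__ = [
    "DispersionResult",
    "reaction_jacobian",
    "jacobian",
    "discrete_dispersion",
    "continuum_dispersion",
    "region_scan",
    "threshold_search",
    "NotBracketedError",
]


class NotBracketedError(RuntimeError):
    """The requested bracket does not straddle the instability boundary."""


@dataclass(frozen=True)
class DispersionResult:
    """Dispersion relation λ_max over a set of spatial modes.

    ``modes`` holds Laplacian eigenvalues Λ (discrete) or wavenumbers k
    (continuum, where λ is evaluated at Λ = −k²).  ``turing_unstable``
    requires both a homogeneously stable base state and a positive maximum
    over the non-uniform modes.
    """

    modes: np.ndarray
    lam_max: np.ndarray
    kind: str  # "discrete" | "continuum"
    homogeneous_stable: bool
    turing_unstable: bool
    max_lam: float
    argmax_mode: float
    band: tuple[float, float] | None = None

    def to_table(self) -> pd.DataFrame:
        col = "eigenvalue" if self.kind == "discrete" else "wavenumber"
        return pd.DataFrame({col: self.modes, "lam_max": self.lam_max})


def reaction_jacobian(
    phi: float, psi: float, eta: float, p: ModelParams
) -> np.ndarray:
    """Analytic 3×3 Jacobian of the reaction terms at (φ, ψ, η).

    Derived by differentiating the rate equations; note the PatS↔HetN block
    vanishes (the inhibitors never couple directly) and the φ-row
    off-diagonals carry the factor 2 of the trimolecular HetR loss.
    """
    F = (
        -p.k_R
        + p.beta_R * hill_deriv(phi, p.K)
        - 4.0 * p.mu_S * phi * psi
        - 4.0 * p.mu_N * phi * eta
    )
    G = p.beta_S * hill_deriv(phi, p.K) - 2.0 * p.mu_S * phi * psi
    return np.array(
        [
            [F, -2.0 * p.mu_S * phi**2, -2.0 * p.mu_N * phi**2],
            [G, -p.k_S - p.mu_S * phi**2, 0.0],
            [-2.0 * p.mu_N * phi * eta, 0.0, -p.k_N - p.mu_N * phi**2],
        ]
    )


def jacobian(
    params: ModelParams, eq: HomogeneousEquilibrium
) -> tuple[np.ndarray, np.ndarray]:
    """Non-spatial Jacobian J0 and diffusion matrix J_D = diag(0, D_S, D_N).

    Raises
    ------
    ValueError
        If ``eq`` is not a fixed point (residual ≥ 1e-9).
    """
    if eq.residual >= 1e-9:
        raise ValueError(f"equilibrium residual {eq.residual:.2e} too large")
    j0 = reaction_jacobian(eq.phi, eq.psi, eq.eta, params)
    jd = np.diag([0.0, params.D_S, params.D_N])
    return j0, jd


def _lam_max(q: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(q).real))


def _dispersion(j0, jd, lam_values) -> np.ndarray:
    return np.array([_lam_max(j0 + jd * lam) for lam in lam_values])


def discrete_dispersion(
    params: ModelParams, eq: HomogeneousEquilibrium, lattice: ChainLattice
) -> DispersionResult:
    """λ_max(Λ^(α)) over the Ω Laplacian modes of the chain."""
    j0, jd = jacobian(params, eq)
    lam_vals = lattice.eigenvalues
    disp = _dispersion(j0, jd, lam_vals)
    hom_stable = _lam_max(j0) < 0
    nonuniform = lam_vals < -1e-12
    max_nonuniform = float(disp[nonuniform].max()) if nonuniform.any() else -np.inf
    arg = (
        float(lam_vals[nonuniform][np.argmax(disp[nonuniform])])
        if nonuniform.any()
        else 0.0
    )
    return DispersionResult(
        modes=lam_vals,
        lam_max=disp,
        kind="discrete",
        homogeneous_stable=hom_stable,
        turing_unstable=bool(hom_stable and max_nonuniform > 0),
        max_lam=max_nonuniform,
        argmax_mode=arg,
    )


def continuum_dispersion(
    params: ModelParams,
    eq: HomogeneousEquilibrium,
    k_grid: np.ndarray | None = None,
) -> DispersionResult:
    """λ_max(−k²) on a continuum wavenumber grid.

    Also reports the positive-growth band [k_low, k_high] when one exists
    (linear interpolation of the sign changes of λ(k)).
    """
    if k_grid is None:
        k_grid = np.linspace(0.0, 2.0, 801)
    k_grid = np.asarray(k_grid, dtype=float)
    j0, jd = jacobian(params, eq)
    disp = _dispersion(j0, jd, -k_grid**2)
    hom_stable = _lam_max(j0) < 0
    pos = k_grid > 0
    max_pos = float(disp[pos].max()) if pos.any() else -np.inf
    arg = float(k_grid[pos][np.argmax(disp[pos])]) if pos.any() else 0.0
    band = None
    if max_pos > 0:
        above = disp > 0
        idx = np.nonzero(above)[0]

        def cross(i, j):
            x0, x1 = k_grid[i], k_grid[j]
            y0, y1 = disp[i], disp[j]
            return x0 - y0 * (x1 - x0) / (y1 - y0) if y1 != y0 else x0

        lo = cross(idx[0] - 1, idx[0]) if idx[0] > 0 else k_grid[0]
        hi = cross(idx[-1], idx[-1] + 1) if idx[-1] < len(k_grid) - 1 else k_grid[-1]
        band = (float(lo), float(hi))
    return DispersionResult(
        modes=k_grid,
        lam_max=disp,
        kind="continuum",
        homogeneous_stable=hom_stable,
        turing_unstable=bool(hom_stable and max_pos > 0),
        max_lam=max_pos,
        argmax_mode=arg,
        band=band,
    )


def _point_status(
    params: ModelParams, lattice: ChainLattice
) -> tuple[bool, bool, float]:
    """(has stable equilibrium, turing unstable, dispersion max) at a point."""
    import warnings as _w

    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            eq = reference_equilibrium(params)
    except NoEquilibriumError:
        return False, False, np.nan
    disp = discrete_dispersion(params, eq, lattice)
    return True, disp.turing_unstable, disp.max_lam


def region_scan(
    template: ModelParams,
    beta_S_values: np.ndarray,
    beta_R_values: np.ndarray,
    lattice: ChainLattice,
) -> pd.DataFrame:
    """Map the Turing-unstable region in the (β_S, β_R) plane.

    Each grid point is classified by: existence of a homogeneously stable
    equilibrium, and sign of the dispersion maximum over non-uniform modes.
    Points with no admissible equilibrium are marked (``stable=False``) but
    not fatal.

    Returns
    -------
    DataFrame with columns beta_S, beta_R, stable, turing_unstable, max_lam.
    """
    rows = []
    for bR in np.asarray(beta_R_values, dtype=float):
        for bS in np.asarray(beta_S_values, dtype=float):
            p = template.replace(beta_S=float(bS), beta_R=float(bR))
            stable, unstable, mx = _point_status(p, lattice)
            rows.append((bS, bR, stable, unstable, mx))
    return pd.DataFrame(
        rows, columns=["beta_S", "beta_R", "stable", "turing_unstable", "max_lam"]
    )


def threshold_search(
    template: ModelParams,
    free_param: str,
    bracket: tuple[float, float],
    lattice: ChainLattice,
    step: float = 0.005,
    tol: float = 1e-4,
) -> float:
    """Critical value of one parameter at the Turing-instability onset.

    Scans ``free_param`` over ``bracket`` on a grid of spacing ``step``,
    finds the first grid value where the state is Turing-unstable, then
    refines the boundary by bisection — using the dispersion maximum where
    an equilibrium exists on both sides, else the grid refinement alone.

    Returns the smallest value of the free parameter (to tolerance ``tol``)
    for which the instability holds.

    Raises
    ------
    NotBracketedError
        If the instability status does not change across the bracket.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    grid = np.arange(lo, hi + step / 2, step)

    def unstable_at(x: float) -> bool:
        p = template.replace(**{free_param: float(x)})
        _, unstable, _ = _point_status(p, lattice)
        return unstable

    flags = [unstable_at(x) for x in grid]
    if all(flags) or not any(flags):
        raise NotBracketedError(
            f"no Turing-instability onset for {free_param} in [{lo}, {hi}]"
        )
    first = int(np.argmax(flags))
    if first == 0:
        return float(grid[0])
    a, b = grid[first - 1], grid[first]  # stable at a, unstable at b
    while b - a > tol:
        mid = 0.5 * (a + b)
        if unstable_at(mid):
            b = mid
        else:
            a = mid
    return float(b)
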