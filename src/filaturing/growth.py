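"""Filament growth by cell duplication.

A growing filament adds a division channel to the stochastic chemistry:
every cell duplicates at constant propensity ρV, so the expected cell count
grows as Ω(τ) = Ω₀ e^{ρVτ} (a Yule process when the chemistry is switched
off).  On division the mother's molecules are split between two adjacent
daughter cells, either equally (odd molecule to the left daughter) or
binomially.  In the deterministic continuum limit, uniform exponential
growth maps onto a fixed unit interval as a dilution term −ρ̃ c plus
diffusion coefficients rescaled by 1/Ω(τ)².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .lattice import ChainLattice, build_chain
from .meanfield import ModelParams, Trajectory, reaction_rhs, reference_equilibrium
from .turing import discrete_dispersion
from .ssa import _param_vector, _ssa_core

__all__ = [
    "GrowthConfig",
    "ssa_growing_run",
    "integrate_growing_continuum",
    "unstable_band",
]


@dataclass(frozen=True)
class GrowthConfig:
    """Growth settings for a dividing filament.

    ``rho`` is the per-cell duplication rate of the stochastic model (the
    propensity is ρV per cell); ``rho_tilde`` the continuum growth rate, so
    Ω(τ) = Ω₀ e^{ρ̃τ} with ρ̃ = ρV.  ``splitting`` is "equal" or
    "binomial".
    """

    rho: float = 1e-8
    rho_tilde: float = 5e-5
    n_cells_init: int = 40
    splitting: str = "equal"
    max_cells: int = 512

    def __post_init__(self) -> None:
        if self.rho < 0 or self.rho_tilde < 0:
            raise ValueError("growth rates must be non-negative")
        if self.n_cells_init < 2:
            raise ValueError("initial filament needs at least 2 cells")
        if self.splitting not in ("equal", "binomial"):
            raise ValueError(f"unknown splitting rule {self.splitting!r}")


def ssa_growing_run(
    params: ModelParams,
    volume: float,
    growth: GrowthConfig,
    init_counts: np.ndarray,
    tau_end: float,
    seed: int,
    d_tau: float = 1.0,
) -> Trajectory:
    """SSA realization on a filament that grows by cell duplication.

    Identical in law to :func:`filaturing.ssa.gillespie_run` when ρ = 0
    (same compiled core, same random stream).  The division event log
    (τ, duplicated cell index) is stored in ``Trajectory.events``; if the
    cell cap is reached, further divisions are dropped and the trajectory
    is flagged truncated in the events list.
    """
    init_counts = np.asarray(init_counts)
    omega0 = growth.n_cells_init
    if init_counts.shape != (omega0, 3):
        raise ValueError(
            f"init_counts shape {init_counts.shape} != ({omega0}, 3)"
        )
    if np.any(init_counts < 0) or not np.issubdtype(init_counts.dtype, np.integer):
        raise ValueError("init_counts must be non-negative integers")
    max_omega = growth.max_cells
    x = np.zeros((3, max_omega), dtype=np.int64)
    x[:, :omega0] = init_counts.T
    t_grid = np.arange(0.0, tau_end + d_tau / 2, d_tau)
    out, omegas, ev_t, ev_i, truncated = _ssa_core(
        x,
        omega0,
        float(volume),
        _param_vector(params),
        float(growth.rho),
        growth.splitting == "binomial",
        t_grid,
        int(seed) % (2**31 - 1),
        max_omega,
    )
    events = [("division", float(t), int(i)) for t, i in zip(ev_t, ev_i)]
    if truncated:
        events.append(("truncated", float(t_grid[-1]), max_omega))
    return Trajectory(
        times=t_grid,
        fields=out.transpose(0, 2, 1),
        mode="ssa",
        volume=float(volume),
        params=params,
        seed=int(seed),
        n_cells=omegas,
        events=events,
    )


def integrate_growing_continuum(
    params: ModelParams,
    rho_tilde: float,
    init_profile: np.ndarray,
    tau_end: float,
    n_cells_init: int = 40,
    n_samples: int = 201,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Deterministic reaction–diffusion dynamics on a growing domain.

    The growing filament is mapped onto the fixed unit interval: the
    reaction terms act unchanged, uniform growth contributes a dilution
    −ρ̃ c to every species, and the inhibitor diffusion coefficients are
    divided by Ω(τ)² with Ω(τ) = Ω₀ e^{ρ̃τ}.  Zero-flux boundaries;
    method of lines on the grid carried by ``init_profile``.

    Parameters
    ----------
    init_profile : (M, 3) ndarray
        Initial concentrations on M uniformly spaced points of [0, 1].
    """
    init_profile = np.asarray(init_profile, dtype=float)
    if init_profile.ndim != 2 or init_profile.shape[1] != 3:
        raise ValueError("init_profile must have shape (M, 3)")
    if np.any(init_profile < 0):
        raise ValueError("initial profile must be non-negative")
    m = init_profile.shape[0]
    dx = 1.0 / (m - 1)
    lap = np.zeros((m, m))
    for i in range(m):
        if i > 0:
            lap[i, i - 1] += 1.0
        if i < m - 1:
            lap[i, i + 1] += 1.0
        lap[i, i] -= (i > 0) + (i < m - 1)  # zero-flux ends
    lap /= dx**2

    def rhs(t, y):
        state = y.reshape(m, 3)
        deriv = reaction_rhs(state, params) - rho_tilde * state
        omega_t = n_cells_init * np.exp(rho_tilde * t)
        deriv[:, 1] += params.D_S / omega_t**2 * (lap @ state[:, 1])
        deriv[:, 2] += params.D_N / omega_t**2 * (lap @ state[:, 2])
        return deriv.ravel()

    t_eval = np.linspace(0.0, tau_end, n_samples)
    sol = solve_ivp(
        rhs, (0.0, tau_end), init_profile.ravel(), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"growing-domain integration failed: {sol.message}")
    fields = np.clip(sol.y.T.reshape(-1, m, 3), 0.0, None)
    n_cells = np.round(n_cells_init * np.exp(rho_tilde * sol.t)).astype(int)
    return Trajectory(
        times=sol.t,
        fields=fields,
        mode="continuum-growth",
        params=params,
        n_cells=n_cells,
    )


def unstable_band(
    params: ModelParams, omega_values: np.ndarray
) -> "np.ndarray":
    """Unstable-mode statistics versus filament length.

    For each cell count Ω: the number of discrete modes with positive
    growth rate, the index of the leading (fastest-growing) mode, and the
    band edges in mode index.  On a pattern-forming parameter set the band
    widens and the leading index grows linearly with Ω — the mechanism by
    which growth keeps inserting new pattern peaks at fixed spacing.

    Returns
    -------
    DataFrame with columns omega, n_unstable, leading_mode,
    band_low, band_high (mode indices in descending-Λ order; NaN band for
    stable sets).
    """
    import pandas as pd

    eq = reference_equilibrium(params)
    rows = []
    for omega in np.asarray(omega_values, dtype=int):
        lattice = build_chain(int(omega))
        disp = discrete_dispersion(params, eq, lattice)
        pos = np.nonzero(disp.lam_max > 0)[0]
        pos = pos[pos > 0]  # exclude the uniform mode
        if pos.size == 0:
            rows.append((omega, 0, np.nan, np.nan, np.nan))
        else:
            lead = int(pos[np.argmax(disp.lam_max[pos])])
            rows.append((omega, int(pos.size), lead, int(pos[0]), int(pos[-1])))
    return pd.DataFrame(
        rows, columns=["omega", "n_unstable", "leading_mode", "band_low", "band_high"]
    )
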