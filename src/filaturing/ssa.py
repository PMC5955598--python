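"""Exact stochastic simulation of the regulator chemistry on a cell chain.

The chemical scheme per cell i (counts r, s, n for HetR, PatS, HetN; cell
volume V setting the demographic-noise strength):

    ∅ → R, S, N              at α_R V, α_S V, α_N V
    ∅ → R                    at β_R V h(r/V)      (HetR autoactivation)
    ∅ → S                    at β_S V h(r/V)      (HetR activates PatS)
    R → ∅, S → ∅, N → ∅      at k_R r, k_S s, k_N n
    2R + S → ∅               at μ_S r(r−1)s / V²
    2R + N → ∅               at μ_N r(r−1)n / V²
    S_i → S_j, N_i → N_j     at D_S s, D_N n per adjacent cell j

with h(x) = x²/(K² + x²).  The V-scaling is the unique convention whose
V → ∞ ensemble-mean drift reproduces the deterministic rate equations
term by term; the exact mass-action pair count r(r−1) replaces r² for the
trimolecular channels.  Simulation uses the Gillespie direct method with
per-cell propensity bookkeeping, compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .lattice import ChainLattice
from .meanfield import ModelParams, Trajectory, hill

__all__ = ["ReactionChannel", "build_channels", "gillespie_run"]

R, S, N = 0, 1, 2


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel of the spatial chemical master equation.

    ``stoich`` lists (cell, species, delta) count changes when the channel
    fires; ``propensity`` maps an (Ω, 3) count array to the firing rate.
    ``equilibrium_rate`` gives the concentration-scale rate at a uniform
    state — the quantity that enters the linear-noise diffusion matrix.
    """

    label: str
    cell: int
    stoich: tuple[tuple[int, int, int], ...]
    propensity: Callable[[np.ndarray], float]
    equilibrium_rate: Callable[[float, float, float], float]
    is_hop: bool = False


def build_channels(
    params: ModelParams, lattice: ChainLattice, volume: float
) -> list[ReactionChannel]:
    """Enumerate every reaction channel of the scheme on the given chain.

    This explicit list is the reference for propensity bookkeeping (the
    compiled simulator implements the same scheme) and feeds the
    channel-by-channel assembly of the linear-noise matrices.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    p, V = params, float(volume)
    chans: list[ReactionChannel] = []
    for i in range(lattice.n_cells):
        chans += [
            ReactionChannel(
                "prod_R", i, ((i, R, +1),),
                lambda x, i=i: p.alpha_R * V,
                lambda phi, psi, eta: p.alpha_R,
            ),
            ReactionChannel(
                "auto_R", i, ((i, R, +1),),
                lambda x, i=i: p.beta_R * V * hill(x[i, R] / V, p.K),
                lambda phi, psi, eta: p.beta_R * hill(phi, p.K),
            ),
            ReactionChannel(
                "decay_R", i, ((i, R, -1),),
                lambda x, i=i: p.k_R * x[i, R],
                lambda phi, psi, eta: p.k_R * phi,
            ),
            ReactionChannel(
                "prod_S", i, ((i, S, +1),),
                lambda x, i=i: p.alpha_S * V,
                lambda phi, psi, eta: p.alpha_S,
            ),
            ReactionChannel(
                "act_S", i, ((i, S, +1),),
                lambda x, i=i: p.beta_S * V * hill(x[i, R] / V, p.K),
                lambda phi, psi, eta: p.beta_S * hill(phi, p.K),
            ),
            ReactionChannel(
                "decay_S", i, ((i, S, -1),),
                lambda x, i=i: p.k_S * x[i, S],
                lambda phi, psi, eta: p.k_S * psi,
            ),
            ReactionChannel(
                "prod_N", i, ((i, N, +1),),
                lambda x, i=i: p.alpha_N * V,
                lambda phi, psi, eta: p.alpha_N,
            ),
            ReactionChannel(
                "decay_N", i, ((i, N, -1),),
                lambda x, i=i: p.k_N * x[i, N],
                lambda phi, psi, eta: p.k_N * eta,
            ),
            ReactionChannel(
                "complex_S", i, ((i, R, -2), (i, S, -1)),
                lambda x, i=i: p.mu_S * x[i, R] * (x[i, R] - 1) * x[i, S] / V**2,
                lambda phi, psi, eta: p.mu_S * phi**2 * psi,
            ),
            ReactionChannel(
                "complex_N", i, ((i, R, -2), (i, N, -1)),
                lambda x, i=i: p.mu_N * x[i, R] * (x[i, R] - 1) * x[i, N] / V**2,
                lambda phi, psi, eta: p.mu_N * phi**2 * eta,
            ),
        ]
        for j in np.nonzero(lattice.adjacency[i])[0]:
            chans.append(
                ReactionChannel(
                    "hop_S", i, ((i, S, -1), (int(j), S, +1)),
                    lambda x, i=i: p.D_S * x[i, S],
                    lambda phi, psi, eta: p.D_S * psi,
                    is_hop=True,
                )
            )
            chans.append(
                ReactionChannel(
                    "hop_N", i, ((i, N, -1), (int(j), N, +1)),
                    lambda x, i=i: p.D_N * x[i, N],
                    lambda phi, psi, eta: p.D_N * eta,
                    is_hop=True,
                )
            )
    return chans


# ---------------------------------------------------------------------------
# compiled direct-method core (shared by fixed and growing filaments)
# ---------------------------------------------------------------------------
# per-cell channel layout (14 slots + duplication):
#  0 prod_R  1 auto_R  2 decay_R  3 complex_S  4 prod_S  5 act_S  6 decay_S
#  7 prod_N  8 decay_N  9 complex_N  10 hopS_left 11 hopS_right
#  12 hopN_left 13 hopN_right  14 duplication

N_CH = 15


@njit(cache=True)
def _cell_propensities(x, i, omega, V, pvec, rho, a_ch):
    aR, aS, aN, bR, bS, K, kR, kS, kN, muS, muN, DS, DN = pvec
    r = x[0, i]
    s = x[1, i]
    n = x[2, i]
    conc = r / V
    h = conc * conc / (K * K + conc * conc)
    a_ch[0] = aR * V
    a_ch[1] = bR * V * h
    a_ch[2] = kR * r
    a_ch[3] = muS * r * (r - 1.0) * s / (V * V)
    a_ch[4] = aS * V
    a_ch[5] = bS * V * h
    a_ch[6] = kS * s
    a_ch[7] = aN * V
    a_ch[8] = kN * n
    a_ch[9] = muN * r * (r - 1.0) * n / (V * V)
    left = i > 0
    right = i < omega - 1
    a_ch[10] = DS * s if left else 0.0
    a_ch[11] = DS * s if right else 0.0
    a_ch[12] = DN * n if left else 0.0
    a_ch[13] = DN * n if right else 0.0
    a_ch[14] = rho * V
    total = 0.0
    for c in range(N_CH):
        total += a_ch[c]
    return total


@njit(cache=True)
def _ssa_core(
    x, omega0, V, pvec, rho, split_binomial, t_grid, seed, max_omega
):
    """Direct-method SSA on an open chain, optionally with cell duplication.

    ``x`` is a (3, max_omega) int64 workspace holding counts in the first
    ``omega`` columns.  Returns sampled counts (T, 3, max_omega), the
    cell-count series, the division event log, and a truncation flag.
    """
    np.random.seed(seed)
    omega = omega0
    n_t = t_grid.shape[0]
    out = np.zeros((n_t, 3, max_omega), dtype=np.int64)
    omegas = np.zeros(n_t, dtype=np.int64)
    events_t = np.zeros(4 * max_omega, dtype=np.float64)
    events_i = np.zeros(4 * max_omega, dtype=np.int64)
    n_events = 0
    truncated = False

    a_cell = np.zeros(max_omega, dtype=np.float64)
    a_ch = np.zeros(N_CH, dtype=np.float64)
    for i in range(omega):
        a_cell[i] = _cell_propensities(x, i, omega, V, pvec, rho, a_ch)

    t = 0.0
    k_out = 0
    while k_out < n_t:
        total = 0.0
        for i in range(omega):
            total += a_cell[i]
        if total <= 0.0:
            # absorbing state: hold current state for remaining samples
            while k_out < n_t:
                out[k_out, :, :] = x
                omegas[k_out] = omega
                k_out += 1
            break
        dt = -np.log(np.random.random()) / total
        t_next = t + dt
        while k_out < n_t and t_grid[k_out] < t_next:
            out[k_out, :, :] = x
            omegas[k_out] = omega
            k_out += 1
        if k_out >= n_t:
            break
        t = t_next
        # select cell then channel
        u = np.random.random() * total
        i = 0
        acc = a_cell[0]
        while acc < u and i < omega - 1:
            i += 1
            acc += a_cell[i]
        u_ch = u - (acc - a_cell[i])
        _cell_propensities(x, i, omega, V, pvec, rho, a_ch)
        c = 0
        acc_ch = a_ch[0]
        while acc_ch < u_ch and c < N_CH - 1:
            c += 1
            acc_ch += a_ch[c]

        touched_neighbor = -1
        if c == 0 or c == 1:
            x[0, i] += 1
        elif c == 2:
            x[0, i] -= 1
        elif c == 3:
            x[0, i] -= 2
            x[1, i] -= 1
        elif c == 4 or c == 5:
            x[1, i] += 1
        elif c == 6:
            x[1, i] -= 1
        elif c == 7:
            x[2, i] += 1
        elif c == 8:
            x[2, i] -= 1
        elif c == 9:
            x[0, i] -= 2
            x[2, i] -= 1
        elif c == 10:
            x[1, i] -= 1
            x[1, i - 1] += 1
            touched_neighbor = i - 1
        elif c == 11:
            x[1, i] -= 1
            x[1, i + 1] += 1
            touched_neighbor = i + 1
        elif c == 12:
            x[2, i] -= 1
            x[2, i - 1] += 1
            touched_neighbor = i - 1
        elif c == 13:
            x[2, i] -= 1
            x[2, i + 1] += 1
            touched_neighbor = i + 1
        else:  # duplication of cell i
            if omega >= max_omega:
                truncated = True
                # drop the event (cap reached); propensity unchanged
                continue
            # shift cells right of i by one slot; daughters occupy i, i+1
            for col in range(omega, i + 1, -1):
                for q in range(3):
                    x[q, col] = x[q, col - 1]
                a_cell[col] = a_cell[col - 1]
            for q in range(3):
                m = x[q, i]
                if split_binomial:
                    left_share = np.random.binomial(m, 0.5)
                else:
                    left_share = (m + 1) // 2  # odd molecule goes left
                x[q, i] = left_share
                x[q, i + 1] = m - left_share
            omega += 1
            if n_events < events_t.shape[0]:
                events_t[n_events] = t
                events_i[n_events] = i
                n_events += 1
            # edge bookkeeping changed for every cell's hop channels only if
            # end cells moved; recompute the duplication neighborhood and ends
            for col in (i - 1, i, i + 1, i + 2):
                if 0 <= col < omega:
                    a_cell[col] = _cell_propensities(
                        x, col, omega, V, pvec, rho, a_ch
                    )
            a_cell[0] = _cell_propensities(x, 0, omega, V, pvec, rho, a_ch)
            a_cell[omega - 1] = _cell_propensities(
                x, omega - 1, omega, V, pvec, rho, a_ch
            )
            continue

        a_cell[i] = _cell_propensities(x, i, omega, V, pvec, rho, a_ch)
        if touched_neighbor >= 0:
            a_cell[touched_neighbor] = _cell_propensities(
                x, touched_neighbor, omega, V, pvec, rho, a_ch
            )

    return out, omegas, events_t[:n_events], events_i[:n_events], truncated


def _param_vector(p: ModelParams) -> np.ndarray:
    return np.array(
        [
            p.alpha_R, p.alpha_S, p.alpha_N, p.beta_R, p.beta_S, p.K,
            p.k_R, p.k_S, p.k_N, p.mu_S, p.mu_N, p.D_S, p.D_N,
        ]
    )


def gillespie_run(
    params: ModelParams,
    lattice: ChainLattice,
    volume: float,
    init_counts: np.ndarray,
    tau_end: float,
    seed: int,
    d_tau: float = 1.0,
) -> Trajectory:
    """Statistically exact SSA realization on a fixed chain.

    Parameters
    ----------
    init_counts : (Ω, 3) integer ndarray
        Non-negative molecule counts per cell and species.
    tau_end : float
        Horizon; the state is read out on a uniform grid of spacing
        ``d_tau`` (piecewise-constant between reaction events).
    seed : int
        Seeds the single RNG stream of the run; recorded in the trajectory.
    """
    if lattice.periodic:
        raise NotImplementedError("SSA core assumes an open chain")
    init_counts = np.asarray(init_counts)
    if init_counts.shape != (lattice.n_cells, 3):
        raise ValueError(f"init_counts shape {init_counts.shape} invalid")
    if np.any(init_counts < 0) or not np.issubdtype(init_counts.dtype, np.integer):
        raise ValueError("init_counts must be non-negative integers")
    if volume <= 0:
        raise ValueError("volume must be positive")
    omega = lattice.n_cells
    x = np.zeros((3, omega), dtype=np.int64)
    x[:, :] = init_counts.T
    t_grid = np.arange(0.0, tau_end + d_tau / 2, d_tau)
    out, _, _, _, _ = _ssa_core(
        x, omega, float(volume), _param_vector(params), 0.0, False,
        t_grid, int(seed) % (2**31 - 1), omega,
    )
    fields = out.transpose(0, 2, 1)  # (T, Ω, 3)
    return Trajectory(
        times=t_grid,
        fields=fields,
        mode="ssa",
        volume=float(volume),
        params=params,
        seed=int(seed),
    )
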