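"""Linear-noise approximation: fluctuation spectra about the uniform state.

At next-to-leading order in the system-size expansion (expansion parameter
V^(−1/2)), fluctuations ξ about the homogeneous fixed point obey linear
Langevin equations.  After projecting onto the Laplacian eigenmodes, each
mode α is an independent 3-species Ornstein–Uhlenbeck process with drift
M(Λ) = J0 + diag(0, D_S, D_N) Λ and noise covariance B(Λ) = B_ns + Λ B_sp.
The stationary power spectrum follows from the resolvent
F(ω, Λ) = −iω I − M(Λ):

    P_q(ω, Λ) = [F⁻¹ B(Λ) (F†)⁻¹]_qq

A peak of the HetR spectrum at an interior mode Λ* < 0 signals a
noise-sustained (stochastic Turing) pattern, which can occur well outside
the deterministic instability region.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .lattice import ChainLattice, mode_transform
from .meanfield import (
    HomogeneousEquilibrium,
    ModelParams,
    NoEquilibriumError,
    Trajectory,
    hill,
    reference_equilibrium,
)
from .turing import discrete_dispersion, reaction_jacobian

__all__ = [
    "LNAMatrices",
    "SpectrumResult",
    "lna_matrices",
    "theoretical_spectrum",
    "empirical_spectrum",
    "spatial_slice",
    "stochastic_region_scan",
]


@dataclass(frozen=True)
class LNAMatrices:
    """Drift and noise matrices of the linearised Langevin dynamics.

    ``m_ns`` is the non-spatial drift (the reaction Jacobian J0), ``m_sp``
    the diffusion drift diag(0, D_S, D_N); the mode-α drift is
    ``m_ns + Λ m_sp``.  ``b_ns`` collects the on-site reaction noise,
    ``b_sp`` the hop noise coefficient (the mode-α covariance is
    ``b_ns + Λ b_sp``; note b_sp has negative entries so that Λ ≤ 0 adds
    positive diffusion noise).
    """

    m_ns: np.ndarray
    m_sp: np.ndarray
    b_ns: np.ndarray
    b_sp: np.ndarray

    def drift(self, lam: float) -> np.ndarray:
        return self.m_ns + self.m_sp * lam

    def noise(self, lam: float) -> np.ndarray:
        return self.b_ns + self.b_sp * lam


@dataclass
class SpectrumResult:
    """Power spectrum P_q(ω, Λ) on a frequency × mode grid.

    ``power`` has shape (3, n_omega, n_modes), species-first (HetR, PatS,
    HetN).  ``modes`` are Laplacian eigenvalues (discrete) or −k² values
    (continuum).  ``normalization`` records how the values are scaled.
    """

    omega: np.ndarray
    modes: np.ndarray
    power: np.ndarray
    normalization: str  # "theoretical" | "empirical" | "empirical-matched"

    def peak(self, species: int = 0) -> tuple[float, float, float]:
        """(ω*, Λ*, height) of the global maximum for one species."""
        p = self.power[species]
        i, j = np.unravel_index(np.argmax(p), p.shape)
        return float(self.omega[i]), float(self.modes[j]), float(p[i, j])

    def to_table(self) -> pd.DataFrame:
        om, lam = np.meshgrid(self.omega, self.modes, indexing="ij")
        return pd.DataFrame(
            {
                "omega": np.tile(om.ravel(), 3),
                "mode": np.tile(lam.ravel(), 3),
                "species": np.repeat(["hetR", "patS", "hetN"], om.size),
                "power": self.power.reshape(3, -1).ravel(),
            }
        )


def lna_matrices(params: ModelParams, eq: HomogeneousEquilibrium) -> LNAMatrices:
    """Assemble the Langevin drift and noise matrices at the fixed point.

    The noise covariance follows the standard system-size-expansion rule
    B = Σ_channels (stoichiometry outer product) × channel rate, evaluated
    at the equilibrium concentrations.  On-site channels give ``b_ns``; the
    symmetric hop channels contribute, per species that diffuses, a
    site-space covariance −2 D c* Δ, i.e. a mode-space term −2 D c* Λ.
    """
    if not eq.stable_homogeneous:
        warnings.warn(
            "equilibrium is not homogeneously stable; the stationary "
            "spectrum formula assumes relaxation about a stable point",
            stacklevel=2,
        )
    p = params
    phi, psi, eta = eq.phi, eq.psi, eq.eta
    h = hill(phi, p.K)
    m_ns = reaction_jacobian(phi, psi, eta, p)
    m_sp = np.diag([0.0, p.D_S, p.D_N])
    cs = p.mu_S * phi**2 * psi  # complex-degradation rates at equilibrium
    cn = p.mu_N * phi**2 * eta
    b_ns = np.array(
        [
            [p.alpha_R + p.beta_R * h + p.k_R * phi + 4 * cs + 4 * cn, 2 * cs, 2 * cn],
            [2 * cs, p.alpha_S + p.beta_S * h + p.k_S * psi + cs, 0.0],
            [2 * cn, 0.0, p.alpha_N + p.k_N * eta + cn],
        ]
    )
    b_sp = np.diag([0.0, -2.0 * p.D_S * psi, -2.0 * p.D_N * eta])
    return LNAMatrices(m_ns=m_ns, m_sp=m_sp, b_ns=b_ns, b_sp=b_sp)


def theoretical_spectrum(
    params: ModelParams,
    eq: HomogeneousEquilibrium,
    modes: ChainLattice | np.ndarray,
    omega_grid: np.ndarray | None = None,
) -> SpectrumResult:
    """Analytic power spectrum from the resolvent of the Langevin dynamics.

    Parameters
    ----------
    modes : ChainLattice or array of Laplacian eigenvalues
        Pass a lattice for the discrete spectrum, or any array of Λ ≤ 0
        values (e.g. −k² on a continuum grid).
    omega_grid : array, optional
        Temporal frequencies; default linspace(0, 2, 201).
    """
    if omega_grid is None:
        omega_grid = np.linspace(0.0, 2.0, 201)
    omega_grid = np.asarray(omega_grid, dtype=float)
    lam_vals = (
        modes.eigenvalues if isinstance(modes, ChainLattice) else np.asarray(modes, float)
    )
    mats = lna_matrices(params, eq)
    power = np.empty((3, omega_grid.size, lam_vals.size))
    eye = np.eye(3)
    for j, lam in enumerate(lam_vals):
        m = mats.drift(lam)
        b = mats.noise(lam)
        for i, om in enumerate(omega_grid):
            f = -1j * om * eye - m
            try:
                finv = np.linalg.inv(f)
            except np.linalg.LinAlgError:
                power[:, i, j] = np.nan
                continue
            spec = finv @ b @ finv.conj().T
            power[:, i, j] = spec.diagonal().real
    return SpectrumResult(
        omega=omega_grid, modes=lam_vals, power=power, normalization="theoretical"
    )


def empirical_spectrum(
    trajectory: Trajectory,
    eq: HomogeneousEquilibrium,
    lattice: ChainLattice,
    tau_window: tuple[float, float],
    match_to: SpectrumResult | None = None,
) -> SpectrumResult:
    """Power spectrum measured from one (or one of many) SSA realizations.

    Fluctuations ξ_i = √V (x_i/V − equilibrium) are projected onto the
    Laplacian modes and Fourier-transformed in time over ``tau_window``
    with a plain rectangular window, following the discrete transform
    f̃_α(ω) = Σ_τ Σ_j f_j(τ) v_j^(α) e^{iωτ} dτ.  The periodogram
    |f̃_α(ω)|²/T estimates the stationary spectrum; average several runs'
    results for a smooth estimate.

    Parameters
    ----------
    match_to : SpectrumResult, optional
        Rescale each species' power so its maximum matches the given
        theoretical result (figure-comparison convention).
    """
    if trajectory.mode != "ssa":
        raise ValueError("empirical spectra are defined for SSA trajectories")
    t0, t1 = tau_window
    times = trajectory.times
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] outside trajectory range "
            f"[{times[0]}, {times[-1]}]"
        )
    sel = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    tt = times[sel]
    dt = float(np.median(np.diff(tt)))
    duration = tt[-1] - tt[0] + dt
    v = float(trajectory.volume)
    conc = trajectory.fields[sel] / v  # (T, Ω, 3)
    xi = np.sqrt(v) * (conc - eq.state[None, None, :])
    power = np.empty((3, tt.size // 2 + 1, lattice.n_cells))
    omega = 2.0 * np.pi * np.fft.rfftfreq(tt.size, d=dt)
    for q in range(3):
        coeffs = mode_transform(xi[:, :, q], lattice)  # (T, Ω modes)
        ft = np.fft.rfft(coeffs, axis=0) * dt
        power[q] = np.abs(ft) ** 2 / duration
    norm = "empirical"
    if match_to is not None:
        for q in range(3):
            mx = power[q].max()
            target = match_to.power[q].max()
            if mx > 0 and np.isfinite(target):
                power[q] *= target / mx
        norm = "empirical-matched"
    return SpectrumResult(
        omega=omega, modes=lattice.eigenvalues, power=power, normalization=norm
    )


def spatial_slice(result: SpectrumResult, species: int = 0) -> pd.DataFrame:
    """P_q(ω=0, Λ) versus mode — the spatial fingerprint of the pattern."""
    i0 = int(np.argmin(np.abs(result.omega)))
    return pd.DataFrame(
        {"mode": result.modes, "power": result.power[species, i0, :]}
    )


def _interior_peak(power_vs_mode: np.ndarray, lam_vals: np.ndarray,
                   min_ratio: float) -> tuple[bool, float, float]:
    """Detect a localized maximum of P(0, Λ) over the Λ < 0 modes.

    Modes are scanned in descending-Λ order (Λ=0 first).  Returns
    (found, Λ*, height); ``found`` requires the maximum over non-uniform
    modes to sit away from the most-negative-Λ end of the band and to
    exceed ``min_ratio`` times the uniform-mode (Λ = 0) power — i.e. the
    spectrum singles out a finite wavelength rather than decaying
    monotonically from (or growing monotonically away from) Λ = 0.
    """
    order = np.argsort(-lam_vals)
    lam = lam_vals[order]
    p = power_vs_mode[order]
    interior = np.arange(1, lam.size)  # non-uniform modes
    if interior.size < 2:
        return False, 0.0, 0.0
    pi = p[interior]
    j = int(np.argmax(pi))
    height = float(pi[j])
    lam_star = float(lam[interior][j])
    uniform = float(p[0])  # Λ = 0 mode
    localized = j < interior.size - 1 and height >= min_ratio * uniform
    return bool(localized), lam_star, height


def stochastic_region_scan(
    template: ModelParams,
    beta_S_values: np.ndarray,
    beta_R_values: np.ndarray,
    lattice: ChainLattice,
    min_peak_ratio: float = 1.2,
) -> pd.DataFrame:
    """Map the noise-driven pattern region in the (β_S, β_R) plane.

    At each grid point with a stable homogeneous equilibrium, the ω = 0
    slice of the theoretical HetR spectrum is scanned for an interior local
    maximum over the non-uniform modes; its height is recorded together
    with the deterministic Turing flag, so the deterministic region can be
    overlaid on the (strictly larger) stochastic one.
    """
    rows = []
    for bR in np.asarray(beta_R_values, dtype=float):
        for bS in np.asarray(beta_S_values, dtype=float):
            p = template.replace(beta_S=float(bS), beta_R=float(bR))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    eq = reference_equilibrium(p)
            except NoEquilibriumError:
                rows.append((bS, bR, False, False, False, np.nan, np.nan))
                continue
            disp = discrete_dispersion(p, eq, lattice)
            spec = theoretical_spectrum(p, eq, lattice, omega_grid=np.array([0.0]))
            found, lam_star, height = _interior_peak(
                spec.power[0, 0, :], lattice.eigenvalues, min_peak_ratio
            )
            rows.append(
                (bS, bR, True, disp.turing_unstable, found, lam_star, height)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "beta_S", "beta_R", "stable", "turing_unstable",
            "stochastic_peak", "peak_mode", "peak_height",
        ],
    )
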