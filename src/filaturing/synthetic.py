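"""Synthetic inputs with known ground truth, and canonical parameter presets.

Everything the analysis pipeline consumes can be generated here: partition
datasets with a known per-molecule brightness ν, sigmoidal
autofluorescence-decay traces with known onset times, perturbed initial
fields for pattern runs, and the named parameter sets used throughout the
model studies.  All generators are pure functions of their arguments and a
seed.
"""

from __future__ import annotations

import numpy as np

from .calibration import FluorescenceTrace, PartitionTriplet
from .growth import GrowthConfig
from .meanfield import HomogeneousEquilibrium, ModelParams

__all__ = [
    "PRESETS",
    "preset",
    "preset_growth",
    "DEFAULT_N_CELLS",
    "DEFAULT_VOLUME",
    "gen_partition_data",
    "gen_decay_traces",
    "gen_perturbed_field",
]

DEFAULT_N_CELLS = 40
DEFAULT_VOLUME = 5000.0

_BASE = dict(
    k_R=0.2, alpha_R=0.2, K=2.0, k_S=0.1, alpha_S=0.1, mu_S=0.1,
    k_N=0.7, alpha_N=0.3, mu_N=3.0,
)

# Named parameter sets: the unequal-diffusivity chain (D_S/D_N = 3) just
# inside ("red") and just outside ("blue") the deterministic Turing region,
# and the equal-diffusivity variants (D_S = D_N = 4) used for the
# stochastic-region comparison.
PRESETS: dict[str, dict] = {
    "fig3_red": dict(_BASE, D_S=3.0, D_N=1.0, beta_R=6.5, beta_S=3.7),
    "fig3_blue": dict(_BASE, D_S=3.0, D_N=1.0, beta_R=6.5, beta_S=3.65),
    "s2_red": dict(_BASE, D_S=4.0, D_N=4.0, beta_R=5.82, beta_S=2.99),
    "s2_blue": dict(_BASE, D_S=4.0, D_N=4.0, beta_R=5.69, beta_S=2.99),
    "fig6": dict(_BASE, D_S=4.0, D_N=4.0, beta_R=6.5, beta_S=3.7),
}

# Growth settings: the stochastic dividing-filament run (per-cell rate ρ with
# V = 5000) and the continuum growing-domain run (rate ρ̃).
GROWTH_PRESETS: dict[str, GrowthConfig] = {
    "fig7": GrowthConfig(rho=1e-8, n_cells_init=DEFAULT_N_CELLS),
    "s4": GrowthConfig(rho_tilde=5e-5, n_cells_init=DEFAULT_N_CELLS),
}


def preset(name: str) -> ModelParams:
    """Return a named ModelParams set (see :data:`PRESETS`)."""
    try:
        return ModelParams(**PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def preset_growth(name: str) -> GrowthConfig:
    """Return a named growth configuration (see :data:`GROWTH_PRESETS`)."""
    try:
        return GROWTH_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown growth preset {name!r}; available: {sorted(GROWTH_PRESETS)}"
        ) from None


def gen_partition_data(
    nu: float,
    n_triplets: int,
    seed: int,
    mean_copies: float = 40.0,
    copy_distribution: str = "poisson",
    background: float = 0.0,
    noise_sd: float = 0.0,
) -> list[PartitionTriplet]:
    """Mother→daughter fluorescence triplets with known brightness ν.

    Mothers carry n molecules (Poisson with the given mean, or exactly
    ``mean_copies`` if ``copy_distribution="fixed"``); each daughter
    receives Binomial(n, 1/2) molecules.  Fluorescence is ν·molecules plus
    a constant background plus Gaussian measurement noise.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    rng = np.random.default_rng(seed)
    if copy_distribution == "poisson":
        n = rng.poisson(mean_copies, size=n_triplets)
    elif copy_distribution == "fixed":
        n = np.full(n_triplets, int(round(mean_copies)))
    else:
        raise ValueError(f"unknown copy_distribution {copy_distribution!r}")
    a = rng.binomial(n, 0.5)
    b = n - a
    f = np.stack([n, a, b], axis=1).astype(float) * nu + background
    if noise_sd > 0:
        f += rng.normal(0.0, noise_sd, size=f.shape)
    return [PartitionTriplet(*row) for row in f]


def gen_decay_traces(
    count: int,
    seed: int,
    onset_jitter: float = 2.0,
    decay_width: float = 1.5,
    reporter_lag: float = 5.0,
    t_span: tuple[float, float] = (-20.0, 20.0),
    d_t: float = 0.5,
    plateau: float = 1.0,
    floor: float = 0.2,
    noise_sd: float = 0.0,
) -> tuple[list[FluorescenceTrace], np.ndarray]:
    """Sigmoidal autofluorescence decays with jittered, known onset times.

    Each cell's autofluorescence falls from ``plateau`` to ``floor`` along
    a logistic sigmoid of width ``decay_width`` centred at a per-cell onset
    drawn uniformly from ±``onset_jitter``.  The reporter channel is a
    switch-like rise lagging the onset by ``reporter_lag`` (mimicking the
    delayed induction of the late inhibitor).  Returns the traces and the
    ground-truth onsets.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(t_span[0], t_span[1] + d_t / 2, d_t)
    onsets = rng.uniform(-onset_jitter, onset_jitter, size=count)
    traces = []
    for cid, t0 in enumerate(onsets):
        decay = 1.0 / (1.0 + np.exp((times - t0) / decay_width))
        af = floor + (plateau - floor) * decay
        rise = 1.0 / (1.0 + np.exp(-(times - t0 - reporter_lag) / (decay_width / 2)))
        fl = rise.copy()
        if noise_sd > 0:
            af = af + rng.normal(0.0, noise_sd, size=times.size)
            fl = fl + rng.normal(0.0, noise_sd, size=times.size)
        traces.append(
            FluorescenceTrace(
                times=times, fluorescence=fl, autofluorescence=af, cell_id=cid
            )
        )
    return traces, onsets


def gen_perturbed_field(
    eq: HomogeneousEquilibrium,
    amplitude: float,
    n_cells: int,
    seed: int,
) -> np.ndarray:
    """Uniform state plus a small random perturbation, the standard initial
    condition for pattern-formation runs.

    Each cell and species independently receives a relative perturbation
    uniform on [−amplitude, +amplitude]; results are clipped at zero.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    base = np.tile(eq.state, (n_cells, 1))
    pert = rng.uniform(-amplitude, amplitude, size=base.shape)
    return np.clip(base * (1.0 + pert), 0.0, None)
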