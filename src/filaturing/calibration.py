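"""Fluorescence calibration and trace alignment.

Absolute molecule numbers are inferred from mother→daughter partitioning
statistics.  With fluorescence proportional to copy number, y = ν n, and
binomial allocation of the mother's n molecules at division, the daughter
difference satisfies Var(f_a − f_b | mother) = ν² n = ν f_mother, so the
per-molecule brightness is estimated as

    ν̂ = ⟨ (f_a − f_b)² / f_mother ⟩

over mother–daughter triplets, after subtracting a constant background.
Copy numbers follow as n̂ = f / ν̂.

Time-lapse traces from different cells are registered on a common clock by
shifting each cell so that the midpoint of its autofluorescence decay
(photosynthetic-pigment degradation after nitrogen step-down) defines
t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PartitionTriplet",
    "FluorescenceTrace",
    "estimate_nu",
    "NuEstimate",
    "align_traces_by_half_decay",
]


@dataclass(frozen=True)
class PartitionTriplet:
    """Fluorescence of a mother cell and its two daughters after division."""

    mother: float
    daughter_a: float
    daughter_b: float
    mother_area: float | None = None


@dataclass
class FluorescenceTrace:
    """Per-cell time series of reporter fluorescence and autofluorescence."""

    times: np.ndarray
    fluorescence: np.ndarray
    autofluorescence: np.ndarray
    cell_id: int | str = 0
    shift: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.autofluorescence = np.asarray(self.autofluorescence, dtype=float)


@dataclass(frozen=True)
class NuEstimate:
    """Per-molecule brightness ν̂ with bootstrap uncertainty."""

    nu: float
    stderr: float
    n_triplets: int
    n_clipped: int
    copy_numbers: np.ndarray = field(repr=False)


def _subtract_background(
    triplets: list[PartitionTriplet], background: float
) -> tuple[np.ndarray, int]:
    arr = np.array(
        [[t.mother, t.daughter_a, t.daughter_b] for t in triplets], dtype=float
    )
    arr -= background
    n_clipped = int(np.sum(arr < 0))
    return np.clip(arr, 0.0, None), n_clipped


def estimate_nu(
    triplets: list[PartitionTriplet],
    background: float = 0.0,
    bleach_correction: bool = False,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> NuEstimate:
    """Estimate the fluorescence-per-molecule constant ν from divisions.

    Parameters
    ----------
    triplets : list of PartitionTriplet
        At least 2 mother–daughter triplets.
    background : float
        Constant offset subtracted from every fluorescence value (negative
        results are clipped at zero and counted).
    bleach_correction : bool
        Rescale each daughter pair so it sums to the mother in expectation
        (compensates photobleaching between frames); off by default.
    n_bootstrap : int
        Resamples for the standard error.

    Returns
    -------
    NuEstimate
        ν̂, bootstrap standard error, and the mothers' inferred copy
        numbers n̂ = f/ν̂.

    Raises
    ------
    ValueError
        Fewer than 2 usable triplets, or all mothers zero after background
        subtraction (the estimator is undefined).
    """
    if len(triplets) < 2:
        raise ValueError("need at least 2 triplets")
    arr, n_clipped = _subtract_background(triplets, background)
    mothers = arr[:, 0]
    daughters = arr[:, 1:]
    if bleach_correction:
        sums = daughters.sum(axis=1)
        ok = sums > 0
        scale = np.mean(mothers[ok] / sums[ok]) if ok.any() else 1.0
        daughters = daughters * scale
    usable = mothers > 0
    if not usable.any():
        raise ValueError("all mother fluorescences are zero after background subtraction")
    diff2 = (daughters[:, 0] - daughters[:, 1]) ** 2
    ratios = diff2[usable] / mothers[usable]
    nu = float(np.mean(ratios))
    rng = np.random.default_rng(seed)
    if ratios.size >= 2 and n_bootstrap > 0:
        idx = rng.integers(0, ratios.size, size=(n_bootstrap, ratios.size))
        stderr = float(np.std(np.mean(ratios[idx], axis=1), ddof=1))
    else:
        stderr = float("nan")
    copy_numbers = mothers / nu if nu > 0 else np.full_like(mothers, np.nan)
    return NuEstimate(
        nu=nu,
        stderr=stderr,
        n_triplets=int(usable.sum()),
        n_clipped=n_clipped,
        copy_numbers=copy_numbers,
    )


def _half_decay_time(
    times: np.ndarray, signal: np.ndarray, edge_fraction: float, smooth: int
) -> float | None:
    """Time where the signal crosses midway between plateau and floor."""
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        signal = np.convolve(signal, kernel, mode="same")
        # convolution shrinks the ends; restore them from the raw signal
    n_edge = max(1, int(round(edge_fraction * signal.size)))
    plateau = float(np.mean(signal[:n_edge]))
    floor = float(np.mean(signal[-n_edge:]))
    if plateau <= floor:
        return None
    half = 0.5 * (plateau + floor)
    below = signal < half
    if not below.any() or below[0]:
        return None
    j = int(np.argmax(below))
    t0, t1 = times[j - 1], times[j]
    y0, y1 = signal[j - 1], signal[j]
    if y1 == y0:
        return float(t1)
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def align_traces_by_half_decay(
    traces: list[FluorescenceTrace],
    edge_fraction: float = 0.1,
    smooth: int = 3,
) -> tuple[list[FluorescenceTrace], list[tuple[int | str, str]]]:
    """Shift every trace so its autofluorescence half-decay sits at t = 0.

    The pre-decay plateau and post-decay floor are estimated from the first
    and last ``edge_fraction`` of samples (after a short moving-average
    smoothing); the half-decay time is found by linear interpolation of the
    first downward crossing of the midpoint.  Both channels of a trace are
    shifted by the same amount.

    Returns
    -------
    (aligned, excluded)
        Aligned traces (with ``shift`` recorded), and a list of
        (cell_id, reason) for traces with no usable crossing.
    """
    aligned: list[FluorescenceTrace] = []
    excluded: list[tuple[int | str, str]] = []
    for tr in traces:
        t_half = _half_decay_time(tr.times, tr.autofluorescence, edge_fraction, smooth)
        if t_half is None:
            excluded.append((tr.cell_id, "no crossing"))
            continue
        aligned.append(
            FluorescenceTrace(
                times=tr.times - t_half,
                fluorescence=tr.fluorescence,
                autofluorescence=tr.autofluorescence,
                cell_id=tr.cell_id,
                shift=-t_half,
            )
        )
    return aligned, excluded
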