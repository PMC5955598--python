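"""Discrete spatial support for filament models.

Cells of a filament are arranged on a one-dimensional chain with
nearest-neighbour coupling.  Inhibitor hopping between cells is encoded by the
graph Laplacian ``Δ = W - diag(k)`` of the chain, whose eigenvectors supply
the discrete analogue of a Fourier basis: spatial fields are analysed by
projecting onto the Laplacian eigenmodes, and linear stability is resolved
mode by mode through the eigenvalues ``Λ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChainLattice", "build_chain", "mode_transform", "mode_reconstruct"]


@dataclass(frozen=True)
class ChainLattice:
    """A 1-D chain of cells with its Laplacian eigensystem.

    Attributes
    ----------
    n_cells : int
        Number of cells Ω.
    adjacency : (Ω, Ω) ndarray
        Symmetric 0/1 adjacency matrix W.
    connectivity : (Ω,) ndarray
        Per-cell degree k_i (2 in the interior, 1 at open ends).
    laplacian : (Ω, Ω) ndarray
        Δ = W − diag(k); symmetric, rows sum to zero, negative semidefinite.
    eigenvalues : (Ω,) ndarray
        Λ^(α), sorted descending so Λ^(1) = 0 comes first; all in [−4, 0].
    eigenvectors : (Ω, Ω) ndarray
        Orthonormal columns v^(α) matching ``eigenvalues`` order.
    periodic : bool
        Whether the chain is closed into a ring (default open / zero-flux).
    """

    n_cells: int
    adjacency: np.ndarray = field(repr=False)
    connectivity: np.ndarray = field(repr=False)
    laplacian: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)
    periodic: bool = False

    def to_edge_table(self) -> pd.DataFrame:
        """Edge list (i, j) with i < j, as a DataFrame."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return pd.DataFrame({"i": ii, "j": jj})

    @staticmethod
    def from_edge_table(edges: pd.DataFrame) -> "ChainLattice":
        """Rebuild a chain from an (i, j) edge list written by
        :meth:`to_edge_table`.  The edges must form a single path."""
        n = int(max(edges["i"].max(), edges["j"].max())) + 1
        w = np.zeros((n, n))
        w[edges["i"], edges["j"]] = 1.0
        w[edges["j"], edges["i"]] = 1.0
        degrees = np.sort(w.sum(axis=1))
        periodic = bool(n > 2 and degrees[0] == 2)
        is_path = (n == 1) or (
            (not periodic and np.all(degrees[:2] == 1) and np.all(degrees[2:] == 2))
            or (periodic and np.all(degrees == 2))
        )
        if not is_path:
            raise ValueError("edge list does not describe a single chain")
        # map back onto canonical cell order by walking the path
        lat = build_chain(n, periodic=periodic)
        if not np.array_equal(lat.adjacency, w):
            raise ValueError("edge list is not in canonical cell order")
        return lat

    def eigensystem_table(self) -> pd.DataFrame:
        """Long table (mode, eigenvalue, cell, component) of the eigenbasis."""
        rows = []
        for a in range(self.n_cells):
            for j in range(self.n_cells):
                rows.append((a, self.eigenvalues[a], j, self.eigenvectors[j, a]))
        return pd.DataFrame(rows, columns=["mode", "eigenvalue", "cell", "component"])


def _chain_adjacency(n: int, periodic: bool) -> np.ndarray:
    w = np.zeros((n, n))
    idx = np.arange(n - 1)
    w[idx, idx + 1] = 1.0
    w[idx + 1, idx] = 1.0
    if periodic and n > 2:
        w[0, -1] = w[-1, 0] = 1.0
    return w


def build_chain(n_cells: int, periodic: bool = False) -> ChainLattice:
    """Construct the Ω-cell chain lattice and its Laplacian eigensystem.

    Parameters
    ----------
    n_cells : int
        Number of cells Ω ≥ 1.
    periodic : bool, optional
        Close the chain into a ring.  The default open chain imposes
        zero-flux boundaries: end cells have a single neighbour.

    Returns
    -------
    ChainLattice
        Eigenpairs sorted by descending eigenvalue (the uniform Λ=0 mode
        first); eigenvector signs fixed so the first component of
        nonvanishing modulus is positive.
    """
    if not isinstance(n_cells, (int, np.integer)) or isinstance(n_cells, bool):
        raise TypeError(f"cell count must be an integer, got {n_cells!r}")
    if n_cells < 1:
        raise ValueError(f"cell count must be >= 1, got {n_cells}")
    n = int(n_cells)
    w = _chain_adjacency(n, periodic)
    k = w.sum(axis=1)
    lap = w - np.diag(k)
    evals, evecs = np.linalg.eigh(lap)
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    # snap the kernel eigenvalue that eigh returns as ~1e-16
    evals[np.abs(evals) < 1e-12] = 0.0
    # deterministic sign: first component with |v_j| > tol positive
    for a in range(n):
        v = evecs[:, a]
        j = np.argmax(np.abs(v) > 1e-8)
        if v[j] < 0:
            evecs[:, a] = -v
    return ChainLattice(
        n_cells=n,
        adjacency=w,
        connectivity=k,
        laplacian=lap,
        eigenvalues=evals,
        eigenvectors=evecs,
        periodic=periodic,
    )


def mode_transform(field: np.ndarray, lattice: ChainLattice) -> np.ndarray:
    """Project a spatial field (or time series of fields) onto Laplacian modes.

    Parameters
    ----------
    field : (Ω,) or (T, Ω) ndarray
        One spatial profile per row.
    lattice : ChainLattice

    Returns
    -------
    ndarray of matching shape
        Coefficients a_α = Σ_j f_j v_j^(α), the discrete analogue of spatial
        Fourier amplitudes on the open chain.
    """
    field = np.asarray(field, dtype=float)
    if field.shape[-1] != lattice.n_cells:
        raise ValueError(
            f"field has {field.shape[-1]} cells, lattice has {lattice.n_cells}"
        )
    return field @ lattice.eigenvectors


def mode_reconstruct(coeffs: np.ndarray, lattice: ChainLattice) -> np.ndarray:
    """Inverse of :func:`mode_transform` (orthonormal basis, so a transpose)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != lattice.n_cells:
        raise ValueError(
            f"coefficients have {coeffs.shape[-1]} modes, lattice has {lattice.n_cells}"
        )
    return coeffs @ lattice.eigenvectors.T
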