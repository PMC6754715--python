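"""Hermitian operator construction and the unitaries derived from them.

Two routes to a Hermitian generator:

* the kernel method — a squared-exponential kernel evaluated at grid
  midpoints gives a real symmetric positive semi-definite matrix;
* the Hamiltonian method — kinetic plus potential energy,
  H = -sigma * d^2/dx^2 + V(x), with hard-wall (Dirichlet) boundaries on
  the bounded rating interval, discretized by the three-point second
  difference.

Unitaries are always built through the spectral decomposition of the
generator (U = sum_j exp(i c lambda_j) V_j V_j^dagger), never through series
expansions, so they are unitary to round-off by construction.  Two sign
conventions coexist in the framework: the kernel route exponentiates with
+i, the Schrodinger route with -i t; they agree through
``spectral_unitary(H) == evolution_unitary(H, -1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, InvalidOperatorError
from .hilbert import Grid, OperatorMatrix

__all__ = [
    "SpectralDecomposition",
    "PotentialSpec",
    "HamiltonianParams",
    "spectral_decompose",
    "kernel_hermitian",
    "spectral_unitary",
    "hamiltonian",
    "evolution_unitary",
]


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigenpairs of a Hermitian operator, ordered by descending |eigenvalue|."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns

    def reconstruct(self) -> np.ndarray:
        v = self.eigenvectors
        return (v * self.eigenvalues) @ v.conj().T

    def function_of(self, f) -> np.ndarray:
        """Apply a scalar function to the spectrum: sum f(lambda_j) V_j V_j^dagger."""
        v = self.eigenvectors
        return (v * f(self.eigenvalues)) @ v.conj().T


@dataclass(frozen=True)
class PotentialSpec:
    """Potential energy V(x): none, linear (slope * x), quadratic (x^2), or tabulated."""

    form: Literal["none", "linear", "quadratic", "tabulated"] = "none"
    slope: float = 0.0
    table: Optional[Sequence[float]] = None

    def values(self, grid: Grid) -> np.ndarray:
        x = grid.midpoints
        if self.form == "none":
            return np.zeros_like(x)
        if self.form == "linear":
            return self.slope * x
        if self.form == "quadratic":
            return x**2
        if self.form == "tabulated":
            t = np.asarray(self.table, dtype=float)
            if t.shape != x.shape:
                raise InvalidArgumentError(
                    f"tabulated potential has {t.shape[0] if t.ndim else 0} entries, "
                    f"grid has {x.shape[0]} cells"
                )
            return t
        raise InvalidArgumentError(f"unknown potential form {self.form!r}")


@dataclass(frozen=True)
class HamiltonianParams:
    """Kinetic coefficient sigma (> 0) and a potential specification."""

    kinetic_coeff: float = 1.0
    potential: PotentialSpec = field(default_factory=PotentialSpec)

    def __post_init__(self) -> None:
        if not (self.kinetic_coeff > 0 and math.isfinite(self.kinetic_coeff)):
            raise InvalidArgumentError("kinetic_coeff must be positive and finite")


def spectral_decompose(h: OperatorMatrix) -> SpectralDecomposition:
    """Eigendecomposition of a Hermitian operator (descending |lambda|)."""
    if h.tag != "hermitian":
        raise InvalidOperatorError("spectral decomposition requires a hermitian tag")
    lam, vec = np.linalg.eigh(h.entries)
    order = np.argsort(-np.abs(lam), kind="stable")
    return SpectralDecomposition(lam[order], vec[:, order])


def kernel_hermitian(grid: Grid, bandwidth: float) -> OperatorMatrix:
    """Squared-exponential kernel matrix H_ij = exp(-((x_i - x_j)/bandwidth)^2)."""
    if not (bandwidth > 0 and math.isfinite(bandwidth)):
        raise InvalidArgumentError("bandwidth must be positive and finite")
    x = grid.midpoints
    d = (x[:, None] - x[None, :]) / bandwidth
    return OperatorMatrix(grid, np.exp(-(d**2)).astype(complex), "hermitian", validate=False)


def spectral_unitary(h: OperatorMatrix) -> OperatorMatrix:
    """U = sum_j exp(+i lambda_j) V_j V_j^dagger (kernel-method sign convention)."""
    dec = spectral_decompose(h)
    u = dec.function_of(lambda lam: np.exp(1j * lam))
    return OperatorMatrix(h.grid, u, "unitary", validate=False)


def hamiltonian(grid: Grid, params: HamiltonianParams) -> OperatorMatrix:
    """H = -sigma * D2 + diag(V(x)) with Dirichlet hard walls at the interval ends.

    D2 is the three-point second difference divided by spacing^2; the
    resulting matrix is real symmetric tridiagonal.
    """
    n = grid.n_cells
    sig = params.kinetic_coeff
    inv_h2 = 1.0 / grid.spacing**2
    diag = 2.0 * sig * inv_h2 + params.potential.values(grid)
    off = -sig * inv_h2 * np.ones(n - 1)
    h = np.diag(diag.astype(complex)) + np.diag(off, 1) + np.diag(off, -1)
    return OperatorMatrix(grid, h, "hermitian", validate=False)


def evolution_unitary(h: OperatorMatrix, t: float) -> OperatorMatrix:
    """Schrodinger propagator U(t) = exp(-i t H) via the spectral decomposition."""
    if not math.isfinite(t):
        raise InvalidArgumentError("evolution time must be finite")
    dec = spectral_decompose(h)
    u = dec.function_of(lambda lam: np.exp(-1j * t * lam))
    return OperatorMatrix(h.grid, u, "unitary", validate=False)
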