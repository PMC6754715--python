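"""Discretized Hilbert space on a bounded rating interval.

The model space is L2 functions on a bounded interval [l, u] (the rating
scale).  We discretize with a cell-centered uniform grid: amplitudes live on
cell midpoints and the inner product is the midpoint quadrature

    <psi | phi> = spacing * sum_i conj(psi_i) * phi_i.

Because the quadrature weight is a single scalar, matrix Hermiticity and
unitarity in the plain linear-algebra sense coincide with the weighted
sense, so operators are ordinary dense matrices.

Interval thresholds are snapped to the nearest cell *boundary*, which makes
every interval projector an exact 0/1 diagonal matrix and keeps projector
algebra exact (P(a) P(b) = P(min(a, b)) without round-off).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    DegenerateStateError,
    IncompatibleGridsError,
    InvalidArgumentError,
    InvalidIntervalError,
    OutOfRangeError,
)

__all__ = [
    "Grid",
    "StateVector",
    "OperatorMatrix",
    "make_grid",
    "inner_product",
    "normalize",
    "interval_projector",
    "bin_projector",
    "event_probability",
]

OperatorTag = Literal["hermitian", "unitary", "projector", "generic"]

#: default resolution for a 0-100 rating scale: one cell per rating point
DEFAULT_RATING_CELLS = 101


@dataclass(frozen=True)
class Grid:
    """Cell-centered uniform grid on [lower, upper] with n_cells cells."""

    lower: float
    upper: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise InvalidArgumentError("grid bounds must be finite")
        if self.upper <= self.lower:
            raise InvalidArgumentError("grid requires upper > lower")
        if self.n_cells < 2:
            raise InvalidArgumentError("grid requires n_cells >= 2")

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / self.n_cells

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower + (np.arange(self.n_cells) + 0.5) * self.spacing

    @property
    def boundaries(self) -> np.ndarray:
        """The n_cells + 1 cell edges, including both interval endpoints."""
        return self.lower + np.arange(self.n_cells + 1) * self.spacing

    def snap_index(self, a: float) -> int:
        """Index of the cell boundary nearest to ``a`` (0 .. n_cells)."""
        if not math.isfinite(a):
            raise InvalidArgumentError("threshold must be finite")
        k = int(round((a - self.lower) / self.spacing))
        return min(max(k, 0), self.n_cells)

    def to_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper, "n_cells": self.n_cells}

    @classmethod
    def from_dict(cls, d: dict) -> "Grid":
        return cls(float(d["lower"]), float(d["upper"]), int(d["n_cells"]))


def make_grid(lower: float, upper: float, n_cells: int) -> Grid:
    """Build a cell-centered uniform grid on [lower, upper]."""
    return Grid(float(lower), float(upper), int(n_cells))


@dataclass
class StateVector:
    """Complex amplitudes over grid cells; psi with rho = psi psi^dagger implicit."""

    grid: Grid
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex)
        if amp.shape != (self.grid.n_cells,):
            raise InvalidArgumentError(
                f"amplitudes shape {amp.shape} does not match grid "
                f"({self.grid.n_cells} cells)"
            )
        self.amplitudes = amp

    @property
    def norm_squared(self) -> float:
        return float(self.grid.spacing * np.sum(np.abs(self.amplitudes) ** 2))

    @property
    def probabilities(self) -> np.ndarray:
        """Cell probabilities |psi_i|^2 * spacing."""
        return np.abs(self.amplitudes) ** 2 * self.grid.spacing

    def mean(self) -> float:
        return float(np.sum(self.probabilities * self.grid.midpoints))

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum(self.probabilities * (self.grid.midpoints - m) ** 2))

    def to_dict(self) -> dict:
        return {
            **self.grid.to_dict(),
            "amplitudes": [
                {"re": float(a.real), "im": float(a.imag)} for a in self.amplitudes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateVector":
        grid = Grid.from_dict(d)
        amp = np.array([complex(a["re"], a["im"]) for a in d["amplitudes"]])
        return cls(grid, amp)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "StateVector":
        return cls.from_dict(json.loads(s))


@dataclass
class OperatorMatrix:
    """Dense operator on the grid, tagged with the algebraic class it claims.

    Tags are checked on construction (``validate=False`` skips the check for
    hot inner loops building many operators of a known-good shape).
    """

    grid: Grid
    entries: np.ndarray
    tag: OperatorTag = "generic"
    validate: bool = field(default=True, repr=False, compare=False)

    _TOL = 1e-10

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=complex)
        n = self.grid.n_cells
        if m.shape != (n, n):
            raise InvalidArgumentError(f"operator shape {m.shape}, expected ({n},{n})")
        self.entries = m
        if self.validate:
            self.check_tag()

    def check_tag(self) -> None:
        m, tol = self.entries, self._TOL
        if self.tag == "hermitian":
            if np.max(np.abs(m - m.conj().T)) >= tol:
                raise InvalidArgumentError("operator tagged hermitian is not")
        elif self.tag == "unitary":
            eye = np.eye(m.shape[0])
            if np.max(np.abs(m.conj().T @ m - eye)) >= tol:
                raise InvalidArgumentError("operator tagged unitary is not")
        elif self.tag == "projector":
            if np.max(np.abs(m @ m - m)) >= tol or np.max(np.abs(m - m.conj().T)) >= tol:
                raise InvalidArgumentError("operator tagged projector is not")

    def apply(self, psi: StateVector) -> StateVector:
        _require_same_grid(self.grid, psi.grid)
        return StateVector(psi.grid, self.entries @ psi.amplitudes)

    @property
    def dagger(self) -> "OperatorMatrix":
        return OperatorMatrix(self.grid, self.entries.conj().T, self.tag, validate=False)


def _require_same_grid(a: Grid, b: Grid) -> None:
    if a != b:
        raise IncompatibleGridsError(f"grids differ: {a} vs {b}")


def inner_product(psi: StateVector, phi: StateVector) -> complex:
    """<psi | phi> by midpoint quadrature (conjugate-linear in psi)."""
    _require_same_grid(psi.grid, phi.grid)
    return complex(psi.grid.spacing * np.vdot(psi.amplitudes, phi.amplitudes))


def normalize(psi: StateVector) -> StateVector:
    """Rescale to unit norm in the quadrature inner product."""
    n2 = psi.norm_squared
    if n2 <= 0.0 or not math.isfinite(n2):
        raise DegenerateStateError("cannot normalize a state with zero norm")
    return StateVector(psi.grid, psi.amplitudes / math.sqrt(n2))


def interval_projector(grid: Grid, a: float) -> OperatorMatrix:
    """Projector P(a) onto the event 'value <= a' (threshold snapped to a cell edge)."""
    if not (grid.lower <= a <= grid.upper):
        raise OutOfRangeError(f"threshold {a} outside [{grid.lower}, {grid.upper}]")
    k = grid.snap_index(a)
    diag = np.zeros(grid.n_cells)
    diag[:k] = 1.0
    return OperatorMatrix(grid, np.diag(diag).astype(complex), "projector", validate=False)


def bin_projector(grid: Grid, a: float, b: float) -> OperatorMatrix:
    """Projector P(b) - P(a) onto the half-open bin (a, b]."""
    if a >= b:
        raise InvalidIntervalError(f"bin requires a < b, got ({a}, {b})")
    pa = interval_projector(grid, a)
    pb = interval_projector(grid, b)
    return OperatorMatrix(grid, pb.entries - pa.entries, "projector", validate=False)


def event_probability(op: OperatorMatrix, psi: StateVector) -> float:
    """Pure-state probability ||op psi||^2 = tr[op rho op^dagger] with rho = psi psi^dagger."""
    _require_same_grid(op.grid, psi.grid)
    v = op.entries @ psi.amplitudes
    return float(psi.grid.spacing * np.sum(np.abs(v) ** 2))
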