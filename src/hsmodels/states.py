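"""Initial-state construction.

Two families of pure initial states are supported, mirroring the prior
distributions used by the matched Markov models in this literature:

* a real uniform amplitude on a sub-interval of the rating scale;
* a truncated complex Gaussian
      psi(x) = C * exp(i p x) * exp(-((x - mu)/sigma)^2 / 2),
  whose squared magnitudes form (up to truncation) a Gaussian density with
  mean mu and standard deviation sigma / sqrt(2).  The momentum parameter
  p only rotates phases, so it leaves the t = 0 distribution untouched but
  sets the drift rate of the packet under free (no-potential) dynamics.

Product states psi_X (x) * psi_Y (y) furnish the two-factor space used when
one observable commutes with a non-commuting pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateStateError,
    EmptySupportError,
    IncompatibleGridsError,
    InvalidArgumentError,
)
from .hilbert import Grid, StateVector, normalize

__all__ = [
    "GaussianStateParams",
    "ProductState",
    "uniform_state",
    "gaussian_state",
    "tensor_state",
]


@dataclass(frozen=True)
class GaussianStateParams:
    """Center mu, width sigma (> 0) and momentum p of a truncated Gaussian state."""

    center: float
    width: float
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and math.isfinite(self.width)):
            raise InvalidArgumentError("width must be positive and finite")
        if not math.isfinite(self.center) or not math.isfinite(self.momentum):
            raise InvalidArgumentError("center and momentum must be finite")


@dataclass
class ProductState:
    """Tensor product psi_L (x) psi_R with joint amplitude left_i * right_j."""

    left: StateVector
    right: StateVector

    def __post_init__(self) -> None:
        if self.left.grid != self.right.grid:
            raise IncompatibleGridsError("product state factors must share a grid")

    @property
    def grid(self) -> Grid:
        return self.left.grid

    @property
    def joint_amplitudes(self) -> np.ndarray:
        return np.outer(self.left.amplitudes, self.right.amplitudes)

    @property
    def joint_probabilities(self) -> np.ndarray:
        """Cell probabilities |psi(x_i, y_j)|^2 * spacing^2."""
        return np.abs(self.joint_amplitudes) ** 2 * self.grid.spacing**2

    def flatten(self) -> np.ndarray:
        """Amplitudes on the n^2-dimensional product space (row-major: left index first)."""
        return self.joint_amplitudes.reshape(-1)


def uniform_state(grid: Grid, support_lo: float, support_hi: float) -> StateVector:
    """Real constant amplitude on the cells inside (support_lo, support_hi]."""
    if support_lo >= support_hi:
        raise InvalidArgumentError("uniform support requires support_lo < support_hi")
    if support_lo < grid.lower or support_hi > grid.upper:
        raise InvalidArgumentError("uniform support must lie inside the grid interval")
    k_lo, k_hi = grid.snap_index(support_lo), grid.snap_index(support_hi)
    if k_hi <= k_lo:
        raise EmptySupportError("support contains no grid cells after snapping")
    amp = np.zeros(grid.n_cells, dtype=complex)
    amp[k_lo:k_hi] = 1.0 / math.sqrt((k_hi - k_lo) * grid.spacing)
    return StateVector(grid, amp)


def gaussian_state(grid: Grid, params: GaussianStateParams) -> StateVector:
    """Truncated complex Gaussian state, normalized numerically on the grid."""
    x = grid.midpoints
    envelope = np.exp(-0.5 * ((x - params.center) / params.width) ** 2)
    carrying = envelope**2 > 1e-14 * float(np.max(envelope) ** 2)
    if int(np.sum(carrying)) < 3:
        raise DegenerateStateError(
            "Gaussian width too small: fewer than 3 cells carry probability mass"
        )
    amp = np.exp(1j * params.momentum * x) * envelope
    return normalize(StateVector(grid, amp))


def tensor_state(left: StateVector, right: StateVector) -> ProductState:
    """Product state of two (normalized) single-factor states."""
    return ProductState(normalize(left), normalize(right))
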