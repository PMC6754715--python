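"""Classical comparator: drift-diffusion dynamics on the bounded rating scale.

The density p(t, x) of the confidence level follows the Kolmogorov forward
(Fokker-Planck) equation

    dp/dt = (sigma^2 / 2) d^2 p / dx^2  -  mu dp/dx,

discretized in finite-volume form on the same cell-centered grid as the
quantum model.  Fluxes through cell faces use a central difference for the
diffusive part and first-order upwinding for the drift part, with
zero-flux (reflecting) walls, so the generator's columns sum to zero
exactly (mass conservation) and all off-diagonal rates are non-negative
(non-negativity of the evolved density).

Classical measurement is observation without disturbance: conditioning a
density on a bin restricts and renormalizes it, and pooling the branches
of any schedule reproduces the unmeasured marginal exactly (marginal
invariance) by linearity -- the defining contrast with the quantum model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .errors import (
    ImpossibleOutcomeError,
    IncompatibleGridsError,
    InvalidArgumentError,
)
from .hilbert import Grid, OperatorMatrix
from .measurement import (
    BinScheme,
    ContextDistribution,
    EvolveEvent,
    MeasureEvent,
    MeasurementSchedule,
)

__all__ = [
    "MarkovParams",
    "ProbabilityDensity",
    "forward_generator",
    "evolve_density",
    "classical_condition",
    "markov_schedule",
]


@dataclass(frozen=True)
class MarkovParams:
    """Constant drift mu (x-units per time) and diffusion sigma (x-units per sqrt-time)."""

    drift: float
    diffusion: float

    def __post_init__(self) -> None:
        if not (self.diffusion > 0 and math.isfinite(self.diffusion)):
            raise InvalidArgumentError("diffusion must be positive and finite")
        if not math.isfinite(self.drift):
            raise InvalidArgumentError("drift must be finite")


@dataclass
class ProbabilityDensity:
    """Cell probability masses on a grid (density = mass / spacing)."""

    grid: Grid
    masses: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (self.grid.n_cells,):
            raise InvalidArgumentError("masses shape does not match grid")
        if np.min(m) < -1e-12:
            raise InvalidArgumentError("negative probability mass")
        self.masses = np.clip(m, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.masses.sum())

    @property
    def density(self) -> np.ndarray:
        return self.masses / self.grid.spacing

    def mean(self) -> float:
        return float(np.sum(self.masses * self.grid.midpoints) / self.total)

    def variance(self) -> float:
        m = self.mean()
        return float(np.sum(self.masses * (self.grid.midpoints - m) ** 2) / self.total)

    def normalized(self) -> "ProbabilityDensity":
        t = self.total
        if t <= 0:
            raise ImpossibleOutcomeError("cannot normalize a zero-mass density")
        return ProbabilityDensity(self.grid, self.masses / t)


def forward_generator(grid: Grid, params: MarkovParams) -> OperatorMatrix:
    """Finite-volume generator A with dm/dt = A m, reflecting walls.

    Face flux between cells i and i+1 (in mass units):
    drift carries the upwind cell's mass at rate |mu|/spacing; diffusion
    exchanges mass at rate D/spacing^2 with D = sigma^2/2.  Boundary faces
    carry no flux.
    """
    n = grid.n_cells
    h = grid.spacing
    d_rate = 0.5 * params.diffusion**2 / h**2
    mu_rate = params.drift / h
    a = np.zeros((n, n))
    for i in range(n - 1):
        # diffusive exchange across face (i, i+1)
        a[i, i] -= d_rate
        a[i + 1, i] += d_rate
        a[i + 1, i + 1] -= d_rate
        a[i, i + 1] += d_rate
        # upwinded drift across the same face
        if mu_rate >= 0:
            a[i, i] -= mu_rate
            a[i + 1, i] += mu_rate
        else:
            a[i + 1, i + 1] += mu_rate
            a[i, i + 1] -= mu_rate
    return OperatorMatrix(grid, a.astype(complex), "generic", validate=False)


def evolve_density(
    p0: ProbabilityDensity, params: MarkovParams, t: float
) -> ProbabilityDensity:
    """Propagate by the matrix exponential of the forward generator."""
    if not (t >= 0 and math.isfinite(t)):
        raise InvalidArgumentError("time must be finite and >= 0")
    if t == 0.0:
        return ProbabilityDensity(p0.grid, p0.masses.copy())
    a = forward_generator(p0.grid, params).entries.real
    return ProbabilityDensity(p0.grid, expm(t * a) @ p0.masses)


def classical_condition(
    p: ProbabilityDensity, bin_interval: tuple
) -> tuple:
    """(bin mass, renormalized restriction of p to the half-open bin (a, b])."""
    a, b = bin_interval
    if a >= b:
        raise InvalidArgumentError("bin requires a < b")
    k_lo, k_hi = p.grid.snap_index(a), p.grid.snap_index(b)
    mask = np.zeros(p.grid.n_cells)
    mask[k_lo:k_hi] = 1.0
    m = float(np.sum(p.masses * mask))
    if m <= 1e-300:
        raise ImpossibleOutcomeError("conditioning on a zero-mass bin")
    return m, ProbabilityDensity(p.grid, p.masses * mask / m)


def markov_schedule(
    p0: ProbabilityDensity,
    params: MarkovParams,
    schedule: MeasurementSchedule,
) -> ContextDistribution:
    """Joint outcome table of a schedule under drift-diffusion dynamics.

    Branches carry unnormalized masses (restriction without renormalizing),
    so a leaf's total mass is the joint path probability; zero-mass
    branches are carried with probability 0.
    """
    grid = p0.grid
    gen = forward_generator(grid, params).entries.real
    # one propagator per distinct duration, shared across branches
    props: dict = {}

    def propagator(t: float) -> np.ndarray:
        if t not in props:
            props[t] = expm(t * gen)
        return props[t]

    branches = [p0.masses.astype(float)]
    labels: list = []
    schemes: list = []
    for event in schedule.events:
        if isinstance(event, EvolveEvent):
            if event.duration > 0:
                u = propagator(event.duration)
                branches = [u @ m for m in branches]
            continue
        assert isinstance(event, MeasureEvent)
        event.bins.check_partition(grid)
        masks = event.bins.bin_masks(grid)
        branches = [np.where(mask, m, 0.0) for m in branches for mask in masks]
        labels.append(event.label)
        schemes.append(event.bins)
    shape = tuple(b.n_bins for b in schemes)
    probs = np.array([m.sum() for m in branches]).reshape(shape)
    return ContextDistribution(tuple(labels), tuple(schemes), probs, None)


def crank_nicolson_evolve(
    p0: ProbabilityDensity, params: MarkovParams, t: float, n_steps: int = 200
) -> ProbabilityDensity:
    """Independent Crank-Nicolson time stepper (cross-check for evolve_density)."""
    a = forward_generator(p0.grid, params).entries.real
    dt = t / n_steps
    n = p0.grid.n_cells
    eye = np.eye(n)
    lhs = eye - 0.5 * dt * a
    rhs = eye + 0.5 * dt * a
    step = np.linalg.solve(lhs, rhs)
    m = p0.masses.copy()
    for _ in range(n_steps):
        m = step @ m
    return ProbabilityDensity(p0.grid, np.clip(m, 0.0, None))
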