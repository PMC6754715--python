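"""Sequential contextual measurement: observables, POVM products, collapse.

An observable is an empirical variable whose event projectors are interval
projectors conjugated by a basis-change unitary:  P_X(x) = U_X P(x) U_X^†.
Two observables commute exactly when they share a basis unitary; distinct
generic bases make their projectors non-commuting and the theory then
predicts order effects and interference.

A *context* is an ordered tuple of observable labels.  The sequential
operator for outcome bins (b1, ..., bk) measured in that order is the
product of the per-step bin projectors applied right-to-left:

    Q = P_k(b_k) ... P_2(b_2) P_1(b_1),

with the first-measured projector acting on the state first.  Q is
generally not a projector; Q^† Q is an element of a positive
operator-valued measure, and the probability of the outcome tuple is
||Q psi||^2.

Measurement schedules interleave Schrodinger evolution with measurements;
because probabilities of full outcome paths factor into products of
collapse-conditional probabilities, branches are propagated unnormalized
and only squared at the leaves.

The two-factor space (one non-commuting pair X, Y on the left factor, a
third observable Z commuting with both on the right factor) is handled in
factorized form: for a product state the joint table is the outer product
of the left-factor sequential table over X, Y and the right-factor binned
table for Z, and the position of Z in the measurement order is irrelevant.
A dense product-space oracle in the test-suite pins this factorization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ImpossibleOutcomeError,
    IncompatibleGridsError,
    IncompletePartitionError,
    InvalidArgumentError,
    InvalidOperatorError,
    UnresolvedObservableError,
    UnsupportedStructureError,
)
from .hilbert import (
    Grid,
    OperatorMatrix,
    StateVector,
    bin_projector,
    event_probability,
    interval_projector,
)
from .operators import spectral_decompose
from .states import ProductState

__all__ = [
    "ObservableSpec",
    "BinScheme",
    "Context",
    "ContextDistribution",
    "MeasurementSchedule",
    "EvolveEvent",
    "MeasureEvent",
    "InterferenceResult",
    "observable_cdf_projector",
    "sequential_operator",
    "sequential_distribution",
    "collapse",
    "run_schedule",
    "interference_effect",
    "h2_sequential_distribution",
]


@dataclass(frozen=True)
class ObservableSpec:
    """An empirical variable: a label plus its basis-change unitary.

    ``basis_unitary=None`` means the identity (the variable is measured in
    the native grid basis).  ``factor`` only matters in the two-factor
    space and says which tensor factor the observable acts on.
    """

    label: str
    basis_unitary: Optional[OperatorMatrix] = None
    factor: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.basis_unitary is not None and self.basis_unitary.tag != "unitary":
            raise InvalidOperatorError(
                f"observable {self.label!r}: basis operator must be tagged unitary"
            )

    def basis_matrix(self, grid: Grid) -> Optional[np.ndarray]:
        if self.basis_unitary is None:
            return None
        if self.basis_unitary.grid != grid:
            raise IncompatibleGridsError(
                f"observable {self.label!r} basis lives on a different grid"
            )
        return self.basis_unitary.entries

    def shares_basis_with(self, other: "ObservableSpec") -> bool:
        a, b = self.basis_unitary, other.basis_unitary
        if a is None and b is None:
            return True
        if a is None or b is None:
            return False
        return bool(np.allclose(a.entries, b.entries, atol=1e-12))


@dataclass(frozen=True)
class BinScheme:
    """Half-open bins (e_j, e_{j+1}] covering the full interval [l, u]."""

    edges: tuple

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) < 2:
            raise InvalidArgumentError("bin scheme needs at least 2 edges")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise InvalidArgumentError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @classmethod
    def equal_width(cls, grid: Grid, n_bins: int) -> "BinScheme":
        if n_bins < 1:
            raise InvalidArgumentError("need at least one bin")
        return cls(tuple(np.linspace(grid.lower, grid.upper, n_bins + 1)))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def snapped(self, grid: Grid) -> "BinScheme":
        b = grid.boundaries
        snapped = tuple(float(b[grid.snap_index(e)]) for e in self.edges)
        if len(set(snapped)) != len(snapped):
            raise InvalidArgumentError("bin edges collapse onto each other after snapping")
        return BinScheme(snapped)

    def check_partition(self, grid: Grid) -> None:
        s = self.snapped(grid)
        if not (
            math.isclose(s.edges[0], grid.lower, abs_tol=1e-12)
            and math.isclose(s.edges[-1], grid.upper, abs_tol=1e-12)
        ):
            raise IncompletePartitionError(
                f"bin edges {self.edges} do not partition [{grid.lower}, {grid.upper}]"
            )

    def cell_bin_indices(self, grid: Grid) -> np.ndarray:
        """For each grid cell, the index of the bin containing its midpoint."""
        self.check_partition(grid)
        ks = [grid.snap_index(e) for e in self.snapped(grid).edges]
        out = np.empty(grid.n_cells, dtype=int)
        for j, (a, b) in enumerate(zip(ks, ks[1:])):
            out[a:b] = j
        return out

    def bin_masks(self, grid: Grid) -> np.ndarray:
        """(n_bins, n_cells) boolean masks of cells per bin."""
        idx = self.cell_bin_indices(grid)
        return idx[None, :] == np.arange(self.n_bins)[:, None]


@dataclass(frozen=True)
class Context:
    """Ordered tuple of observable labels measured together."""

    steps: tuple
    space: Literal["H", "H2"] = "H"

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        if not steps:
            raise InvalidArgumentError("context needs at least one step")
        if len(set(steps)) != len(steps):
            raise InvalidArgumentError("context labels must be distinct")
        object.__setattr__(self, "steps", steps)


@dataclass
class ContextDistribution:
    """Probability table over bin tuples for an ordered measurement context."""

    step_labels: tuple
    bin_schemes: tuple
    probabilities: np.ndarray
    context: Optional[Context] = None

    def __post_init__(self) -> None:
        shape = tuple(b.n_bins for b in self.bin_schemes)
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != shape:
            raise InvalidArgumentError(f"table shape {p.shape}, bins imply {shape}")
        if np.min(p) < -1e-12:
            raise InvalidArgumentError("negative probability in context table")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.probabilities.sum())

    def marginal(self, step: Union[int, str]) -> np.ndarray:
        if isinstance(step, str):
            step = self.step_labels.index(step)
        axes = tuple(i for i in range(self.probabilities.ndim) if i != step)
        return self.probabilities.sum(axis=axes)

    def to_dataframe(self, context_id: str = "ctx") -> pd.DataFrame:
        """Tidy table: one row per (bin tuple, step)."""
        rows = []
        for cell, idx in enumerate(iter_product(*(range(b.n_bins) for b in self.bin_schemes))):
            p = float(self.probabilities[idx])
            for order, (label, j) in enumerate(zip(self.step_labels, idx)):
                b = self.bin_schemes[order]
                rows.append(
                    {
                        "context_id": context_id,
                        "cell_id": cell,
                        "step_order": order,
                        "variable": label,
                        "bin_index": j,
                        "bin_lo": b.edges[j],
                        "bin_hi": b.edges[j + 1],
                        "probability": p,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvolveEvent:
    duration: float

    def __post_init__(self) -> None:
        if not (self.duration >= 0 and math.isfinite(self.duration)):
            raise InvalidArgumentError("evolution duration must be finite and >= 0")


@dataclass(frozen=True)
class MeasureEvent:
    label: str
    bins: BinScheme


@dataclass(frozen=True)
class MeasurementSchedule:
    """Alternating evolve/measure events; at least one measurement."""

    events: tuple

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        if not any(isinstance(e, MeasureEvent) for e in ev):
            raise InvalidArgumentError("schedule needs at least one measure event")
        object.__setattr__(self, "events", ev)

    @property
    def measure_events(self) -> tuple:
        return tuple(e for e in self.events if isinstance(e, MeasureEvent))


def _resolve(label: str, observables: Mapping[str, ObservableSpec]) -> ObservableSpec:
    try:
        return observables[label]
    except KeyError:
        raise UnresolvedObservableError(f"no observable registered for label {label!r}")


def observable_cdf_projector(obs: ObservableSpec, x: float, grid: Grid) -> OperatorMatrix:
    """P_X(x) = U_X P(x) U_X^† for the event 'X <= x'."""
    p = interval_projector(grid, x)
    u = obs.basis_matrix(grid)
    if u is None:
        return p
    return OperatorMatrix(grid, u @ p.entries @ u.conj().T, "projector", validate=False)


def _step_bin_projector(obs: ObservableSpec, bins: BinScheme, j: int, grid: Grid) -> OperatorMatrix:
    a, b = bins.snapped(grid).edges[j], bins.snapped(grid).edges[j + 1]
    p = bin_projector(grid, a, b)
    u = obs.basis_matrix(grid)
    if u is None:
        return p
    return OperatorMatrix(grid, u @ p.entries @ u.conj().T, "projector", validate=False)


def sequential_operator(
    context: Context,
    observables: Mapping[str, ObservableSpec],
    bin_choice: Sequence[tuple],
    grid: Grid,
) -> OperatorMatrix:
    """Product of per-step bin projectors, first-measured rightmost.

    ``bin_choice`` gives one (BinScheme, bin_index) pair per context step.
    The result is itself a projector only when all bases coincide.
    """
    if len(bin_choice) != len(context.steps):
        raise InvalidArgumentError("need exactly one bin choice per context step")
    q = np.eye(grid.n_cells, dtype=complex)
    for label, (bins, j) in zip(context.steps, bin_choice):
        obs = _resolve(label, observables)
        p = _step_bin_projector(obs, bins, j, grid)
        q = p.entries @ q  # later measurements compose on the left
    return OperatorMatrix(grid, q, "generic", validate=False)


def _branch_project(
    vec: np.ndarray, obs: ObservableSpec, masks: np.ndarray, grid: Grid
) -> list:
    """Split an (unnormalized) amplitude vector into per-bin projected vectors."""
    u = obs.basis_matrix(grid)
    if u is None:
        return [np.where(m, vec, 0.0) for m in masks]
    w = u.conj().T @ vec
    return [u @ np.where(m, w, 0.0) for m in masks]


def sequential_distribution(
    psi: StateVector,
    context: Context,
    observables: Mapping[str, ObservableSpec],
    bins: Sequence[BinScheme],
) -> ContextDistribution:
    """Joint table of ||Q psi||^2 over all bin tuples of an ordered context."""
    if len(bins) != len(context.steps):
        raise InvalidArgumentError("need one bin scheme per context step")
    grid = psi.grid
    for b in bins:
        b.check_partition(grid)
    branches = [psi.amplitudes]
    for label, scheme in zip(context.steps, bins):
        obs = _resolve(label, observables)
        masks = scheme.bin_masks(grid)
        branches = [v for vec in branches for v in _branch_project(vec, obs, masks, grid)]
    shape = tuple(b.n_bins for b in bins)
    probs = grid.spacing * np.array(
        [np.sum(np.abs(v) ** 2) for v in branches]
    ).reshape(shape)
    return ContextDistribution(tuple(context.steps), tuple(bins), probs, context)


def collapse(psi: StateVector, op: OperatorMatrix) -> StateVector:
    """Renormalized post-measurement state op psi / ||op psi||."""
    if op.grid != psi.grid:
        raise IncompatibleGridsError("collapse operator on a different grid")
    v = op.entries @ psi.amplitudes
    n = math.sqrt(psi.grid.spacing * float(np.sum(np.abs(v) ** 2)))
    if n <= 1e-14:
        raise ImpossibleOutcomeError("collapse onto a zero-probability outcome")
    return StateVector(psi.grid, v / n)


class _Propagator:
    """Caches the eigendecomposition of a Hermitian generator for repeated U(t) psi."""

    def __init__(self, h: OperatorMatrix):
        self.dec = spectral_decompose(h)

    def evolve(self, vec: np.ndarray, t: float) -> np.ndarray:
        if t == 0.0:
            return vec
        v = self.dec.eigenvectors
        return v @ (np.exp(-1j * t * self.dec.eigenvalues) * (v.conj().T @ vec))


def run_schedule(
    psi0: StateVector,
    schedule: MeasurementSchedule,
    dynamics: OperatorMatrix,
    observables: Mapping[str, ObservableSpec],
) -> ContextDistribution:
    """Joint outcome table of a schedule alternating evolution and measurement.

    Branches carry unnormalized amplitudes; a leaf's probability is
    spacing * ||amplitude||^2, which equals the product of successive
    collapse-conditional probabilities.  Zero-probability branches are kept
    with probability 0 so enumeration is total.
    """
    if dynamics.tag != "hermitian":
        raise InvalidOperatorError("schedule dynamics must be a hermitian generator")
    grid = psi0.grid
    if dynamics.grid != grid:
        raise IncompatibleGridsError("dynamics generator on a different grid")
    prop = _Propagator(dynamics)
    branches = [psi0.amplitudes]
    labels: list = []
    schemes: list = []
    for event in schedule.events:
        if isinstance(event, EvolveEvent):
            branches = [prop.evolve(v, event.duration) for v in branches]
            continue
        obs = _resolve(event.label, observables)
        event.bins.check_partition(grid)
        masks = event.bins.bin_masks(grid)
        branches = [v for vec in branches for v in _branch_project(vec, obs, masks, grid)]
        labels.append(event.label)
        schemes.append(event.bins)
    shape = tuple(b.n_bins for b in schemes)
    probs = grid.spacing * np.array(
        [np.sum(np.abs(v) ** 2) for v in branches]
    ).reshape(shape)
    return ContextDistribution(tuple(labels), tuple(schemes), probs, None)


@dataclass
class InterferenceResult:
    """Marginal-invariance violation at the second measurement time."""

    bin_scheme: BinScheme
    measured_marginal: np.ndarray  # pooled over first-measurement outcomes
    unmeasured_marginal: np.ndarray
    differences: np.ndarray
    total_variation: float


def interference_effect(
    psi0: StateVector,
    dynamics: OperatorMatrix,
    t1: float,
    t2: float,
    obs: ObservableSpec,
    bins: BinScheme,
    first_bins: Optional[BinScheme] = None,
) -> InterferenceResult:
    """Difference between the time-t2 marginal with vs without a time-t1 measurement.

    ``first_bins`` is the partition measured (and pooled over) at t1;
    it defaults to ``bins``.  t1 and t2 are absolute times, t2 >= t1 >= 0.
    """
    if not (0 <= t1 <= t2):
        raise InvalidArgumentError("need 0 <= t1 <= t2")
    fb = first_bins if first_bins is not None else bins
    observables = {obs.label: obs}
    with_meas = run_schedule(
        psi0,
        MeasurementSchedule(
            (
                EvolveEvent(t1),
                MeasureEvent(obs.label, fb),
                EvolveEvent(t2 - t1),
                MeasureEvent(obs.label, bins),
            )
        ),
        dynamics,
        observables,
    )
    without = run_schedule(
        psi0,
        MeasurementSchedule((EvolveEvent(t2), MeasureEvent(obs.label, bins))),
        dynamics,
        observables,
    )
    pooled = with_meas.probabilities.sum(axis=0)
    plain = without.probabilities
    diff = pooled - plain
    return InterferenceResult(bins, pooled, plain, diff, float(0.5 * np.abs(diff).sum()))


def h2_sequential_distribution(
    product_state: ProductState,
    context: Context,
    observables: Mapping[str, ObservableSpec],
    bins: Sequence[BinScheme],
) -> ContextDistribution:
    """Joint table on the two-factor space, computed in factorized form.

    Supported structure: at most two observables on the left factor (the
    possibly non-commuting pair) and any observables on the right factor,
    which commute with everything on the left.  For a product state the
    joint probability of (left bins, right bins) is the product of the
    left-factor sequential probability and the right-factor probability,
    independent of where the right-factor steps sit in the order.
    """
    if context.space != "H2":
        raise UnsupportedStructureError("context must be declared on the two-factor space")
    if len(bins) != len(context.steps):
        raise InvalidArgumentError("need one bin scheme per context step")
    specs = [_resolve(lbl, observables) for lbl in context.steps]
    left_pos = [i for i, s in enumerate(specs) if s.factor == "left"]
    right_pos = [i for i, s in enumerate(specs) if s.factor == "right"]
    if len(left_pos) > 2:
        raise UnsupportedStructureError(
            "two-factor contexts support at most two left-factor (non-commuting) steps"
        )

    def factor_table(positions, psi):
        if not positions:
            return None
        sub = Context(tuple(context.steps[i] for i in positions), "H")
        return sequential_distribution(
            psi, sub, observables, [bins[i] for i in positions]
        ).probabilities

    left_tab = factor_table(left_pos, product_state.left)
    right_tab = factor_table(right_pos, product_state.right)
    if left_tab is None:
        joint_sorted = right_tab
    elif right_tab is None:
        joint_sorted = left_tab
    else:
        joint_sorted = np.multiply.outer(left_tab, right_tab)
    # axes of joint_sorted follow left_pos + right_pos; restore step order
    perm = np.argsort(np.array(left_pos + right_pos))
    joint = np.transpose(joint_sorted, axes=perm)
    return ContextDistribution(tuple(context.steps), tuple(bins), joint, context)
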