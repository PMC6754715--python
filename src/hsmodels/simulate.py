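"""Seeded generators of multi-context binned rating datasets.

Every generator draws multinomial counts from an exact probability table —
produced by the quantum model, the Markov comparator, or an explicit
classical joint — with a single numpy PCG64 stream per dataset, and stamps
provenance (generator kind, parameters, seed, rng algorithm) into the
dataset metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError, UnresolvedObservableError
from .inference import (
    ClassicalJoint,
    ContextDataset,
    ContextRecord,
    RatingModelSpec,
)
from .measurement import BinScheme

__all__ = [
    "SimulationSpec",
    "simulate_dataset",
    "simulate_model_dataset",
    "simulate_from_tables",
    "make_context_free_fixture",
    "make_order_effect_fixture",
]

#: desk-scale default trials per context
DEFAULT_N_PER_CONTEXT = 5000


def _draw_counts(table: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    p = np.clip(np.asarray(table, dtype=float).reshape(-1), 0.0, None)
    p = p / p.sum()
    return rng.multinomial(n, p).reshape(table.shape).astype(float)


def _provenance(generator: str, seed: int, **extra) -> Dict:
    return {
        "generator": generator,
        "seed": int(seed),
        "rng": "numpy PCG64 (default_rng)",
        **extra,
    }


def simulate_from_tables(
    tables: Mapping[str, np.ndarray],
    labels: Mapping[str, Sequence[str]],
    bins: Mapping[str, Sequence[BinScheme]],
    n_per_context: int,
    seed: int,
    metadata: Optional[Dict] = None,
) -> ContextDataset:
    """Multinomial counts from explicit per-context probability tables."""
    if n_per_context < 1:
        raise InvalidArgumentError("n_per_context must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    registry: Dict[str, BinScheme] = {}
    for cid in tables:
        lab = tuple(labels[cid])
        sch = tuple(bins[cid])
        counts = _draw_counts(tables[cid], n_per_context, rng)
        records.append(ContextRecord(cid, lab, sch, counts))
        for lbl, scheme in zip(lab, sch):
            registry.setdefault(lbl, scheme)
    meta = metadata or _provenance("tables", seed)
    return ContextDataset(tuple(records), registry, meta)


def simulate_model_dataset(
    spec: RatingModelSpec,
    mu: float,
    sigma: float,
    n_per_condition: int = DEFAULT_N_PER_CONTEXT,
    seed: int = 0,
    conditions: Optional[Sequence[str]] = None,
) -> ContextDataset:
    """Sample a dataset from a quantum or Markov rating model at (mu, sigma)."""
    tables = spec.tables(mu, sigma)
    cond_ids = list(conditions) if conditions is not None else list(spec.conditions)
    tables = {cid: tables[cid] for cid in cond_ids}
    labels = {cid: spec.record_labels(cid) for cid in cond_ids}
    bins = {cid: spec.record_bins(cid) for cid in cond_ids}
    meta = _provenance(
        spec.kind, seed, params={"mu": float(mu), "sigma": float(sigma)},
        n_per_context=int(n_per_condition),
    )
    return simulate_from_tables(tables, labels, bins, n_per_condition, seed, meta)


def make_context_free_fixture(
    joint: ClassicalJoint,
    contexts: Sequence[Tuple[str, ...]],
    n_per_context: int = DEFAULT_N_PER_CONTEXT,
    seed: int = 0,
) -> ContextDataset:
    """Null fixture: every context's table is the corresponding margin of one joint.

    Both orders of the same variable set share one margin (transposed into
    the measurement order), so the dataset is context-free by construction.
    """
    rng = np.random.default_rng(seed)
    records = []
    registry: Dict[str, BinScheme] = {}
    for i, labels in enumerate(contexts):
        labels = tuple(labels)
        for lbl in labels:
            if lbl not in joint.variables:
                raise UnresolvedObservableError(f"unknown variable {lbl!r}")
        table = joint.margin(labels)
        schemes = tuple(joint.bin_schemes[joint.variables.index(lbl)] for lbl in labels)
        cid = "ctx_" + "_".join(labels)
        counts = _draw_counts(table, n_per_context, rng)
        records.append(ContextRecord(cid, labels, schemes, counts))
        for lbl, scheme in zip(labels, schemes):
            registry.setdefault(lbl, scheme)
    meta = _provenance("classical_joint", seed, n_per_context=int(n_per_context))
    return ContextDataset(tuple(records), registry, meta)


def make_order_effect_fixture(
    base_table: np.ndarray,
    bin_schemes: Tuple[BinScheme, BinScheme],
    delta: float,
    n_per_context: int = DEFAULT_N_PER_CONTEXT,
    seed: int = 0,
    labels: Tuple[str, str] = ("X", "Y"),
) -> ContextDataset:
    """Order-effect fixture: [X,Y] uses the base table; [Y,X] its transpose
    perturbed by moving ``delta`` of mass from the last diagonal cell to the
    first (then renormalized).  ``delta = 0`` gives a context-free dataset.
    """
    base = np.asarray(base_table, dtype=float)
    if base.ndim != 2:
        raise InvalidArgumentError("base table must be two-dimensional")
    base = base / base.sum()
    flipped = base.T.copy()
    if delta != 0.0:
        if flipped[-1, -1] - delta < 0 or flipped[0, 0] + delta > 1:
            raise InvalidArgumentError("delta infeasible for this base table")
        flipped[0, 0] += delta
        flipped[-1, -1] -= delta
        flipped = flipped / flipped.sum()
    x, y = labels
    tables = {f"ctx_{x}_{y}": base, f"ctx_{y}_{x}": flipped}
    labs = {f"ctx_{x}_{y}": (x, y), f"ctx_{y}_{x}": (y, x)}
    bins = {
        f"ctx_{x}_{y}": bin_schemes,
        f"ctx_{y}_{x}": (bin_schemes[1], bin_schemes[0]),
    }
    meta = _provenance(
        "order_effect", seed, delta=float(delta), n_per_context=int(n_per_context)
    )
    return simulate_from_tables(tables, labs, bins, n_per_context, seed, meta)


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of a dataset simulation (used by the CLI).

    ``generator`` is either a RatingModelSpec (with ``params``) or a
    ClassicalJoint (with ``contexts``).
    """

    generator: object
    n_per_context: int = DEFAULT_N_PER_CONTEXT
    seed: int = 0
    params: Mapping[str, float] = field(default_factory=dict)
    contexts: Tuple[Tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_context < 1:
            raise InvalidArgumentError("n_per_context must be >= 1")


def simulate_dataset(spec: SimulationSpec) -> ContextDataset:
    """Run a SimulationSpec, dispatching on its generator type."""
    gen = spec.generator
    if isinstance(gen, RatingModelSpec):
        return simulate_model_dataset(
            gen,
            mu=float(spec.params["mu"]),
            sigma=float(spec.params["sigma"]),
            n_per_condition=spec.n_per_context,
            seed=spec.seed,
        )
    if isinstance(gen, ClassicalJoint):
        if not spec.contexts:
            raise InvalidArgumentError("classical-joint simulation needs contexts")
        return make_context_free_fixture(
            gen, spec.contexts, spec.n_per_context, spec.seed
        )
    raise InvalidArgumentError(f"unsupported generator type {type(gen).__name__}")
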