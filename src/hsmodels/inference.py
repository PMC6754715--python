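"""Fitting and testing binned multi-context rating data.

Three layers:

* the *context-free* (classical, Kolmogorov) model: one joint distribution
  over all registered variables, every context's table a margin of it.
  Its maximum-likelihood fit is an expectation-maximization over the
  latent full joint, and the log-likelihood-ratio statistic

      G^2 = 2 sum_contexts sum_cells n log( n / (N_c * p_hat) )

  against the saturated per-context multinomials is the test for context
  effects (order effects and marginal-invariance violations load onto it);
* multinomial log-likelihoods of *generative* model tables (quantum or
  Markov) on the same data;
* bounded derivative-free maximum-likelihood fitting of the two-parameter
  (mu, sigma) quantum and Markov rating models, with seeded restarts,
  holdout prediction for unseen conditions, and BIC comparison.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import (
    IncomparableFitsError,
    InvalidArgumentError,
    SchemaMismatchError,
    UnidentifiableJointWarning,
    UnresolvedObservableError,
)
from .hilbert import Grid, StateVector
from .markov import MarkovParams, ProbabilityDensity, markov_schedule
from .measurement import (
    BinScheme,
    MeasureEvent,
    MeasurementSchedule,
    ObservableSpec,
    run_schedule,
)
from .operators import HamiltonianParams, PotentialSpec, hamiltonian
from .states import GaussianStateParams, gaussian_state, uniform_state

__all__ = [
    "ContextRecord",
    "ContextDataset",
    "ClassicalJoint",
    "ContextFreeTestResult",
    "RatingModelSpec",
    "FitResult",
    "HoldoutPrediction",
    "ModelComparison",
    "context_free_mle",
    "context_free_test",
    "model_loglik",
    "fit_model",
    "holdout_predict",
    "compare_models",
]

PROB_FLOOR = 1e-12  # floor inside logs; documented continuity convention


@dataclass
class ContextRecord:
    """Observed counts for one ordered measurement context."""

    context_id: str
    labels: Tuple[str, ...]
    bin_schemes: Tuple[BinScheme, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bin_schemes):
            raise InvalidArgumentError("one bin scheme per step required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidArgumentError("record labels must be distinct")
        c = np.asarray(self.counts, dtype=float)
        shape = tuple(b.n_bins for b in self.bin_schemes)
        if c.shape != shape:
            raise InvalidArgumentError(f"counts shape {c.shape}, bins imply {shape}")
        if np.min(c) < 0:
            raise InvalidArgumentError("counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class ContextDataset:
    """Collection of context records plus the variable registry (label -> bins)."""

    records: Tuple[ContextRecord, ...]
    registry: Dict[str, BinScheme]
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        if not self.records:
            raise InvalidArgumentError("dataset needs at least one record")
        for rec in self.records:
            for lbl, scheme in zip(rec.labels, rec.bin_schemes):
                if lbl not in self.registry:
                    raise UnresolvedObservableError(
                        f"record {rec.context_id!r} uses unregistered variable {lbl!r}"
                    )
                if self.registry[lbl].edges != scheme.edges:
                    raise SchemaMismatchError(
                        f"variable {lbl!r} binned differently in {rec.context_id!r} "
                        "than in the registry"
                    )

    @property
    def n_total(self) -> float:
        return float(sum(rec.total for rec in self.records))

    def signature(self) -> str:
        """Hash of counts + structure; identifies the data for fit comparability."""
        h = hashlib.sha256()
        for rec in sorted(self.records, key=lambda r: r.context_id):
            h.update(rec.context_id.encode())
            h.update(",".join(rec.labels).encode())
            h.update(np.ascontiguousarray(rec.counts).tobytes())
        return h.hexdigest()


@dataclass
class ClassicalJoint:
    """Context-free joint table over the full variable x bin lattice."""

    variables: Tuple[str, ...]
    bin_schemes: Tuple[BinScheme, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        shape = tuple(b.n_bins for b in self.bin_schemes)
        if t.shape != shape:
            raise InvalidArgumentError(f"joint shape {t.shape}, bins imply {shape}")
        if np.min(t) < -1e-12 or not math.isclose(t.sum(), 1.0, abs_tol=1e-6):
            raise InvalidArgumentError("joint must be a probability table")
        self.table = np.clip(t, 0.0, None)
        self.table /= self.table.sum()

    def margin(self, labels: Sequence[str]) -> np.ndarray:
        """Marginal table over ``labels``, axes in the order given."""
        for lbl in labels:
            if lbl not in self.variables:
                raise UnresolvedObservableError(f"unknown variable {lbl!r}")
        keep = [self.variables.index(lbl) for lbl in labels]
        drop = tuple(i for i in range(len(self.variables)) if i not in keep)
        m = self.table.sum(axis=drop)
        # axes of m follow sorted(keep); permute into requested order
        ranks = np.argsort(np.argsort(keep))
        return np.transpose(m, axes=ranks) if len(keep) > 1 else m


def _coverage_connected(data: ContextDataset) -> bool:
    nodes = set(data.registry)
    adj: Dict[str, set] = {v: set() for v in nodes}
    for rec in data.records:
        for a in rec.labels:
            adj[a].update(rec.labels)
    seen, stack = set(), [next(iter(nodes))]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v] - seen)
    return seen == nodes


def _record_margin(joint: ClassicalJoint, rec: ContextRecord) -> np.ndarray:
    return joint.margin(rec.labels)


def _observed_loglik(joint: ClassicalJoint, data: ContextDataset) -> float:
    ll = 0.0
    for rec in data.records:
        p = np.clip(_record_margin(joint, rec), PROB_FLOOR, None)
        ll += float(np.sum(rec.counts * np.log(p)))
    return ll


def context_free_mle(
    data: ContextDataset, max_iter: int = 500, tol: float = 1e-9
) -> Tuple[ClassicalJoint, Dict]:
    """EM fit of the single joint distribution behind all contexts.

    The E-step allocates each observed context-cell count across the
    unobserved variables proportionally to the current joint; the M-step
    renormalizes the pooled pseudo-counts.  Both orders of the same
    variable set act as replicate observations of one margin, so order
    effects in the data cannot be absorbed and instead inflate the test
    statistic.  Returns the fitted joint and an info dict with the
    (monotone) log-likelihood trace.
    """
    if not _coverage_connected(data):
        warnings.warn(
            "variable coverage across contexts is disconnected; "
            "the joint is not fully identifiable",
            UnidentifiableJointWarning,
        )
    variables = tuple(sorted(data.registry))
    schemes = tuple(data.registry[v] for v in variables)
    shape = tuple(b.n_bins for b in schemes)
    table = np.full(shape, 1.0 / float(np.prod(shape)))
    joint = ClassicalJoint(variables, schemes, table)
    trace = [_observed_loglik(joint, data)]
    converged = False
    for _ in range(max_iter):
        pseudo = np.zeros(shape)
        for rec in data.records:
            axes_keep = [variables.index(lbl) for lbl in rec.labels]
            drop = tuple(i for i in range(len(variables)) if i not in axes_keep)
            margin = joint.table.sum(axis=drop, keepdims=True)
            # counts aligned to joint axes (observed axes in registry order)
            sort_order = np.argsort(axes_keep)
            counts_sorted = np.transpose(rec.counts, axes=sort_order)
            expand = [slice(None) if i in axes_keep else None for i in range(len(variables))]
            counts_al = counts_sorted[tuple(expand)]
            ratio = np.where(margin > 0, counts_al / np.clip(margin, PROB_FLOOR, None), 0.0)
            pseudo += joint.table * ratio
        total = pseudo.sum()
        if total <= 0:
            break
        joint = ClassicalJoint(variables, schemes, pseudo / total)
        trace.append(_observed_loglik(joint, data))
        denom = abs(trace[-2]) + 1.0
        if abs(trace[-1] - trace[-2]) / denom < tol:
            converged = True
            break
    return joint, {"loglik_trace": trace, "converged": converged, "n_iter": len(trace) - 1}


@dataclass
class ContextFreeTestResult:
    """Log-likelihood-ratio test of the context-free joint."""

    joint: ClassicalJoint
    g2: float
    df: int
    p_value: float
    loglik_model: float
    loglik_saturated: float
    n_free_params: int


def context_free_test(
    data: ContextDataset, max_iter: int = 500, tol: float = 1e-9, zero_tol: float = 1e-10
) -> ContextFreeTestResult:
    """G^2 test of the fitted context-free joint against saturated multinomials.

    Degrees of freedom: sum_c (cells_c - 1) minus the number of free joint
    parameters, counted as the joint cells carrying fitted mass above
    ``zero_tol`` (structural zeros removed) minus one.
    """
    joint, _ = context_free_mle(data, max_iter=max_iter, tol=tol)
    g2 = 0.0
    ll_sat = 0.0
    ll_mod = 0.0
    df_sat = 0
    for rec in data.records:
        n_c = rec.total
        p_hat = np.clip(_record_margin(joint, rec), PROB_FLOOR, None)
        obs = rec.counts
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(obs > 0, obs * np.log(obs / (n_c * p_hat)), 0.0)
        g2 += 2.0 * float(term.sum())
        ll_mod += float(np.sum(obs * np.log(p_hat)))
        with np.errstate(divide="ignore", invalid="ignore"):
            ll_sat += float(np.sum(np.where(obs > 0, obs * np.log(obs / n_c), 0.0)))
        df_sat += obs.size - 1
    k_free = int(np.sum(joint.table > zero_tol)) - 1
    df = df_sat - k_free
    p = float(chi2.sf(g2, df)) if df > 0 else float("nan")
    return ContextFreeTestResult(joint, float(g2), df, p, ll_mod, ll_sat, k_free)


def model_loglik(
    tables: Mapping[str, np.ndarray], data: ContextDataset, floor: float = PROB_FLOOR
) -> float:
    """Multinomial log-likelihood of per-context model tables on the dataset."""
    ll = 0.0
    for rec in data.records:
        if rec.context_id not in tables:
            raise SchemaMismatchError(f"no model table for context {rec.context_id!r}")
        p = np.asarray(tables[rec.context_id], dtype=float)
        if p.shape != rec.counts.shape:
            raise SchemaMismatchError(
                f"model table shape {p.shape} mismatches counts {rec.counts.shape} "
                f"for context {rec.context_id!r}"
            )
        ll += float(np.sum(rec.counts * np.log(np.clip(p, floor, None))))
    return ll


@dataclass(frozen=True)
class RatingModelSpec:
    """A two-parameter (mu, sigma) generative rating model over timed conditions.

    kind='quantum': Schrodinger dynamics with kinetic coefficient sigma and
    linear potential slope mu; measurement collapses the state.
    kind='markov': drift-diffusion with drift mu and diffusion sigma;
    measurement conditions the density without disturbance.  Both use the
    same initial distribution (the Markov density is the squared magnitude
    of the quantum initial state), mirroring the matched-assumption design.
    """

    kind: str
    grid: Grid
    conditions: Mapping[str, MeasurementSchedule]
    initial: Mapping = field(default_factory=lambda: {"kind": "uniform"})
    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"mu": (-1.0, 1.0), "sigma": (0.01, 10.0)}
    )

    def __post_init__(self) -> None:
        if self.kind not in ("quantum", "markov"):
            raise InvalidArgumentError("model kind must be 'quantum' or 'markov'")
        if not self.conditions:
            raise InvalidArgumentError("model needs at least one condition")

    def initial_state(self) -> StateVector:
        init = dict(self.initial)
        kind = init.get("kind", "uniform")
        if kind == "gaussian":
            return gaussian_state(
                self.grid,
                GaussianStateParams(
                    center=float(init["center"]),
                    width=float(init["width"]),
                    momentum=float(init.get("momentum", 0.0)),
                ),
            )
        if kind == "uniform":
            lo = float(init.get("lo", self.grid.lower))
            hi = float(init.get("hi", self.grid.upper))
            return uniform_state(self.grid, lo, hi)
        raise InvalidArgumentError(f"unknown initial state kind {kind!r}")

    def _observables(self) -> Dict[str, ObservableSpec]:
        obs: Dict[str, ObservableSpec] = {}
        for sched in self.conditions.values():
            for ev in sched.measure_events:
                obs.setdefault(ev.label, ObservableSpec(ev.label))
        return obs

    def tables(self, mu: float, sigma: float) -> Dict[str, np.ndarray]:
        """Predicted probability tables for every condition at (mu, sigma)."""
        out: Dict[str, np.ndarray] = {}
        if self.kind == "quantum":
            psi0 = self.initial_state()
            h = hamiltonian(
                self.grid,
                HamiltonianParams(
                    kinetic_coeff=sigma, potential=PotentialSpec("linear", slope=mu)
                ),
            )
            obs = self._observables()
            for cid, sched in self.conditions.items():
                out[cid] = run_schedule(psi0, sched, h, obs).probabilities
        else:
            psi0 = self.initial_state()
            p0 = ProbabilityDensity(self.grid, psi0.probabilities)
            params = MarkovParams(drift=mu, diffusion=sigma)
            for cid, sched in self.conditions.items():
                out[cid] = markov_schedule(p0, params, sched).probabilities
        return out

    def record_labels(self, cond_id: str) -> Tuple[str, ...]:
        return tuple(ev.label for ev in self.conditions[cond_id].measure_events)

    def record_bins(self, cond_id: str) -> Tuple[BinScheme, ...]:
        return tuple(ev.bins for ev in self.conditions[cond_id].measure_events)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a rating model."""

    kind: str
    params: Dict[str, float]
    loglik: float
    bic: float
    n_obs: float
    n_free_params: int
    converged: bool
    seed: int
    restarts: int
    n_evals: int
    data_signature: str
    context_ids: Tuple[str, ...]


def fit_model(
    spec: RatingModelSpec,
    data: ContextDataset,
    seed: int = 0,
    restarts: int = 5,
    coarse: int = 4,
    maxfev: int = 250,
) -> FitResult:
    """Bounded derivative-free ML fit of (mu, sigma) with seeded restarts.

    A coarse lattice scan of the bounded box supplies the first start;
    the remaining ``restarts - 1`` starts are drawn uniformly from the box
    with a generator seeded by ``seed``, so refits are bit-identical.
    """
    if restarts < 1:
        raise InvalidArgumentError("need at least one restart")
    lo_mu, hi_mu = spec.bounds["mu"]
    lo_sg, hi_sg = spec.bounds["sigma"]
    fit_ids = tuple(cid for cid in spec.conditions if any(
        rec.context_id == cid for rec in data.records))
    if not fit_ids:
        raise SchemaMismatchError("no dataset record matches any model condition")
    sub_spec_conditions = {cid: spec.conditions[cid] for cid in fit_ids}
    n_evals = 0

    def negloglik(theta: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        mu = float(np.clip(theta[0], lo_mu, hi_mu))
        sg = float(np.clip(theta[1], lo_sg, hi_sg))
        part = RatingModelSpec(spec.kind, spec.grid, sub_spec_conditions, spec.initial, spec.bounds)
        return -model_loglik(part.tables(mu, sg), data_subset)

    data_subset = ContextDataset(
        tuple(rec for rec in data.records if rec.context_id in fit_ids),
        data.registry,
        data.metadata,
    )

    rng = np.random.default_rng(seed)
    mu_grid = np.linspace(lo_mu, hi_mu, coarse + 2)[1:-1]
    sg_grid = np.linspace(lo_sg, hi_sg, coarse + 2)[1:-1]
    scan = [(negloglik(np.array([m, s])), m, s) for m in mu_grid for s in sg_grid]
    best_scan = min(scan)
    starts = [np.array([best_scan[1], best_scan[2]])]
    for _ in range(restarts - 1):
        starts.append(
            np.array(
                [rng.uniform(lo_mu, hi_mu), rng.uniform(lo_sg, hi_sg)]
            )
        )
    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="Nelder-Mead",
            bounds=[(lo_mu, hi_mu), (lo_sg, hi_sg)],
            options={
                "maxfev": maxfev,
                "xatol": 1e-4 * max(hi_mu - lo_mu, hi_sg - lo_sg),
                "fatol": 1e-7,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    mu_hat = float(np.clip(best.x[0], lo_mu, hi_mu))
    sg_hat = float(np.clip(best.x[1], lo_sg, hi_sg))
    ll = -float(best.fun)
    n_obs = data_subset.n_total
    k = 2
    bic = k * math.log(n_obs) - 2.0 * ll
    return FitResult(
        kind=spec.kind,
        params={"mu": mu_hat, "sigma": sg_hat},
        loglik=ll,
        bic=bic,
        n_obs=n_obs,
        n_free_params=k,
        converged=converged,
        seed=seed,
        restarts=restarts,
        n_evals=n_evals,
        data_signature=data_subset.signature(),
        context_ids=fit_ids,
    )


@dataclass
class HoldoutPrediction:
    """Model table for an unseen condition, with its holdout log-likelihood."""

    cond_id: str
    table: np.ndarray
    holdout_loglik: Optional[float]


def holdout_predict(
    fit: FitResult,
    spec: RatingModelSpec,
    cond_id: str,
    data: Optional[ContextDataset] = None,
) -> HoldoutPrediction:
    """Predict a condition's table at the fitted parameters, with no refitting."""
    if cond_id not in spec.conditions:
        raise UnresolvedObservableError(f"model declares no condition {cond_id!r}")
    table = spec.tables(fit.params["mu"], fit.params["sigma"])[cond_id]
    ll = None
    if data is not None:
        recs = [rec for rec in data.records if rec.context_id == cond_id]
        if recs:
            ll = model_loglik({cond_id: table}, ContextDataset(tuple(recs), data.registry))
    return HoldoutPrediction(cond_id, table, ll)


@dataclass
class ModelComparison:
    """Delta BIC = BIC_A - BIC_B; negative favours model A."""

    delta_bic: float
    preferred: str


def compare_models(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    if fit_a.data_signature != fit_b.data_signature:
        raise IncomparableFitsError("fits were not obtained on identical data")
    delta = fit_a.bic - fit_b.bic
    preferred = fit_a.kind if delta < 0 else (fit_b.kind if delta > 0 else "tie")
    return ModelComparison(float(delta), preferred)
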