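"""Canned desk-scale study configurations.

`two_rating_study` replicates, at desk scale, the design in which a
confidence rating is requested at a pair (t1, t2) of times under three
conditions — (0.5 s, 1.5 s), (1.5 s, 2.5 s) and (0.5 s, 2.5 s) — on a
0-100 rating scale.  Variables R05, R15, R25 denote the rating at 0.5,
1.5 and 2.5 s; each condition observes two of the three, giving exactly
the overlapping-context structure (fit two conditions, predict the third).

`choice_confidence_study` replicates the earlier paradigm: a coarse
(binary) judgement at t1 followed by a full rating at t2, against the
rating-only control — the setting in which quantum collapse predicts an
interference effect on the pooled t2 marginal and the Markov comparator
predicts none.

Default truths were chosen once for identifiability on the 0-100 scale at
these time points (visible drift, diffusion and interference); the methods
note documents the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .hilbert import Grid, make_grid
from .measurement import (
    BinScheme,
    EvolveEvent,
    MeasureEvent,
    MeasurementSchedule,
)
from .inference import RatingModelSpec

__all__ = [
    "TwoRatingStudy",
    "two_rating_study",
    "choice_confidence_schedules",
]

#: default desk-scale true parameters
QUANTUM_TRUTH = {"mu": 0.08, "sigma": 50.0}
MARKOV_TRUTH = {"mu": 10.0, "sigma": 15.0}


@dataclass(frozen=True)
class TwoRatingStudy:
    """Both model specs plus truths for the three-condition rating design."""

    grid: Grid
    bins: BinScheme
    quantum: RatingModelSpec
    markov: RatingModelSpec
    quantum_truth: Dict[str, float]
    markov_truth: Dict[str, float]
    holdout: str = "cond3"

    @property
    def training_conditions(self) -> Tuple[str, str]:
        return ("cond1", "cond2")

    def spec(self, kind: str) -> RatingModelSpec:
        return self.quantum if kind == "quantum" else self.markov


def two_rating_study(
    n_cells: int = 50,
    n_bins: int = 5,
    times: Tuple[float, float, float] = (0.5, 1.5, 2.5),
) -> TwoRatingStudy:
    """Desk-scale three-condition rating study on the 0-100 scale."""
    grid = make_grid(0.0, 100.0, n_cells)
    bins = BinScheme.equal_width(grid, n_bins)
    t1, t2, t3 = times
    conditions = {
        "cond1": MeasurementSchedule(
            (
                EvolveEvent(t1),
                MeasureEvent("R05", bins),
                EvolveEvent(t2 - t1),
                MeasureEvent("R15", bins),
            )
        ),
        "cond2": MeasurementSchedule(
            (
                EvolveEvent(t2),
                MeasureEvent("R15", bins),
                EvolveEvent(t3 - t2),
                MeasureEvent("R25", bins),
            )
        ),
        "cond3": MeasurementSchedule(
            (
                EvolveEvent(t1),
                MeasureEvent("R05", bins),
                EvolveEvent(t3 - t1),
                MeasureEvent("R25", bins),
            )
        ),
    }
    initial = {"kind": "gaussian", "center": 50.0, "width": 20.0, "momentum": 0.0}
    quantum = RatingModelSpec(
        kind="quantum",
        grid=grid,
        conditions=conditions,
        initial=initial,
        bounds={"mu": (0.0, 0.3), "sigma": (5.0, 150.0)},
    )
    markov = RatingModelSpec(
        kind="markov",
        grid=grid,
        conditions=conditions,
        initial=initial,
        bounds={"mu": (-30.0, 30.0), "sigma": (2.0, 40.0)},
    )
    return TwoRatingStudy(
        grid, bins, quantum, markov, dict(QUANTUM_TRUTH), dict(MARKOV_TRUTH)
    )


def choice_confidence_schedules(
    grid: Grid,
    t1: float = 0.5,
    t2: float = 1.0,
    n_rating_bins: int = 5,
) -> Dict[str, MeasurementSchedule]:
    """Choice-confidence vs confidence-only schedules for interference tests."""
    choice_bins = BinScheme.equal_width(grid, 2)
    rating_bins = BinScheme.equal_width(grid, n_rating_bins)
    return {
        "choice_confidence": MeasurementSchedule(
            (
                EvolveEvent(t1),
                MeasureEvent("choice", choice_bins),
                EvolveEvent(t2 - t1),
                MeasureEvent("rating", rating_bins),
            )
        ),
        "confidence_only": MeasurementSchedule(
            (EvolveEvent(t2), MeasureEvent("rating", rating_bins))
        ),
    }
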