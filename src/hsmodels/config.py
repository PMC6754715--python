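"""Run-configuration schema (YAML or JSON) for the command-line interface.

Validation is strict: unknown keys are rejected, and every block is checked
before any computation starts.  A validated config materializes into the
library objects (Grid, schedules, RatingModelSpec, SimulationSpec).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import InvalidArgumentError
from .hilbert import Grid, make_grid
from .inference import RatingModelSpec
from .measurement import BinScheme, EvolveEvent, MeasureEvent, MeasurementSchedule
from .simulate import SimulationSpec

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(InvalidArgumentError):
    """Configuration file failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridBlock(_Strict):
    lower: float = 0.0
    upper: float = 100.0
    n_cells: int = Field(default=50, ge=2)


class InitialBlock(_Strict):
    kind: Literal["uniform", "gaussian"] = "gaussian"
    center: Optional[float] = None
    width: Optional[float] = None
    momentum: float = 0.0
    lo: Optional[float] = None
    hi: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "InitialBlock":
        if self.kind == "gaussian" and (self.center is None or self.width is None):
            raise ValueError("gaussian initial state needs center and width")
        return self


class ModelBlock(_Strict):
    kind: Literal["quantum", "markov"]
    mu: float
    sigma: float


class BinsBlock(_Strict):
    n_bins: Optional[int] = Field(default=5, ge=1)
    edges: Optional[List[float]] = None


class EventBlock(_Strict):
    evolve: Optional[float] = Field(default=None, ge=0)
    measure: Optional[str] = None
    bins: Optional[BinsBlock] = None

    @model_validator(mode="after")
    def _check(self) -> "EventBlock":
        if (self.evolve is None) == (self.measure is None):
            raise ValueError("each event is exactly one of {evolve: t} or {measure: label}")
        if self.evolve is not None and self.bins is not None:
            raise ValueError("bins only apply to measure events")
        return self


class FitBlock(_Strict):
    restarts: int = Field(default=5, ge=1)
    maxfev: int = Field(default=250, ge=10)
    mu_bounds: Tuple[float, float] = (-30.0, 30.0)
    sigma_bounds: Tuple[float, float] = (0.5, 150.0)


class InterferenceBlock(_Strict):
    t1: float = Field(default=0.5, ge=0)
    t2: float = Field(default=1.5, ge=0)
    n_first_bins: int = Field(default=2, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "InterferenceBlock":
        if self.t2 < self.t1:
            raise ValueError("need t2 >= t1")
        return self


class RunConfig(_Strict):
    """Top-level run configuration."""

    grid: GridBlock = GridBlock()
    model: ModelBlock
    initial: InitialBlock = InitialBlock(kind="gaussian", center=50.0, width=20.0)
    bins: BinsBlock = BinsBlock()
    conditions: Dict[str, List[EventBlock]]
    fit: FitBlock = FitBlock()
    interference: InterferenceBlock = InterferenceBlock()
    n_per_condition: int = Field(default=5000, ge=1)
    seed: int = 0

    def make_grid(self) -> Grid:
        return make_grid(self.grid.lower, self.grid.upper, self.grid.n_cells)

    def _bin_scheme(self, grid: Grid, block: Optional[BinsBlock]) -> BinScheme:
        b = block or self.bins
        if b.edges is not None:
            return BinScheme(tuple(b.edges))
        return BinScheme.equal_width(grid, b.n_bins)

    def schedules(self) -> Dict[str, MeasurementSchedule]:
        grid = self.make_grid()
        out: Dict[str, MeasurementSchedule] = {}
        for cid, events in self.conditions.items():
            evs = []
            for e in events:
                if e.evolve is not None:
                    evs.append(EvolveEvent(e.evolve))
                else:
                    evs.append(MeasureEvent(e.measure, self._bin_scheme(grid, e.bins)))
            out[cid] = MeasurementSchedule(tuple(evs))
        return out

    def model_spec(self, kind: Optional[str] = None) -> RatingModelSpec:
        return RatingModelSpec(
            kind=kind or self.model.kind,
            grid=self.make_grid(),
            conditions=self.schedules(),
            initial=self.initial.model_dump(exclude_none=True),
            bounds={"mu": self.fit.mu_bounds, "sigma": self.fit.sigma_bounds},
        )

    def simulation_spec(self) -> SimulationSpec:
        return SimulationSpec(
            generator=self.model_spec(),
            n_per_context=self.n_per_condition,
            seed=self.seed,
            params={"mu": self.model.mu, "sigma": self.model.sigma},
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML/JSON config; raise ConfigError on violation."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    try:
        raw = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{p}: cannot parse: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{p}: invalid configuration:\n" + "\n".join(lines)) from exc
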