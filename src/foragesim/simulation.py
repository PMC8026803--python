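"""Strategy execution against a ground-truth dataset and the Monte-Carlo
heuristic-versus-random comparison.

Executing a strategy mimics the task interface: at each step the requested
number of that location's stocked replicates is revealed uniformly at
random without replacement (a replicate is never shown twice), and the
cumulative effective coverage and hypothesis fitting error are recorded
after every step.  Repeating a strategy many times and collecting the
final fitting errors gives the error distribution compared against the
dataset's representative fitting error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .hypothesis_fit import (
    CoverageSpec,
    InsufficientDataError,
    effective_coverage,
    fit_piecewise,
    representative_fitting_error,
)
from .strategies import SamplingStrategy, evenly_spaced_strategy, random_strategy
from .synthetic_data import GroundTruthDataset, InvalidParameterError

__all__ = [
    "LogStep",
    "CumulativePoint",
    "ObservationLog",
    "StrategySpec",
    "ErrorDistribution",
    "parse_strategy_spec",
    "execute_strategy",
    "fitting_trajectory",
    "strategy_error_distribution",
]


@dataclass(frozen=True)
class LogStep:
    location: int
    phase: str
    replicate_indices: tuple[int, ...]
    moisture: tuple[float, ...]
    strength: tuple[float, ...]


@dataclass(frozen=True)
class CumulativePoint:
    n_observations: int
    coverage: float
    rmse: float        # NaN until a fit is defined (>= 3 obs, >= 2 moistures)


@dataclass(frozen=True)
class ObservationLog:
    """What one execution of a strategy actually revealed, step by step."""

    steps: tuple[LogStep, ...]
    cumulative: tuple[CumulativePoint, ...]

    def observed_points(self, upto: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """All (moisture, strength) pairs revealed through step ``upto``."""
        steps = self.steps if upto is None else self.steps[:upto]
        m = [v for s in steps for v in s.moisture]
        y = [v for s in steps for v in s.strength]
        return np.asarray(m), np.asarray(y)

    @property
    def n_observations(self) -> int:
        return sum(len(s.moisture) for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory table: step,location,n_drawn,cum_n,coverage,rmse."""
        rows = []
        for i, (s, c) in enumerate(zip(self.steps, self.cumulative), start=1):
            rows.append((i, s.location, len(s.moisture), c.n_observations,
                         c.coverage, c.rmse))
        return pd.DataFrame(
            rows, columns=["step", "location", "n_drawn", "cum_n", "coverage", "rmse"]
        )


def _cumulative_fit_error(m: np.ndarray, y: np.ndarray, **fit_kwargs) -> float:
    if m.size < 3 or np.unique(m).size < 2:
        return float("nan")
    return fit_piecewise(m, y, **fit_kwargs).rmse


def execute_strategy(
    dataset: GroundTruthDataset,
    strategy: SamplingStrategy,
    seed,
    coverage_spec: CoverageSpec = CoverageSpec(),
    track_cumulative: bool = True,
    **fit_kwargs,
) -> ObservationLog:
    """Execute a strategy on a dataset, drawing replicates without replacement.

    Each step draws the requested number of the location's remaining
    replicates uniformly at random; a request exceeding what remains is
    capped with a warning and draws whatever is left.  With
    ``track_cumulative`` the coverage and fitting error are recomputed from
    scratch after every step (fitting error is NaN until at least three
    observations with two distinct moisture values exist).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_loc = {
        int(loc): df for loc, df in dataset.records.groupby("location_index")
    }
    remaining: dict[int, list[int]] = {}
    steps: list[LogStep] = []
    cumulative: list[CumulativePoint] = []
    all_m: list[float] = []
    all_y: list[float] = []
    for st in strategy.steps:
        loc_df = per_loc.get(st.location)
        if loc_df is None:
            raise InvalidParameterError(f"location {st.location} absent from dataset")
        if st.location not in remaining:
            remaining[st.location] = list(loc_df["replicate_index"])
        pool = remaining[st.location]
        n_draw = st.n
        if n_draw > len(pool):
            warnings.warn(
                f"step requests {st.n} replicates at location {st.location} "
                f"but only {len(pool)} remain; drawing {len(pool)}",
                stacklevel=2,
            )
            n_draw = len(pool)
        if n_draw == 0:
            drawn: list[int] = []
        else:
            drawn = [pool[i] for i in rng.choice(len(pool), size=n_draw, replace=False)]
        remaining[st.location] = [r for r in pool if r not in drawn]
        sub = loc_df.set_index("replicate_index").loc[drawn]
        m = tuple(float(v) for v in sub["moisture"])
        y = tuple(float(v) for v in sub["strength"])
        steps.append(LogStep(st.location, st.phase, tuple(drawn), m, y))
        all_m.extend(m)
        all_y.extend(y)
        if track_cumulative:
            am, ay = np.asarray(all_m), np.asarray(all_y)
            cumulative.append(
                CumulativePoint(
                    n_observations=len(all_m),
                    coverage=effective_coverage(am, dataset, coverage_spec),
                    rmse=_cumulative_fit_error(am, ay, **fit_kwargs),
                )
            )
    return ObservationLog(tuple(steps), tuple(cumulative))


def fitting_trajectory(
    log: ObservationLog, dataset: GroundTruthDataset
) -> list[tuple[float, float]]:
    """(effective coverage, fitting error) after each step with a defined fit.

    The final point's error equals the error of fitting all observed data;
    when the log exhausts the dataset it equals the representative fitting
    error by construction.
    """
    if not log.cumulative:
        raise InvalidParameterError(
            "log has no cumulative metrics; execute with track_cumulative=True"
        )
    return [
        (c.coverage, c.rmse) for c in log.cumulative if not np.isnan(c.rmse)
    ]


# ---------------------------------------------------------------------------
# Monte-Carlo strategy comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategySpec:
    """Parametric description of a strategy family, e.g. even:8x3."""

    kind: str            # "even" or "random"
    n_locations: int
    magic_number: int

    def __post_init__(self) -> None:
        if self.kind not in ("even", "random"):
            raise InvalidParameterError("kind must be 'even' or 'random'")

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.n_locations}x{self.magic_number}"

    def make(self, grid, rng) -> SamplingStrategy:
        if self.kind == "even":
            return evenly_spaced_strategy(grid, self.n_locations, self.magic_number)
        return random_strategy(grid, self.n_locations, self.magic_number, rng)


def parse_strategy_spec(text: str) -> StrategySpec:
    """Parse labels like ``even:8x3`` or ``random:11x3``."""
    try:
        kind, rest = text.split(":")
        n_loc, magic = rest.lower().split("x")
        return StrategySpec(kind, int(n_loc), int(magic))
    except (ValueError, TypeError) as exc:
        raise InvalidParameterError(
            f"cannot parse strategy spec {text!r}; expected e.g. 'even:8x3'"
        ) from exc


@dataclass(frozen=True)
class ErrorDistribution:
    strategy_label: str
    hypothesis_id: str
    final_errors: np.ndarray
    representative_error: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.final_errors) + 1),
                "final_rmse": self.final_errors,
            }
        )

    def sidecar(self) -> dict:
        return {
            "strategy": self.strategy_label,
            "hypothesis": self.hypothesis_id,
            "n_iterations": int(len(self.final_errors)),
            "representative_error": self.representative_error,
        }


def strategy_error_distribution(
    spec: StrategySpec | str | Callable[[np.random.Generator], SamplingStrategy],
    dataset: GroundTruthDataset,
    n_iter: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> ErrorDistribution:
    """Final-fitting-error distribution of a strategy family over ``n_iter``
    executions.

    Heuristic (``even``) strategies keep their locations fixed across
    iterations — only the replicate draws vary; ``random`` strategies
    redraw their locations each iteration before fresh replicate draws.  A
    callable spec receives a per-iteration generator and returns the
    strategy to execute.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    if isinstance(spec, str):
        spec = parse_strategy_spec(spec)
    label = spec.label if isinstance(spec, StrategySpec) else getattr(
        spec, "__name__", "custom"
    )
    finals = np.empty(n_iter)
    for it in range(n_iter):
        ss = np.random.SeedSequence([int(seed), it])
        strat_rng, exec_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        if isinstance(spec, StrategySpec):
            strategy = spec.make(dataset.grid, strat_rng)
        else:
            strategy = spec(strat_rng)
        log = execute_strategy(
            dataset, strategy, exec_rng, track_cumulative=False, **fit_kwargs
        )
        m, y = log.observed_points()
        finals[it] = fit_piecewise(m, y, **fit_kwargs).rmse
    return ErrorDistribution(
        strategy_label=label,
        hypothesis_id=dataset.hypothesis_id,
        final_errors=finals,
        representative_error=representative_fitting_error(dataset, **fit_kwargs),
    )
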