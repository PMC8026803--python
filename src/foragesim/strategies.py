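"""Sampling strategies and the two field-sampling heuristics.

A strategy is an ordered plan of (location, measurement-count) steps,
tagged by phase: the ``initial`` plan reported before seeing any data,
plus any ``added`` mid-run or post-plan amendments.  Two heuristics
observed in field scientists are classified here:

* *equal spacing* — locations at (near-)uniform intervals, measured by
  the average interval discrepancy (0 = perfectly uniform; strategies at
  or under a threshold of one grid step count as equal-spacing),
* *magic number* — one fixed measurement count at every location.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import InvalidParameterError, TransectGrid

__all__ = [
    "StrategyStep",
    "SamplingStrategy",
    "StrategyClassification",
    "DegenerateStrategyError",
    "evenly_spaced_strategy",
    "random_strategy",
    "average_interval_discrepancy",
    "detect_magic_number",
    "classify_strategy",
]

PHASES = ("initial", "added")

#: per-location replicate cap in the bounded task
DEFAULT_MEASUREMENT_CAP = 10


class DegenerateStrategyError(ValueError):
    """Strategy too small for the requested statistic (< 2 locations)."""


@dataclass(frozen=True)
class StrategyStep:
    location: int      # 1-based location index on the grid
    n: int             # measurements requested at this step
    phase: str = "initial"

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidParameterError(f"phase must be one of {PHASES}")


@dataclass(frozen=True)
class SamplingStrategy:
    """Ordered plan of sampling steps on a transect grid."""

    grid: TransectGrid
    steps: tuple[StrategyStep, ...]
    measurement_cap: int = DEFAULT_MEASUREMENT_CAP

    def __post_init__(self) -> None:
        steps = tuple(
            s if isinstance(s, StrategyStep) else StrategyStep(*s) for s in self.steps
        )
        if not steps:
            raise InvalidParameterError("strategy must contain at least one step")
        for s in steps:
            if not 1 <= s.location <= self.grid.n_locations:
                raise InvalidParameterError(
                    f"step location {s.location} outside grid 1..{self.grid.n_locations}"
                )
            if not 1 <= s.n <= self.measurement_cap:
                raise InvalidParameterError(
                    f"step count {s.n} outside 1..{self.measurement_cap}"
                )
        object.__setattr__(self, "steps", steps)

    # -- views --------------------------------------------------------------

    @property
    def initial_steps(self) -> tuple[StrategyStep, ...]:
        return tuple(s for s in self.steps if s.phase == "initial")

    @property
    def added_steps(self) -> tuple[StrategyStep, ...]:
        return tuple(s for s in self.steps if s.phase == "added")

    def initial_locations(self) -> tuple[int, ...]:
        """Distinct initial-plan locations, ascending."""
        return tuple(sorted({s.location for s in self.initial_steps}))

    @property
    def total_measurements(self) -> int:
        return sum(s.n for s in self.steps)

    def with_step(self, location: int, n: int, phase: str = "added",
                  at: int | None = None) -> "SamplingStrategy":
        """Copy with one step inserted at position ``at`` (default: appended)."""
        steps = list(self.steps)
        pos = len(steps) if at is None else at
        steps.insert(pos, StrategyStep(location, n, phase))
        return SamplingStrategy(self.grid, tuple(steps), self.measurement_cap)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid_size": self.grid.n_locations,
                "steps": [
                    {"location": s.location, "n": s.n, "phase": s.phase}
                    for s in self.steps
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SamplingStrategy":
        obj = json.loads(text)
        grid = TransectGrid.regular(int(obj["grid_size"]))
        steps = tuple(
            StrategyStep(int(s["location"]), int(s["n"]), s.get("phase", "initial"))
            for s in obj["steps"]
        )
        return cls(grid, steps)

    def to_frame(self) -> pd.DataFrame:
        """CSV-friendly table with columns order,location,n,phase."""
        return pd.DataFrame(
            {
                "order": range(1, len(self.steps) + 1),
                "location": [s.location for s in self.steps],
                "n": [s.n for s in self.steps],
                "phase": [s.phase for s in self.steps],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: TransectGrid) -> "SamplingStrategy":
        df = df.sort_values("order")
        steps = tuple(
            StrategyStep(int(r.location), int(r.n), str(r.phase))
            for r in df.itertuples()
        )
        return cls(grid, steps)


@dataclass(frozen=True)
class StrategyClassification:
    avg_interval_discrepancy: float
    is_equal_spacing: bool
    magic_number: Optional[int]
    n_locations: int
    total_measurements: int


# ---------------------------------------------------------------------------
# strategy constructors
# ---------------------------------------------------------------------------

def _spread_indices(n_grid: int, n_locations: int) -> np.ndarray:
    """0-based grid indices spreading n_locations uniformly over 0..n_grid-1.

    Real-valued equispaced coordinates are rounded half-up to the nearest
    grid index; collisions are resolved by shifting outward from the
    center, which is deterministic and order-independent.
    """
    target = np.linspace(0, n_grid - 1, n_locations)
    idx = np.floor(target + 0.5).astype(int)
    mid = n_locations // 2
    for i in range(mid + 1, n_locations):          # push right of center
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    for i in range(mid - 1, -1, -1):               # push left of center
        if idx[i] >= idx[i + 1]:
            idx[i] = idx[i + 1] - 1
    if idx[0] < 0 or idx[-1] > n_grid - 1:
        raise InvalidParameterError("n_locations does not fit on the grid")
    return idx


def evenly_spaced_strategy(
    grid: TransectGrid, n_locations: int, magic_number: int,
    measurement_cap: int = DEFAULT_MEASUREMENT_CAP,
) -> SamplingStrategy:
    """Heuristic strategy: ``magic_number`` measurements at ``n_locations``
    locations spread as uniformly as the integer grid allows, visited in
    ascending spatial order."""
    if not 2 <= n_locations <= grid.n_locations:
        raise InvalidParameterError(
            f"n_locations must be in 2..{grid.n_locations}, got {n_locations}"
        )
    if magic_number < 1:
        raise InvalidParameterError("magic_number must be >= 1")
    idx = _spread_indices(grid.n_locations, n_locations)
    steps = tuple(StrategyStep(int(i) + 1, magic_number) for i in idx)
    return SamplingStrategy(grid, steps, measurement_cap)


def random_strategy(
    grid: TransectGrid, n_locations: int, magic_number: int, seed,
    measurement_cap: int = DEFAULT_MEASUREMENT_CAP,
) -> SamplingStrategy:
    """Control strategy: ``n_locations`` distinct locations drawn uniformly
    without replacement, visited in ascending order."""
    if not 2 <= n_locations <= grid.n_locations:
        raise InvalidParameterError(
            f"n_locations must be in 2..{grid.n_locations}, got {n_locations}"
        )
    if magic_number < 1:
        raise InvalidParameterError("magic_number must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locs = np.sort(rng.choice(grid.n_locations, size=n_locations, replace=False)) + 1
    steps = tuple(StrategyStep(int(l), magic_number) for l in locs)
    return SamplingStrategy(grid, steps, measurement_cap)


# ---------------------------------------------------------------------------
# heuristic classification
# ---------------------------------------------------------------------------

def average_interval_discrepancy(
    strategy: SamplingStrategy, method: str = "successive"
) -> float:
    """Spread statistic over the initial plan's between-location intervals.

    Intervals between consecutive distinct initial locations (in grid-step
    units) are sorted ascending; the default statistic is the mean of
    successive differences of that sorted list, which is zero exactly when
    all intervals are equal and equals (max-min)/(n_intervals-1) otherwise.
    ``method="pairwise"`` gives the mean absolute pairwise difference
    instead.  With fewer than two intervals the discrepancy is 0 by
    convention; fewer than two locations is an error.
    """
    locs = strategy.initial_locations()
    if len(locs) < 2:
        raise DegenerateStrategyError(
            "interval discrepancy requires >= 2 distinct initial locations"
        )
    positions = np.array([strategy.grid.position_of(l) for l in locs])
    intervals = np.sort(np.diff(positions))
    if len(intervals) < 2:
        return 0.0
    if method == "successive":
        return float(np.mean(np.diff(intervals)))
    if method == "pairwise":
        return float(np.mean([abs(a - b) for a, b in combinations(intervals, 2)]))
    raise InvalidParameterError(f"unknown discrepancy method {method!r}")


def detect_magic_number(strategy: SamplingStrategy) -> Optional[int]:
    """The common initial per-location count, or None if counts differ."""
    counts = {s.n for s in strategy.initial_steps}
    if not counts:
        raise InvalidParameterError("strategy has no initial-phase steps")
    return counts.pop() if len(counts) == 1 else None


def classify_strategy(
    strategy: SamplingStrategy, threshold: float = 1.0, method: str = "successive"
) -> StrategyClassification:
    """Classify a strategy by the equal-spacing and magic-number heuristics."""
    disc = average_interval_discrepancy(strategy, method=method)
    return StrategyClassification(
        avg_interval_discrepancy=disc,
        is_equal_spacing=bool(disc <= threshold),
        magic_number=detect_magic_number(strategy),
        n_locations=len(strategy.initial_locations()),
        total_measurements=strategy.total_measurements,
    )
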