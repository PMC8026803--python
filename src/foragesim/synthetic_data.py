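"""Seeded generation of the two ground-truth transect datasets.

The simulated task presents a dune transect with 22 labeled sampling
locations, each holding 10 replicate (moisture, strength) measurements.
Replicates are drawn from truncated normal distributions around a mean
soil-strength-versus-moisture curve; two curves encode the competing
hypotheses:

* ``given`` — soil shear strength increases with moisture until the sand
  saturates, after which strength is constant,
* ``alternative`` — strength rises, then decreases slightly past
  saturation before levelling off.

Strength noise uses sd 2 truncated at +/-2 about the mean; moisture noise
uses sd 0.5 truncated at +/-1.  All draws are reproducible from a single
master seed via per-location counter-based substreams.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransectGrid",
    "GradientModel",
    "NoiseModel",
    "GroundTruthDataset",
    "sample_truncated_normal",
    "build_gradient_model",
    "generate_dataset",
]

HYPOTHESES = ("given", "alternative")

#: number of replicate measurements stocked at each location
REPLICATES_PER_LOCATION = 10


class InvalidParameterError(ValueError):
    """A model, noise or grid parameter violates its constraints."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _default_positions() -> tuple[float, ...]:
    return tuple(float(i) for i in range(1, 23))


@dataclass(frozen=True)
class TransectGrid:
    """Labeled sampling sites along the dune transect.

    Positions are strictly increasing coordinates in grid-step units;
    the default is the integer grid 1..22 used in the bounded task.
    """

    n_locations: int = 22
    positions: tuple[float, ...] = field(default_factory=_default_positions)

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise InvalidParameterError("n_locations must be >= 1")
        pos = tuple(float(p) for p in self.positions)
        if len(pos) != self.n_locations:
            raise InvalidParameterError(
                f"positions has length {len(pos)}, expected n_locations={self.n_locations}"
            )
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InvalidParameterError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def regular(cls, n_locations: int) -> "TransectGrid":
        return cls(n_locations, tuple(float(i) for i in range(1, n_locations + 1)))

    def position_of(self, location_index: int) -> float:
        """Coordinate of a 1-based location index."""
        if not 1 <= location_index <= self.n_locations:
            raise InvalidParameterError(
                f"location_index {location_index} outside 1..{self.n_locations}"
            )
        return self.positions[location_index - 1]


@dataclass(frozen=True)
class GradientModel:
    """Mean moisture-vs-location and strength-vs-moisture curves for one hypothesis.

    Below the saturation moisture ``b_true`` mean strength rises as
    ``k_true * b_true * (m / b_true) ** rise_power`` — a concave
    strengthening curve whose average slope over the rise is ``k_true``
    (``rise_power=1`` gives the straight line ``k_true * m``).  The default
    exponent 0.25 concentrates the strengthening at low moisture, where
    grain-binding by pore water acts most strongly.  At and above ``b_true``
    strength sits at the stabilized level ``a_true``; the alternative
    hypothesis instead dips by ``dip_depth`` over ``dip_width`` % moisture
    past saturation before levelling off.  Moisture runs linearly from
    ``moisture_min`` at the dry crest (location 1) to ``moisture_max`` at
    the wet interdune (last location).
    """

    hypothesis_id: str = "given"
    k_true: float = 2.0          # mean rise slope, strength units per % moisture
    a_true: float = 10.0         # stabilized strength level
    b_true: float = 3.0          # saturation moisture, % water content
    rise_power: float = 0.25     # concavity of the pre-saturation rise
    dip_depth: float = 0.0       # post-saturation decrease (alternative only)
    dip_width: float = 1.5       # % moisture over which the dip develops
    moisture_min: float = 0.0    # mean moisture at the crest, %
    moisture_max: float = 6.0    # mean moisture at the interdune, %

    def __post_init__(self) -> None:
        if self.hypothesis_id not in HYPOTHESES:
            raise InvalidParameterError(
                f"hypothesis_id must be one of {HYPOTHESES}, got {self.hypothesis_id!r}"
            )
        if self.k_true < 0:
            raise InvalidParameterError("k_true must be >= 0")
        if self.a_true <= 0:
            raise InvalidParameterError("a_true must be > 0")
        if not self.moisture_min <= self.b_true <= self.moisture_max:
            raise InvalidParameterError(
                "b_true must lie inside the transect moisture range"
            )
        if self.moisture_max <= self.moisture_min:
            raise InvalidParameterError("moisture_max must exceed moisture_min")
        if self.rise_power <= 0:
            raise InvalidParameterError("rise_power must be > 0")
        if self.dip_depth < 0:
            raise InvalidParameterError("dip_depth must be >= 0")
        if self.hypothesis_id == "given" and self.dip_depth != 0:
            raise InvalidParameterError("given hypothesis has no dip (dip_depth must be 0)")
        if self.dip_width <= 0:
            raise InvalidParameterError("dip_width must be > 0")
        if self.a_true - self.dip_depth < 0:
            raise InvalidParameterError("dip_depth would produce negative strength")

    def moisture_of_location(self, grid: TransectGrid, location_index) -> np.ndarray:
        """Mean moisture (%) at 1-based location index(es): dry crest -> wet interdune."""
        idx = np.asarray(location_index)
        if np.any(idx < 1) or np.any(idx > grid.n_locations):
            raise InvalidParameterError("location_index outside grid")
        pos = np.asarray(grid.positions)[idx - 1]
        lo, hi = grid.positions[0], grid.positions[-1]
        frac = (pos - lo) / (hi - lo) if hi > lo else np.zeros_like(pos)
        return self.moisture_min + frac * (self.moisture_max - self.moisture_min)

    def mean_strength_of_moisture(self, moisture) -> np.ndarray:
        """Mean strength at the given moisture(s), per this hypothesis' curve."""
        m = np.asarray(moisture, dtype=float)
        scaled = np.clip(m / self.b_true, 0.0, None) if self.b_true > 0 else np.zeros_like(m)
        below = self.k_true * self.b_true * scaled**self.rise_power
        if self.dip_depth == 0.0:
            above = np.full_like(m, self.a_true)
        else:
            dip_frac = np.clip((m - self.b_true) / self.dip_width, 0.0, 1.0)
            above = self.a_true - self.dip_depth * dip_frac
        return np.where(m < self.b_true, below, above)


@dataclass(frozen=True)
class NoiseModel:
    """Truncated-normal measurement noise, as absolute offsets from the mean."""

    strength_sd: float = 2.0
    strength_bound: float = 2.0
    moisture_sd: float = 0.5
    moisture_bound: float = 1.0

    def __post_init__(self) -> None:
        for name in ("strength_sd", "strength_bound", "moisture_sd", "moisture_bound"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class GroundTruthDataset:
    """The full table of replicate (moisture, strength) measurements.

    ``records`` has one row per replicate with columns
    ``location_index`` (1-based), ``replicate_index`` (1-based),
    ``moisture`` and ``strength``.
    """

    hypothesis_id: str
    grid: TransectGrid
    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"location_index", "replicate_index", "moisture", "strength"}
        missing = required - set(self.records.columns)
        if missing:
            raise InvalidParameterError(f"records missing columns {sorted(missing)}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def moisture_range(self) -> tuple[float, float]:
        m = self.records["moisture"]
        return float(m.min()), float(m.max())

    def replicates_at(self, location_index: int) -> pd.DataFrame:
        return self.records[self.records["location_index"] == location_index]

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """All (moisture, strength) observations as two arrays."""
        return (
            self.records["moisture"].to_numpy(),
            self.records["strength"].to_numpy(),
        )

    # -- CSV round trip (12 significant digits) -----------------------------

    def to_csv(self, path_or_buf) -> None:
        df = self.records.copy()
        df.insert(0, "hypothesis", self.hypothesis_id)
        df.to_csv(path_or_buf, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path_or_buf, grid: TransectGrid | None = None) -> "GroundTruthDataset":
        df = pd.read_csv(path_or_buf)
        hyp = df["hypothesis"].iloc[0]
        if not (df["hypothesis"] == hyp).all():
            raise InvalidParameterError("dataset CSV mixes hypotheses")
        records = df.drop(columns=["hypothesis"]).reset_index(drop=True)
        if grid is None:
            grid = TransectGrid.regular(int(records["location_index"].max()))
        return cls(str(hyp), grid, records)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_truncated_normal(
    mean: float, sd: float, bound: float, n: int, seed
) -> np.ndarray:
    """Draw ``n`` values from Normal(mean, sd) truncated to ``mean +/- bound``.

    Sampling is by inversion of the truncated-normal CDF so the number of
    uniform variates consumed is exactly ``n`` — draw counts are
    deterministic per seed and never depend on rejection luck.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if sd <= 0:
        raise InvalidParameterError("sd must be > 0")
    if bound <= 0:
        raise InvalidParameterError("bound must be > 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = _as_rng(seed)
    alpha = -bound / sd
    lo_cdf, hi_cdf = stats.norm.cdf(alpha), stats.norm.cdf(-alpha)
    u = rng.uniform(lo_cdf, hi_cdf, size=int(n))
    z = stats.norm.ppf(u)
    # inversion can graze the bound through floating error; clip to the contract
    return mean + sd * np.clip(z, alpha, -alpha)


def build_gradient_model(hypothesis_id: str, **params) -> GradientModel:
    """Construct and validate the mean-curve model for one hypothesis.

    For ``alternative`` a positive ``dip_depth`` default is applied unless
    explicitly overridden (``dip_depth=0`` reduces it to the given curve).
    """
    if hypothesis_id == "alternative" and "dip_depth" not in params:
        params["dip_depth"] = 1.0
    return GradientModel(hypothesis_id=hypothesis_id, **params)


def _location_rng(seed: int, location_index: int, stream: int) -> np.random.Generator:
    # counter-based substream: adding locations never reshuffles earlier draws
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(location_index), int(stream)])
    )


def generate_dataset(
    model: GradientModel,
    noise: NoiseModel | None = None,
    grid: TransectGrid | None = None,
    seed: int = 0,
    n_replicates: int = REPLICATES_PER_LOCATION,
    couple_strength_to_noisy_moisture: bool = True,
) -> GroundTruthDataset:
    """Generate the replicate table for one hypothesis, fully seeded.

    At each location, ``n_replicates`` moisture values are drawn about the
    location's mean moisture and strength values about the mean curve.  By
    default each replicate's strength is centered on the curve evaluated
    at that replicate's own noisy moisture draw, so the scatter in
    (moisture, strength) space follows the hypothesis curve — the space in
    which the data are displayed and fit.  Set
    ``couple_strength_to_noisy_moisture=False`` to center strength on the
    curve at the location's *mean* moisture instead (fully independent
    noise channels).
    """
    noise = noise or NoiseModel()
    grid = grid or TransectGrid()
    if int(seed) < 0:
        raise InvalidParameterError("seed must be a nonnegative integer")
    rows = []
    for loc in range(1, grid.n_locations + 1):
        mean_m = float(model.moisture_of_location(grid, loc))
        moisture = sample_truncated_normal(
            mean_m, noise.moisture_sd, noise.moisture_bound, n_replicates,
            _location_rng(seed, loc, 0),
        )
        if couple_strength_to_noisy_moisture:
            centers = model.mean_strength_of_moisture(moisture)
            offsets = sample_truncated_normal(
                0.0, noise.strength_sd, noise.strength_bound, n_replicates,
                _location_rng(seed, loc, 1),
            )
            strength = centers + offsets
        else:
            mean_s = float(model.mean_strength_of_moisture(mean_m))
            strength = sample_truncated_normal(
                mean_s, noise.strength_sd, noise.strength_bound, n_replicates,
                _location_rng(seed, loc, 1),
            )
        for rep in range(1, n_replicates + 1):
            rows.append((loc, rep, moisture[rep - 1], strength[rep - 1]))
    records = pd.DataFrame(
        rows, columns=["location_index", "replicate_index", "moisture", "strength"]
    )
    return GroundTruthDataset(model.hypothesis_id, grid, records)
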