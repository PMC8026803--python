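"""Piecewise-linear hypothesis fitting and the two convergence metrics.

The given hypothesis relates soil erodibility (here, shear strength ``y``)
to moisture ``x`` through a piecewise linear model

    y = k*x   for x < b        (pre-saturation rise through the origin)
    y = a     for x >= b       (stabilized level past saturation moisture b)

fit by grid search over the breakpoint ``b``: for each candidate, ``k`` is
the least-squares through-origin slope on points below ``b`` and ``a`` the
mean strength at or above it; the fit minimizing the root-mean-squared
error (RMSE) over all points wins.  Continuity a = k*b is not imposed by
the model and therefore not enforced by the default fit (a ``continuous``
variant is available).

Two summary metrics describe how informative a sample is:

* *representative fitting error* — the RMSE when every available
  measurement is used; the convergence reference for any partial sample,
* *effective coverage* — the fraction of equal-width moisture bins of the
  full dataset's range that contain at least one sampled observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic_data import GroundTruthDataset, InvalidParameterError

__all__ = [
    "PiecewiseLinearFit",
    "CoverageSpec",
    "InsufficientDataError",
    "piecewise_predict",
    "fit_piecewise",
    "fitting_error",
    "representative_fitting_error",
    "effective_coverage",
]

#: default number of equally spaced breakpoint candidates across the
#: observed moisture range
DEFAULT_BREAKPOINT_CANDIDATES = 200


class InsufficientDataError(ValueError):
    """Too few points, or no moisture spread, to fit the model."""


@dataclass(frozen=True)
class PiecewiseLinearFit:
    k: float        # pre-saturation slope, strength per % moisture
    a: float        # stabilized strength level
    b: float        # saturation moisture, %
    rmse: float     # root-mean-squared fitting error, strength units
    n_points: int

    def predict(self, x) -> np.ndarray:
        return piecewise_predict(self.k, self.a, self.b, x)

    def to_dict(self) -> dict:
        """JSON-ready fit report."""
        return {"k": self.k, "a": self.a, "b": self.b,
                "rmse": self.rmse, "n_points": self.n_points}


@dataclass(frozen=True)
class CoverageSpec:
    """Binning convention for effective coverage of the moisture range."""

    n_intervals: int = 10
    range_source: str = "full_dataset"   # or "fixed"
    fixed_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_intervals < 2:
            raise InvalidParameterError("n_intervals must be >= 2")
        if self.range_source not in ("full_dataset", "fixed"):
            raise InvalidParameterError("range_source must be 'full_dataset' or 'fixed'")
        if self.range_source == "fixed" and self.fixed_range is None:
            raise InvalidParameterError("fixed range_source requires fixed_range")


def piecewise_predict(k: float, a: float, b: float, x) -> np.ndarray:
    """Evaluate y = {k*x for x < b; a for x >= b}."""
    x = np.asarray(x, dtype=float)
    return np.where(x < b, k * x, a)


def _candidate_breakpoints(
    x: np.ndarray, n_candidates: int, candidates: str
) -> np.ndarray:
    if candidates == "grid":
        return np.linspace(x.min(), x.max(), n_candidates)
    if candidates == "observed":
        return np.unique(x)
    raise InvalidParameterError("candidates must be 'grid' or 'observed'")


def fit_piecewise(
    x,
    y,
    n_candidates: int = DEFAULT_BREAKPOINT_CANDIDATES,
    candidates: str = "grid",
    continuous: bool = False,
) -> PiecewiseLinearFit:
    """Grid-search fit of the piecewise saturation model.

    Parameters
    ----------
    x, y
        Moisture and strength observations (equal length, >= 3 points with
        >= 2 distinct moisture values).
    n_candidates
        Number of equally spaced breakpoint candidates spanning the
        observed moisture range (``candidates="grid"``).
    candidates
        ``"grid"`` for the equally spaced candidate set, ``"observed"`` to
        restrict candidates to sampled moisture values.
    continuous
        Enforce a = k*b (a continuous curve at the breakpoint); the default
        fits the two branches independently.

    Notes
    -----
    Degenerate candidate splits stay in the search: an empty pre-saturation
    branch fixes k = 0, an empty post-saturation branch fixes a at the
    global mean strength.  Ties in RMSE resolve to the smallest breakpoint.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidParameterError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need >= 3 points to fit")
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 distinct moisture values")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # prefix sums: S*[i] = sum over the first i sorted points
    zeros = np.zeros(1)
    Sx2 = np.concatenate([zeros, np.cumsum(xs * xs)])
    Sxy = np.concatenate([zeros, np.cumsum(xs * ys)])
    Sy = np.concatenate([zeros, np.cumsum(ys)])
    Sy2 = np.concatenate([zeros, np.cumsum(ys * ys)])

    bs = _candidate_breakpoints(xs, n_candidates, candidates)
    # i = number of points strictly below each candidate b
    i = np.searchsorted(xs, bs, side="left")
    n_above = n - i

    sx2, sxy = Sx2[i], Sxy[i]
    sy_ab = Sy[n] - Sy[i]
    sy2_ab = Sy2[n] - Sy2[i]

    with np.errstate(divide="ignore", invalid="ignore"):
        if continuous:
            denom = sx2 + n_above * bs * bs
            k = np.where(denom > 0, (sxy + bs * sy_ab) / np.where(denom > 0, denom, 1.0), 0.0)
            a = k * bs
        else:
            k = np.where(sx2 > 0, sxy / np.where(sx2 > 0, sx2, 1.0), 0.0)
            mean_all = Sy[n] / n
            a = np.where(n_above > 0, sy_ab / np.where(n_above > 0, n_above, 1.0), mean_all)
    sse_below = Sy2[i] - 2 * k * sxy + k * k * sx2
    sse_above = sy2_ab - 2 * a * sy_ab + n_above * a * a
    rmse = np.sqrt(np.maximum(sse_below + sse_above, 0.0) / n)

    best = int(np.argmin(rmse))   # ties -> smallest candidate b
    return PiecewiseLinearFit(
        k=float(k[best]), a=float(a[best]), b=float(bs[best]),
        rmse=float(rmse[best]), n_points=n,
    )


def fitting_error(x, y, fit: PiecewiseLinearFit) -> float:
    """RMSE of observations against a fixed piecewise model."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientDataError("no points to evaluate")
    resid = y - piecewise_predict(fit.k, fit.a, fit.b, x)
    return float(np.sqrt(np.mean(resid * resid)))


def representative_fitting_error(
    dataset: GroundTruthDataset, **fit_kwargs
) -> float:
    """RMSE of the best piecewise fit using *all* available measurements.

    This is the convergence reference any partial sampling strategy is
    judged against.  A dataset with fewer records than its grid stocks
    (n_locations x 10) is still fit, with a warning.
    """
    expected = dataset.grid.n_locations * 10
    if dataset.n_records < expected:
        warnings.warn(
            f"dataset has {dataset.n_records} of {expected} records; "
            "representative error computed on available records",
            stacklevel=2,
        )
    x, y = dataset.points()
    return fit_piecewise(x, y, **fit_kwargs).rmse


def effective_coverage(
    observed_moisture,
    dataset: GroundTruthDataset | None = None,
    spec: CoverageSpec = CoverageSpec(),
) -> float:
    """Fraction of moisture-range bins containing >= 1 observation.

    The full dataset (or ``spec.fixed_range``) defines the binning range,
    partitioned into ``spec.n_intervals`` equal-width bins; observations
    outside the range are ignored, and the maximum of the range falls in
    the last bin.
    """
    if spec.range_source == "fixed":
        lo, hi = spec.fixed_range  # type: ignore[misc]
    else:
        if dataset is None:
            raise InvalidParameterError("full_dataset coverage requires a dataset")
        lo, hi = dataset.moisture_range()
    m = np.asarray(observed_moisture, dtype=float).ravel()
    if m.size == 0:
        return 0.0
    if hi <= lo:
        raise InvalidParameterError("degenerate moisture range")
    width = (hi - lo) / spec.n_intervals
    inside = m[(m >= lo) & (m <= hi)]
    idx = np.minimum(((inside - lo) / width).astype(int), spec.n_intervals - 1)
    return float(np.unique(idx).size / spec.n_intervals)
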