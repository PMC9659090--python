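"""Orthogonality metrics between two separation dimensions.

Two metrics are implemented, both based on how much of the normalized
2D separation space the identified peptides occupy:

* **Surface-coverage (bin-counting) method.** The unit square is divided
  into a side x side grid with side = ceil(sqrt(N)); the orthogonality
  factor is ``(occupied - side) / (0.63 * side**2)``. The ``side`` term
  subtracts the bins a perfectly correlated (diagonal) dataset would
  occupy, and 0.63 is the surface coverage regarded as optimal for a
  fully orthogonal pair of separations, so the factor is 0 for a
  perfectly correlated system and ~1 for an ideally orthogonal one.

* **Regression-deviation method.** y is regressed on x (no
  normalization); the extreme residuals — after discarding the most
  extreme 5%, split between tails — are expressed as a percentage of
  the observed y-range. The occupied band (positive bound plus the
  magnitude of the negative bound) over 100 is the factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Surface coverage considered optimal for an orthogonal system; full
#: coverage is unattainable in practice, so 63% plays the role of 100%.
OPTIMAL_COVERAGE = 0.63


@dataclass(frozen=True)
class TimePairSet:
    """Paired coordinates of the same analytes in two separation dimensions."""

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise ValueError(f"need at least 3 pairs, got {self.x.size}")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("missing values are not allowed in a TimePairSet")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class BinGridResult:
    side: int
    total_bins: int
    occupied: int
    coverage_pct: float
    factor: float


@dataclass(frozen=True)
class RegressionDeviationResult:
    slope: float | None
    intercept: float | None
    dev_neg_pct: float
    dev_pos_pct: float
    occupied_pct: float
    factor: float


def normalize_minmax(pairs: TimePairSet) -> TimePairSet:
    """Min-max normalize each axis onto [0, 1]; order-preserving."""
    out = []
    for axis, label in ((pairs.x, pairs.x_label), (pairs.y, pairs.y_label)):
        rng = axis.max() - axis.min()
        if rng <= 0:
            raise ValueError(f"axis {label!r} has zero range; cannot normalize")
        out.append((axis - axis.min()) / rng)
    return TimePairSet(out[0], out[1], pairs.x_label, pairs.y_label)


def grid_side(n: int) -> int:
    """Bins per axis: ceil(sqrt(N)) so total bins ~ number of points."""
    return math.ceil(math.sqrt(n))


def factor_from_counts(occupied: int, side: int) -> float:
    """Surface-coverage orthogonality factor from a bin-count summary."""
    return (occupied - side) / (OPTIMAL_COVERAGE * side * side)


def bin_occupancy(pairs: TimePairSet, side: int | None = None) -> np.ndarray:
    """side x side occupancy count matrix over normalized pairs.

    Bins are half-open on [0, 1) with the last bin closed at 1, so the
    maximum-coordinate point is counted exactly once.
    """
    if side is None:
        side = grid_side(pairs.n)
    ix = np.minimum((pairs.x * side).astype(int), side - 1)
    iy = np.minimum((pairs.y * side).astype(int), side - 1)
    grid = np.zeros((side, side), dtype=int)
    np.add.at(grid, (ix, iy), 1)
    return grid


def surface_coverage_orthogonality(pairs: TimePairSet) -> BinGridResult:
    """Bin-counting orthogonality over min-max normalized pairs."""
    norm = normalize_minmax(pairs)
    side = grid_side(norm.n)
    grid = bin_occupancy(norm, side)
    occupied = int((grid > 0).sum())
    return BinGridResult(
        side=side,
        total_bins=side * side,
        occupied=occupied,
        coverage_pct=100.0 * occupied / (side * side),
        factor=factor_from_counts(occupied, side),
    )


def expected_occupied_uniform(n: int, total_bins: int) -> float:
    """Expected occupied bins when n points fall i.i.d. uniformly.

    Each of B bins is empty with probability (1 - 1/B)^n, so the
    expectation is B * (1 - (1 - 1/B)^n) — the calibration reference for
    the surface-coverage method.
    """
    return total_bins * (1.0 - (1.0 - 1.0 / total_bins) ** n)


def factor_from_deviation_bounds(
    dev_neg_pct: float,
    dev_pos_pct: float,
    slope: float | None = None,
    intercept: float | None = None,
) -> RegressionDeviationResult:
    """Regression-method result from already-measured deviation bounds."""
    if dev_neg_pct > 0 or dev_pos_pct < 0:
        raise ValueError("expected dev_neg_pct <= 0 <= dev_pos_pct")
    occupied = dev_pos_pct + abs(dev_neg_pct)
    return RegressionDeviationResult(
        slope=slope,
        intercept=intercept,
        dev_neg_pct=dev_neg_pct,
        dev_pos_pct=dev_pos_pct,
        occupied_pct=occupied,
        factor=occupied / 100.0,
    )


def regression_deviation_orthogonality(
    pairs: TimePairSet, trim: float = 0.95
) -> RegressionDeviationResult:
    """Regression-deviation orthogonality on raw (unnormalized) pairs.

    The OLS fit uses all points; residuals are expressed as a percentage
    of the observed y-range, and the most extreme ``1 - trim`` fraction
    (split equally between tails) is discarded before taking the
    surviving extremes as the deviation bounds.
    """
    if not 0.0 < trim <= 1.0:
        raise ValueError(f"trim must be in (0, 1], got {trim}")
    if np.ptp(pairs.x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(pairs.x, pairs.y)
    y_range = np.ptp(pairs.y)
    if y_range == 0:
        resid_pct = np.zeros(pairs.n)
    else:
        resid = pairs.y - (fit.intercept + fit.slope * pairs.x)
        resid_pct = 100.0 * resid / y_range
    k = int(math.floor(pairs.n * (1.0 - trim) / 2.0))
    surviving = np.sort(resid_pct)
    if k > 0:
        surviving = surviving[k:-k]
    dev_neg = min(float(surviving[0]), 0.0)
    dev_pos = max(float(surviving[-1]), 0.0)
    return factor_from_deviation_bounds(
        dev_neg, dev_pos, slope=float(fit.slope), intercept=float(fit.intercept)
    )
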