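"""Peak capacity of a one-dimensional separation from an integrated peak list.

Peak capacity = 1 + (MT_L - MT_F) / (mean W4sigma), where MT_F and MT_L
are the apex times of the first and last peptide of the window and
W4sigma is the peak width at 13.4% of maximum height (4 standard
deviations for a Gaussian peak). Widths measured as FWHM are converted
with the Gaussian ratio 4 / (2 * sqrt(2 ln 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Gaussian 4-sigma width over FWHM: 4 / (2 sqrt(2 ln 2)) ~ 1.69864.
W4SIGMA_PER_FWHM = 4.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak: apex time and FWHM, both in minutes."""

    apex: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")

    @property
    def w4sigma(self) -> float:
        return fwhm_to_w4sigma(self.fwhm)


@dataclass(frozen=True)
class PeakCapacityResult:
    mt_first: float
    mt_last: float
    n: int
    mean_w4sigma: float
    capacity: float


def fwhm_to_w4sigma(fwhm: float) -> float:
    """Width at 13.4% of maximum height under the Gaussian peak model."""
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    return fwhm * W4SIGMA_PER_FWHM


def peak_capacity(peaks: Sequence[PeakRecord]) -> PeakCapacityResult:
    """Peak capacity of the window spanned by the given peaks (>= 2)."""
    if len(peaks) < 2:
        raise ValueError(f"need at least 2 peaks, got {len(peaks)}")
    apexes = [p.apex for p in peaks]
    mean_w = sum(p.w4sigma for p in peaks) / len(peaks)
    first, last = min(apexes), max(apexes)
    return PeakCapacityResult(
        mt_first=first,
        mt_last=last,
        n=len(peaks),
        mean_w4sigma=mean_w,
        capacity=1.0 + (last - first) / mean_w,
    )


def migration_window(times: Iterable[float]) -> tuple[float, float, float]:
    """(first, last, span) of migration times; requires >= 1 value."""
    times = list(times)
    if not times:
        raise ValueError("no migration times given")
    first, last = min(times), max(times)
    return first, last, last - first
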