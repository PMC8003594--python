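"""Tumor volume and exponential doubling-time estimation from caliper data.

Volume follows the standard two-diameter ellipsoid approximation
``V = L × S² / 2`` (mm³, L the largest and S the smallest perpendicular
diameter in mm). Growth is modelled as exponential, ``N(t) = N0 · exp(a t)``,
fitted per animal by ordinary least squares on log-volume; the doubling time
is ``DT = ln2 / a`` (days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "GrowthRecord",
    "GrowthFit",
    "tumor_volume",
    "fit_exponential_growth",
    "summarize_groups",
]


def tumor_volume(largest_mm: float, smallest_mm: float) -> float:
    """Caliper tumor volume L × S² / 2 in mm³.

    Requires L >= S > 0 (the two-diameter convention).
    """
    if not smallest_mm > 0:
        raise ValidationError(f"smallest diameter must be > 0, got {smallest_mm}")
    if largest_mm < smallest_mm:
        raise ValidationError(
            f"largest diameter {largest_mm} < smallest {smallest_mm}: convention violated"
        )
    return largest_mm * smallest_mm**2 / 2.0


@dataclass(frozen=True)
class GrowthRecord:
    """Caliper observations for one animal.

    Diameters of zero mark not-yet-palpable tumors; such observations are
    excluded from the fit (log-volume undefined) and counted.
    """

    animal: str
    days: np.ndarray
    largest_mm: np.ndarray
    smallest_mm: np.ndarray
    group: str = "control"

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        L = np.asarray(self.largest_mm, dtype=float)
        S = np.asarray(self.smallest_mm, dtype=float)
        if not (len(days) == len(L) == len(S)):
            raise ValidationError("days, largest_mm and smallest_mm must have equal length")
        if np.any(np.diff(days) <= 0):
            raise ValidationError("days must be strictly increasing per animal")
        if np.any(L < S) or np.any(S < 0):
            raise ValidationError("need L >= S >= 0 for every observation")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "largest_mm", L)
        object.__setattr__(self, "smallest_mm", S)

    def volumes(self) -> np.ndarray:
        """Volumes in mm³; zero where the tumor was not yet palpable."""
        return np.where(self.smallest_mm > 0, self.largest_mm * self.smallest_mm**2 / 2.0, 0.0)


@dataclass(frozen=True)
class GrowthFit:
    """Per-animal exponential growth fit; DT·a = ln2 by construction."""

    animal: str
    group: str
    n0_mm3: float
    a_per_day: float
    doubling_time_days: float
    r_squared: float
    n_excluded: int = 0
    shrinking: bool = False


def fit_exponential_growth(record: GrowthRecord) -> GrowthFit:
    """Log-linear least squares of ln(volume) on day for one animal.

    Observations with zero volume are excluded. A nonpositive slope yields an
    infinite doubling time with the ``shrinking`` flag set rather than an
    error.
    """
    v = record.volumes()
    keep = v > 0
    n_excluded = int((~keep).sum())
    days, v = record.days[keep], v[keep]
    if len(days) < 3:
        raise InsufficientDataError(
            f"animal {record.animal!r}: need >= 3 positive-volume observations, have {len(days)}"
        )
    res = stats.linregress(days, np.log(v))
    a = float(res.slope)
    if a > 0:
        dt, shrinking = math.log(2.0) / a, False
    else:
        dt, shrinking = math.inf, True
    return GrowthFit(
        animal=record.animal,
        group=record.group,
        n0_mm3=float(np.exp(res.intercept)),
        a_per_day=a,
        doubling_time_days=dt,
        r_squared=float(res.rvalue) ** 2,
        n_excluded=n_excluded,
        shrinking=shrinking,
    )


def summarize_groups(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    """Median and mean doubling time per group (finite fits only for the mean)."""
    df = pd.DataFrame(
        {
            "group": [f.group for f in fits],
            "doubling_time_days": [f.doubling_time_days for f in fits],
        }
    )
    return (
        df.groupby("group")["doubling_time_days"]
        .agg(n="size", median_dt="median", mean_dt="mean")
        .reset_index()
    )
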