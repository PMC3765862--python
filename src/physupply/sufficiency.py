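"""Supply-versus-need evaluation of a physician forecast.

The sufficiency level of a group (all clinicians, or one speciality) is

    level(t) = forecast(t) / (required_hospital_number x corrective_coefficient)

where the required number comes from a survey of hospital administrators and
therefore excludes clinics; the corrective coefficient scales that
hospitals-only need up to all practice settings (so it is expected to be > 1
under this convention).  A level >= 1 is read as "sufficient", < 1 as
"shortage"; speciality-level maldistribution is flagged whenever exactly one
of the two groups under comparison is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InvalidParameterError

SUFFICIENT = "sufficient"
SHORTAGE = "shortage"


@dataclass(frozen=True)
class SufficiencyCriterion:
    """Required hospital headcount plus the clinic-coverage correction.

    When ``time_varying`` is true, ``required_hospital_number`` is a mapping
    from calendar year to headcount; otherwise it is a single constant applied
    over the whole horizon (the survey behind the criterion is a snapshot, so
    constant is the default).
    """

    required_hospital_number: float | Mapping[int, float]
    corrective_coefficient: float
    time_varying: bool = False

    def __post_init__(self):
        if self.corrective_coefficient <= 0:
            raise InvalidParameterError("corrective coefficient must be positive")
        if self.time_varying:
            if not isinstance(self.required_hospital_number, Mapping):
                raise InvalidParameterError(
                    "time-varying criterion needs a year -> headcount mapping"
                )
            bad = [v for v in self.required_hospital_number.values() if v <= 0]
        else:
            if isinstance(self.required_hospital_number, Mapping):
                raise InvalidParameterError(
                    "constant criterion takes a single required number"
                )
            bad = [] if self.required_hospital_number > 0 else [self.required_hospital_number]
        if bad:
            raise InvalidParameterError("required numbers must be positive")

    def required(self, year: int | None = None) -> float:
        if self.time_varying:
            if year is None:
                raise InvalidParameterError("time-varying criterion needs a year")
            try:
                return float(self.required_hospital_number[int(year)])
            except KeyError:
                raise InvalidParameterError(
                    f"criterion does not cover year {year}"
                ) from None
        return float(self.required_hospital_number)

    def effective_required(self, year: int | None = None) -> float:
        """Required headcount across all settings: hospital need scaled up for clinics."""
        return self.required(year) * self.corrective_coefficient


def sufficiency_level(forecast: float, criterion: SufficiencyCriterion,
                      year: int | None = None) -> float:
    """Ratio of forecast supply to corrected required number (dimensionless)."""
    if forecast < 0:
        raise InvalidParameterError("forecast headcount must be non-negative")
    return forecast / criterion.effective_required(year)


def classify(level: float) -> str:
    """Sufficient iff the level reaches 1 (closed boundary)."""
    if level <= 0:
        raise InvalidParameterError("sufficiency level must be positive")
    return SUFFICIENT if level >= 1.0 else SHORTAGE


def maldistribution_flag(level_all: float, level_speciality: float) -> bool:
    """True iff exactly one of the two groups is at a sufficient level."""
    return (classify(level_all) == SUFFICIENT) != (classify(level_speciality) == SUFFICIENT)


def per_capita(headcount: float, population: float) -> float:
    """Physicians per 1 000 persons."""
    if population <= 0:
        raise InvalidParameterError("population must be positive")
    if headcount < 0:
        raise InvalidParameterError("headcount must be non-negative")
    return 1000.0 * headcount / population


@dataclass
class SufficiencySeries:
    """Per-year sufficiency levels and their classification for one group."""

    frame: pd.DataFrame  # columns: year, level, classification

    @classmethod
    def from_forecast(cls, forecast: pd.Series,
                      criterion: SufficiencyCriterion) -> "SufficiencySeries":
        rows = [
            {"year": int(year), "level": sufficiency_level(value, criterion, int(year)),
             "classification": classify(sufficiency_level(value, criterion, int(year)))}
            for year, value in forecast.sort_index().items()
        ]
        return cls(pd.DataFrame(rows))

    @property
    def levels(self) -> pd.Series:
        return self.frame.set_index("year")["level"]

    def growth_pct(self) -> float:
        """Percent growth of the level from the first to the last year."""
        levels = self.levels
        return 100.0 * (levels.iloc[-1] / levels.iloc[0] - 1.0)


def crossing_year(series: pd.Series | SufficiencySeries,
                  threshold: float = 1.0) -> int | None:
    """First year the series reaches the threshold; None if it never does."""
    values = series.levels if isinstance(series, SufficiencySeries) else series
    if len(values) == 0:
        raise InvalidParameterError("series must be non-empty")
    hit = values.sort_index()[values.sort_index() >= threshold]
    return int(hit.index[0]) if len(hit) else None
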