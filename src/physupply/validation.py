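"""Backcast validation: simulated versus observed headcounts.

For each validation year the per-year relative error is

    e_t = |simulated_t - observed_t| / observed_t

and the aggregate statistics over the n validation years are

* ``mse_literal`` - the mean of the squared relative errors, sum(e_t^2)/n;
* ``rmse``        - its square root;
* ``mean_relative_error`` - the plain mean of the e_t.

All three are reported side by side: the squared-error mean is tiny (order
1e-5 for percent-level errors) while the root and the plain mean live on the
same scale as the per-year errors, and published summaries of this kind of
backcast are often quoted on that per-year scale.  Printing every candidate
keeps the report unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidParameterError


def relative_error(historic: float, simulated: float) -> float:
    """Absolute relative error of a simulated headcount against the observed one."""
    if historic <= 0:
        raise InvalidParameterError(f"historic headcount must be positive, got {historic}")
    if simulated < 0:
        raise InvalidParameterError("simulated headcount must be non-negative")
    return abs(simulated - historic) / historic


@dataclass(frozen=True)
class ValidationRecord:
    year: int
    historic: float
    simulated: float

    @property
    def relative_error(self) -> float:
        return relative_error(self.historic, self.simulated)


@dataclass
class ValidationReport:
    """Per-year records plus the aggregate error statistics."""

    records: list[ValidationRecord]
    mse_literal: float
    rmse: float
    mean_relative_error: float

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def errors(self) -> list[float]:
        return [r.relative_error for r in self.records]

    @property
    def max_relative_error(self) -> float:
        return max(self.errors)

    def passes(self, threshold: float = 0.10) -> bool:
        """Reasonableness check on the per-year-scale statistic (rmse)."""
        return self.rmse < threshold

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Wide layout: one column per year, rows historic / simulated / error.

        Error cells are rounded half-even to ``decimals`` places, the usual
        presentation in published comparisons of this shape.
        """
        years = [r.year for r in self.records]
        frame = pd.DataFrame(
            {
                "row": ["historic", "simulated", "relative_error"],
                **{
                    str(r.year): [r.historic, r.simulated,
                                  _round_half_even(r.relative_error, decimals)]
                    for r in self.records
                },
            }
        )
        frame["mse_literal"] = [float("nan"), float("nan"), self.mse_literal]
        frame["rmse"] = [float("nan"), float("nan"),
                         _round_half_even(self.rmse, decimals)]
        frame["mean_relative_error"] = [float("nan"), float("nan"),
                                        _round_half_even(self.mean_relative_error, decimals)]
        return frame.set_index("row")

    def to_csv(self, path, decimals: int = 3) -> None:
        self.to_frame(decimals).to_csv(path)


def _round_half_even(x: float, decimals: int) -> float:
    return float(pd.Series([x]).round(decimals).iloc[0])


def aggregate_errors(records: list[ValidationRecord]) -> ValidationReport:
    """Aggregate per-year records into the three candidate error statistics."""
    if not records:
        raise InvalidParameterError("at least one validation record is required")
    errors = [r.relative_error for r in records]
    mse = sum(e * e for e in errors) / len(errors)
    return ValidationReport(
        records=list(records),
        mse_literal=mse,
        rmse=math.sqrt(mse),
        mean_relative_error=sum(errors) / len(errors),
    )


def compare_series(historic: pd.Series, simulated: pd.Series,
                   years: list[int] | None = None) -> ValidationReport:
    """Validate a simulated series against the observed one at the given years."""
    if years is None:
        years = sorted(set(historic.index) & set(simulated.index))
        if not years:
            raise InvalidParameterError("series share no years")
    missing_h = [y for y in years if y not in historic.index]
    missing_s = [y for y in years if y not in simulated.index]
    if missing_h or missing_s:
        parts = []
        if missing_h:
            parts.append(f"historic series lacks years {missing_h}")
        if missing_s:
            parts.append(f"simulated series lacks years {missing_s}")
        raise InvalidParameterError("; ".join(parts))
    records = [
        ValidationRecord(int(y), float(historic.loc[y]), float(simulated.loc[y]))
        for y in years
    ]
    return aggregate_errors(records)
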