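"""Readers and writers for the package's plain-text interfaces.

Formats (all CSV with a header row, or YAML for parameter files):

* quota series:         ``year,quota``
* population series:    ``year,population``
* headcount series:     ``year,headcount`` (historic or simulated totals)
* workforce census:     ``year,age_band,sex,speciality,workplace,headcount``
* required survey:      ``group,required_hospital_number``
* parameter file:       YAML mapping of :class:`~physupply.pipeline.ParameterSet`
                        fields, with the quota series inline
* scenario file:        YAML list of scenario mappings
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError
from .pipeline import ParameterSet
from .scenarios import Scenario
from .sufficiency import SufficiencyCriterion


def _read_two_column(path, value_column: str) -> pd.Series:
    frame = pd.read_csv(path)
    for column in ("year", value_column):
        if column not in frame.columns:
            raise ConfigurationError(f"{path}: missing column {column!r}")
    series = frame.set_index(frame["year"].astype(int))[value_column].astype(float)
    return series.sort_index()


def read_quota_csv(path) -> pd.Series:
    return _read_two_column(path, "quota")


def write_quota_csv(quota: Mapping[int, float] | pd.Series, path) -> None:
    series = pd.Series(dict(quota)).sort_index()
    series.rename_axis("year").rename("quota").to_csv(path)


def read_population_csv(path) -> pd.Series:
    return _read_two_column(path, "population")


def write_population_csv(population: pd.Series, path) -> None:
    population.rename_axis("year").rename("population").to_csv(path)


def read_headcount_csv(path) -> pd.Series:
    return _read_two_column(path, "headcount")


def write_headcount_csv(series: pd.Series, path) -> None:
    series.rename_axis("year").rename("headcount").to_csv(path)


_CENSUS_COLUMNS = ["year", "age_band", "sex", "speciality", "workplace", "headcount"]


def read_census_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_CENSUS_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing census columns {sorted(missing)}")
    return frame[_CENSUS_COLUMNS]


def write_census_csv(census: pd.DataFrame, path) -> None:
    census[_CENSUS_COLUMNS].to_csv(path, index=False)


def read_required_csv(path, corrective_coefficient: float) -> dict[str, SufficiencyCriterion]:
    """One sufficiency criterion per group row, sharing a corrective coefficient."""
    frame = pd.read_csv(path)
    for column in ("group", "required_hospital_number"):
        if column not in frame.columns:
            raise ConfigurationError(f"{path}: missing column {column!r}")
    return {
        str(row["group"]): SufficiencyCriterion(
            required_hospital_number=float(row["required_hospital_number"]),
            corrective_coefficient=corrective_coefficient,
        )
        for _, row in frame.iterrows()
    }


def write_required_csv(criteria: Mapping[str, SufficiencyCriterion] | pd.DataFrame, path) -> None:
    if isinstance(criteria, pd.DataFrame):
        criteria.to_csv(path, index=False)
        return
    frame = pd.DataFrame(
        [{"group": group, "required_hospital_number": c.required()}
         for group, c in criteria.items()]
    )
    frame.to_csv(path, index=False)


def load_parameters(path) -> ParameterSet:
    """Load a ParameterSet from YAML; ``quota_csv`` may replace an inline series."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    if "quota_csv" in raw:
        quota_path = Path(path).parent / raw.pop("quota_csv")
        raw["quota_series"] = read_quota_csv(quota_path).to_dict()
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown parameter fields {sorted(unknown)}")
    try:
        return ParameterSet(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def save_parameters(params: ParameterSet, path) -> None:
    payload = dataclasses.asdict(params)
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=True)


def load_scenarios(path) -> list[Scenario]:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list):
        raise ConfigurationError(f"{path}: expected a list of scenarios")
    known = {f.name for f in dataclasses.fields(Scenario)}
    scenarios = []
    for entry in raw:
        unknown = set(entry) - known
        if unknown:
            raise ConfigurationError(
                f"{path}: scenario {entry.get('name', '?')!r} has unknown fields {sorted(unknown)}"
            )
        scenarios.append(Scenario(**entry))
    return scenarios


def save_scenarios(scenarios: list[Scenario], path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump([dataclasses.asdict(s) for s in scenarios], handle, sort_keys=False)
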