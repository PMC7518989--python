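"""Readers and writers for the CSV/YAML exchange formats.

Time series travel as CSV (``date,tmax,tmean,tmin,humidity`` for climate,
``date,deaths`` for mortality, ``day,tmax,hot_days,apf,tpf,deaths,ap`` for
trajectories); configuration travels as YAML (an ``exposure:`` block, an
``adaptation:`` block with weights and the reference city, a ``tables:``
block with MA/HDAF breakpoint lists).  All writes are atomic: the file is
either fully written or absent.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import logging
import os
import tempfile
from contextlib import contextmanager
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .adaptation import AdaptationParameters, CityProfile
from .climate import DailyClimateRecord, TableFunction, TemperatureSeries
from .engine import ModelParameters, SimulationResult
from .errors import ConfigurationError, InputError
from .exposure import ExposureParameters

__all__ = [
    "read_climate_csv", "write_climate_csv",
    "read_deaths_csv", "write_deaths_csv",
    "read_city", "write_city_yaml",
    "read_params_yaml", "write_params_yaml",
    "write_simulation_csv", "read_simulation_csv",
    "default_parameters",
]

logger = logging.getLogger(__name__)

_CLIMATE_FIELDS = ("date", "tmax", "tmean", "tmin", "humidity")


@contextmanager
def atomic_write(path: str | Path):
    """Yield a text handle; move into place only on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _parse_date(text: str, lineno: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise InputError(f"line {lineno}: invalid ISO-8601 date {text!r}") from None


def read_climate_csv(path: str | Path) -> TemperatureSeries:
    """Parse a daily climate CSV into a gap-free temperature series.

    Errors name the offending line; duplicate or non-consecutive dates are
    rejected.
    """
    records: list[DailyClimateRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[0] != "date" or "tmax" not in reader.fieldnames:
            raise InputError(f"{path}: expected header starting 'date,tmax'")
        for row in reader:
            lineno = reader.line_num
            try:
                def opt(key: str) -> float | None:
                    v = (row.get(key) or "").strip()
                    return float(v) if v else None

                records.append(
                    DailyClimateRecord(
                        date=_parse_date(row["date"], lineno),
                        tmax=float(row["tmax"]),
                        tmean=opt("tmean"),
                        tmin=opt("tmin"),
                        humidity=opt("humidity"),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise InputError(f"{path} line {lineno}: malformed row ({exc})") from None
    if not records:
        raise InputError(f"{path}: no data rows")
    try:
        return TemperatureSeries(records)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


def write_climate_csv(series: TemperatureSeries, path: str | Path) -> None:
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLIMATE_FIELDS)
        for r in series:
            writer.writerow(
                [
                    r.date.isoformat(),
                    _fmt(r.tmax),
                    _fmt(r.tmean),
                    _fmt(r.tmin),
                    _fmt(r.humidity),
                ]
            )


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))  # repr round-trips exactly


def read_deaths_csv(path: str | Path) -> pd.Series:
    """Parse a ``date,deaths`` CSV into an integer series indexed by date."""
    dates: list[dt.date] = []
    counts: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["date", "deaths"]:
            raise InputError(f"{path}: expected header 'date,deaths'")
        for row in reader:
            lineno = reader.line_num
            dates.append(_parse_date(row["date"], lineno))
            try:
                counts.append(int(row["deaths"]))
            except (TypeError, ValueError):
                raise InputError(
                    f"{path} line {lineno}: deaths must be an integer, "
                    f"got {row['deaths']!r}"
                ) from None
    if not dates:
        raise InputError(f"{path}: no data rows")
    return pd.Series(counts, index=pd.Index(dates, name="date"), name="deaths")


def write_deaths_csv(deaths: pd.Series, path: str | Path) -> None:
    with atomic_write(path) as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "deaths"])
        for date, count in deaths.items():
            writer.writerow([date.isoformat(), int(count)])


def read_city(path: str | Path) -> CityProfile:
    """Read a city profile from YAML (``city:`` block) or a one-row CSV."""
    path = Path(path)
    field_names = [f.name for f in dataclasses.fields(CityProfile)]
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        block = doc.get("city") if isinstance(doc, dict) else None
        if not isinstance(block, dict):
            raise InputError(f"{path}: expected a 'city:' mapping")
        return _city_from_mapping(block, str(path))
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if len(rows) != 1:
        raise InputError(f"{path}: expected exactly one data row, got {len(rows)}")
    return _city_from_mapping(rows[0], str(path))


def _city_from_mapping(mapping: dict, source: str) -> CityProfile:
    kwargs = {}
    for f in dataclasses.fields(CityProfile):
        if f.name not in mapping:
            raise InputError(f"{source}: missing city field {f.name!r}")
        try:
            kwargs[f.name] = float(mapping[f.name])
        except (TypeError, ValueError):
            raise InputError(
                f"{source}: city field {f.name!r} must be numeric"
            ) from None
    try:
        return CityProfile(**kwargs)
    except InputError as exc:
        raise InputError(f"{source}: {exc}") from None


def write_city_yaml(profile: CityProfile, path: str | Path) -> None:
    with atomic_write(path) as fh:
        yaml.safe_dump({"city": dataclasses.asdict(profile)}, fh, sort_keys=False)


_NEUTRAL_TABLE = [[0.0, 1.0], [30.0, 1.0]]


def read_params_yaml(path: str | Path) -> ModelParameters:
    """Load a full parameter set, validating every declared invariant.

    Absent optional blocks get documented defaults; a missing MA or HDAF
    table becomes the neutral table (constant 1) with a logged warning.
    Validation failures name the offending field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return params_from_mapping(doc, source=str(path))


def params_from_mapping(doc: dict, source: str = "<config>") -> ModelParameters:
    exposure_doc = doc.get("exposure", {})
    try:
        exposure = ExposureParameters(**exposure_doc)
    except (TypeError, InputError) as exc:
        raise ConfigurationError(f"{source}: exposure block invalid: {exc}") from None

    ad_doc = dict(doc.get("adaptation", {}))
    ref_doc = ad_doc.pop("reference_city", None)
    if ref_doc is None:
        raise ConfigurationError(f"{source}: adaptation.reference_city is required")
    reference = _city_from_mapping(ref_doc, f"{source}: adaptation.reference_city")
    try:
        adaptation = AdaptationParameters(reference_profile=reference, **ad_doc)
    except (TypeError, ConfigurationError) as exc:
        raise ConfigurationError(f"{source}: adaptation block invalid: {exc}") from None

    tables = doc.get("tables", {})
    table_objs = {}
    for key in ("MA", "HDAF"):
        if key in tables:
            try:
                table_objs[key] = TableFunction(tables[key])
            except ConfigurationError as exc:
                raise ConfigurationError(f"{source}: tables.{key}: {exc}") from None
        else:
            logger.warning("%s: no %s table; using neutral default", source, key)
            table_objs[key] = TableFunction(_NEUTRAL_TABLE)

    extra = {}
    for key in ("background_rate", "bed_capacity", "allowance_elasticity",
                "elderly_vulnerability", "hot_threshold"):
        if key in doc:
            extra[key] = float(doc[key])
    for key in ("cf_on_apf", "tpf_delay"):
        if key in doc:
            extra[key] = bool(doc[key])
    return ModelParameters(
        exposure=exposure,
        adaptation=adaptation,
        ma_table=table_objs["MA"],
        hdaf_table=table_objs["HDAF"],
        **extra,
    )


def write_params_yaml(params: ModelParameters, path: str | Path) -> None:
    doc = {
        "exposure": dataclasses.asdict(params.exposure),
        "adaptation": {
            "af0": params.adaptation.af0,
            "af_cap": params.adaptation.af_cap,
            "factor_floor": params.adaptation.factor_floor,
            "factor_cap": params.adaptation.factor_cap,
            "weights": dict(params.adaptation.weights),
            "reference_city": dataclasses.asdict(params.adaptation.reference_profile),
        },
        "tables": {
            "MA": [list(p) for p in params.ma_table.breakpoints],
            "HDAF": [list(p) for p in params.hdaf_table.breakpoints],
        },
        "background_rate": params.background_rate,
        "bed_capacity": params.bed_capacity,
        "allowance_elasticity": params.allowance_elasticity,
        "elderly_vulnerability": params.elderly_vulnerability,
        "hot_threshold": params.hot_threshold,
        "cf_on_apf": params.cf_on_apf,
        "tpf_delay": params.tpf_delay,
    }
    with atomic_write(path) as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_parameters() -> ModelParameters:
    """The shipped default calibration (fitted on the 2013-like fixture)."""
    ref = resources.files("heatsd.data").joinpath("default_params.yaml")
    with resources.as_file(ref) as path:
        return read_params_yaml(path)


def write_simulation_csv(result: SimulationResult, path: str | Path) -> None:
    """Trajectory CSV with a comment line carrying the params fingerprint."""
    frame = result.to_frame()
    with atomic_write(path) as fh:
        fh.write(
            f"# params: {result.fingerprint} scenario: {result.scenario.kind}\n"
        )
        frame.to_csv(fh, index=False)


def read_simulation_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
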