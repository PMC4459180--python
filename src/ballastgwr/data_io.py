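"""Station flux table I/O.

The observation unit of the whole analysis is a *station*: one location and
date with surface (Th-234 derived) export fluxes of POC and the three
mineral phases — PIC (calcium carbonate), BSi (biogenic silica / opal) and
lithogenic material — in mg m⁻² d⁻¹.  Tables travel as plain CSV with one
header row, comma separator, "." decimal, ISO-8601 dates and empty cells
for missing optional values.

Canonical ``stations.csv`` columns::

    station_id,date,lat,lon,f_poc,f_pic,f_bsi,f_lith,pal,f_th,region

``pal`` (particulate-Al concentration, nmol L⁻¹), ``f_th`` (Th-234 flux,
dpm m⁻² d⁻¹) and ``region`` are optional.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mandatory columns of a station table, in canonical order.
MANDATORY_COLUMNS = ("station_id", "date", "lat", "lon", "f_poc", "f_pic", "f_bsi", "f_lith")
#: Optional columns, in canonical order.
OPTIONAL_COLUMNS = ("pal", "f_th", "region")
#: Full canonical column order.
ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

FLUX_COLUMNS = ("f_poc", "f_pic", "f_bsi", "f_lith")


class SchemaError(ValueError):
    """The file lacks a mandatory column."""


class ParseError(ValueError):
    """A cell could not be parsed; names the row and column."""


class ValidationError(ValueError):
    """A row violates a station-table invariant."""


def normalize_longitude(lon: float) -> float:
    """Map a longitude in degrees east onto (−180, 180]."""
    lon = (float(lon) + 180.0) % 360.0 - 180.0
    return 180.0 if lon == -180.0 else lon


@dataclass(frozen=True)
class StationRecord:
    """One station's location, date and export fluxes.

    Fluxes are in mg m⁻² d⁻¹; ``pal`` is the particulate-Al concentration
    in nmol L⁻¹ and ``f_th`` the Th-234 flux in dpm m⁻² d⁻¹ (both may be
    ``None``).
    """

    station_id: str
    date: _dt.date
    lat: float
    lon: float
    f_poc: float
    f_pic: float
    f_bsi: float
    f_lith: float
    pal: float | None = None
    f_th: float | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.station_id:
            raise ValidationError("station_id must be non-empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"station {self.station_id!r}: lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"station {self.station_id!r}: lon {self.lon} outside [-180, 180]")
        for name in FLUX_COLUMNS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"station {self.station_id!r}: {name}={value} must be finite and >= 0"
                )
        for name in ("pal", "f_th"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValidationError(
                    f"station {self.station_id!r}: {name}={value} must be finite and >= 0"
                )


@dataclass
class StationTable:
    """Ordered, validated collection of :class:`StationRecord`.

    Non-empty and free of duplicated station ids.  Provides array views of
    the columns the regressions consume.
    """

    records: list[StationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("station table must be non-empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.station_id in seen:
                raise ValidationError(f"duplicated station_id {rec.station_id!r}")
            seen.add(rec.station_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StationRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> StationRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StationTable):
            return NotImplemented
        return self.records == other.records

    # -- array views -------------------------------------------------
    def column(self, name: str) -> np.ndarray:
        """Numeric column as a float array (None → NaN)."""
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.column("lat")

    @property
    def lons(self) -> np.ndarray:
        return self.column("lon")

    @property
    def station_ids(self) -> list[str]:
        return [r.station_id for r in self.records]

    def design_matrix(self) -> np.ndarray:
        """n × 4 design [f_pic, f_bsi, f_lith, 1] for the carrying-coefficient model."""
        n = len(self)
        X = np.empty((n, 4))
        X[:, 0] = self.column("f_pic")
        X[:, 1] = self.column("f_bsi")
        X[:, 2] = self.column("f_lith")
        X[:, 3] = 1.0
        return X

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "station_id": r.station_id,
                    "date": r.date.isoformat(),
                    "lat": r.lat,
                    "lon": r.lon,
                    "f_poc": r.f_poc,
                    "f_pic": r.f_pic,
                    "f_bsi": r.f_bsi,
                    "f_lith": r.f_lith,
                    "pal": r.pal,
                    "f_th": r.f_th,
                    "region": r.region,
                }
            )
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))

    def subset(self, indices: Sequence[int]) -> "StationTable":
        return StationTable([self.records[i] for i in indices])


def _parse_float(value: object, row: int, column: str, optional: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if optional:
            return None
        raise ParseError(f"row {row}: missing value in column {column!r}")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {row}: non-numeric value {value!r} in column {column!r}") from exc


def _parse_date(value: object, row: int) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ParseError(f"row {row}: unparseable ISO date {value!r}") from exc


def read_station_table(path: str | Path, strict: bool = True) -> StationTable:
    """Read and validate a station flux table from CSV.

    Parameters
    ----------
    path:
        CSV file with the canonical header.
    strict:
        If True (default) any invalid row raises, naming the row; if False
        invalid rows are dropped with a logged warning and the count of
        dropped rows is reported via the logger.

    Returns
    -------
    StationTable

    Raises
    ------
    SchemaError
        A mandatory column is missing from the header.
    ParseError, ValidationError
        Under ``strict``, the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "region": str}, float_precision="round_trip")
    try:
        return from_dataframe(df, strict=strict)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_station_table(table: StationTable, path: str | Path) -> None:
    """Write a station table to CSV so that it round-trips exactly.

    Numeric fields are written with 17 significant digits (lossless for
    doubles); missing optional values become empty cells.
    """
    if not isinstance(table, StationTable):
        raise TypeError("expected a StationTable")
    df = table.to_dataframe()
    df.to_csv(Path(path), index=False, float_format="%.17g")


PROFILE_COLUMNS = ("station_id", "depth_m", "th234_dpm_l")


def read_profiles(path: str | Path, u238_slope: float = 0.0786, u238_offset: float = -0.315):
    """Read Th-234 activity profiles keyed by station.

    ``profiles.csv`` schema: ``station_id,depth_m,th234_dpm_l,u238_dpm_l,
    salinity``.  Direct U-238 measurements take precedence; where absent,
    U-238 is derived from salinity with the linear law (configurable
    coefficients).  Returns ``dict[station_id, ActivityProfile]``.
    """
    from .thflux import ActivityProfile, u238_from_salinity

    df = pd.read_csv(Path(path), dtype={"station_id": str}, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    if "u238_dpm_l" not in df.columns and "salinity" not in df.columns:
        raise SchemaError(f"{path}: need either u238_dpm_l or salinity")
    profiles = {}
    for sid, grp in df.groupby("station_id", sort=False):
        grp = grp.sort_values("depth_m")
        u238 = grp["u238_dpm_l"].to_numpy(float) if "u238_dpm_l" in grp else np.full(len(grp), np.nan)
        if np.any(~np.isfinite(u238)):
            if "salinity" not in grp:
                raise ParseError(f"station {sid!r}: u238_dpm_l missing and no salinity column")
            sal = grp["salinity"].to_numpy(float)
            u238 = np.array(
                [
                    u if np.isfinite(u) else u238_from_salinity(s, u238_slope, u238_offset)
                    for u, s in zip(u238, sal)
                ]
            )
        profiles[str(sid)] = ActivityProfile(
            depths=grp["depth_m"].to_numpy(float),
            th234=grp["th234_dpm_l"].to_numpy(float),
            u238=u238,
        )
    return profiles


def from_dataframe(df: pd.DataFrame, strict: bool = True) -> StationTable:
    """Build a validated StationTable from an in-memory DataFrame."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[StationRecord] = []
    dropped = 0
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        row_d = row.to_dict()
        try:
            region = row_d.get("region")
            if region is None or (isinstance(region, float) and math.isnan(region)) or region == "":
                region = None
            records.append(
                StationRecord(
                    station_id=str(row_d["station_id"]),
                    date=_parse_date(row_d["date"], i),
                    lat=float(_parse_float(row_d["lat"], i, "lat")),
                    lon=normalize_longitude(_parse_float(row_d["lon"], i, "lon")),
                    f_poc=float(_parse_float(row_d["f_poc"], i, "f_poc")),
                    f_pic=float(_parse_float(row_d["f_pic"], i, "f_pic")),
                    f_bsi=float(_parse_float(row_d["f_bsi"], i, "f_bsi")),
                    f_lith=float(_parse_float(row_d["f_lith"], i, "f_lith")),
                    pal=_parse_float(row_d.get("pal"), i, "pal", optional=True),
                    f_th=_parse_float(row_d.get("f_th"), i, "f_th", optional=True),
                    region=str(region) if region is not None else None,
                )
            )
        except (ParseError, ValidationError) as exc:
            if strict:
                raise
            dropped += 1
            logger.warning("dropping row %d: %s", i, exc)
    if dropped:
        logger.warning("dropped %d invalid row(s), kept %d", dropped, len(records))
    return StationTable(records)
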