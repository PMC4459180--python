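"""Partition POC export into mineral-associated and unassociated portions.

With fitted carrying coefficients (global or local), each station's POC
flux decomposes exactly as

    f_poc = a·f_pic + b·f_bsi + c·f_lith + d + residual,

so the PIC-, BSi- and lithogenic-associated POC fluxes are coefficient ×
mineral flux, the unassociated portion is the intercept, and the remainder
is the model residual.  Percentages are expressed against the *observed*
POC flux; negative associated fluxes (from negative local coefficients)
are reported as-is and flagged, with an optional clipped variant.
Regional aggregates are unweighted station means by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ballast_gwr import GWRFit
from .ballast_mlra import GlobalFit
from .data_io import StationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSpec:
    """A latitude/longitude box naming an ocean region.

    Bounds are inclusive; longitude bounds in (−180, 180].  Stations are
    assigned to the first matching region in list order (first-match
    priority), so overlapping boxes are allowed.
    """

    name: str
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max
        )


#: Default ocean provinces: high-latitude North Atlantic, Nordic/Arctic seas,
#: subtropical gyres, Southern Ocean.  Listed in priority order (the Arctic
#: box is checked first so HLNA stops at the polar circle).
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec("Arctic", lat_min=66.5),
    RegionSpec("HLNA", lat_min=45.0, lat_max=66.5, lon_min=-80.0, lon_max=30.0),
    RegionSpec("Subtropical gyres", lat_min=-25.0, lat_max=25.0),
    RegionSpec("Southern Ocean", lat_max=-45.0),
)


@dataclass
class PartitionResult:
    """Per-station mineral-associated POC fluxes and percent-ballasted shares.

    Fluxes in mg C m⁻² d⁻¹; percentages relative to the observed POC flux.
    ``pct_ballasted`` = pct_pic + pct_bsi + pct_lith.  ``flags`` marks
    stations with negative components or zero observed POC.
    """

    station_ids: list[str]
    poc_pic: np.ndarray
    poc_bsi: np.ndarray
    poc_lith: np.ndarray
    poc_nonassoc: np.ndarray
    residual: np.ndarray
    pct_pic: np.ndarray
    pct_bsi: np.ndarray
    pct_lith: np.ndarray
    pct_ballasted: np.ndarray
    pct_nonassoc: np.ndarray
    flags: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_ids,
                "poc_pic": self.poc_pic,
                "poc_bsi": self.poc_bsi,
                "poc_lith": self.poc_lith,
                "poc_nonassoc": self.poc_nonassoc,
                "residual": self.residual,
                "pct_pic": self.pct_pic,
                "pct_bsi": self.pct_bsi,
                "pct_lith": self.pct_lith,
                "pct_ballasted": self.pct_ballasted,
                "pct_nonassoc": self.pct_nonassoc,
            }
        )


def _coefficient_arrays(fit: GWRFit | GlobalFit, n: int) -> np.ndarray:
    """n × 4 per-station coefficients from either fit type."""
    if isinstance(fit, GWRFit):
        if fit.n != n:
            raise ValueError("fit and table are misaligned (different station counts)")
        return fit.local_coefficients
    if isinstance(fit, GlobalFit):
        if fit.n != n:
            raise ValueError("fit and table are misaligned (different station counts)")
        return np.tile(fit.coefficients, (n, 1))
    raise TypeError(f"expected GWRFit or GlobalFit, got {type(fit).__name__}")


def partition_poc(
    fit: GWRFit | GlobalFit,
    table: StationTable,
    clip_negative: bool = False,
) -> PartitionResult:
    """Decompose each station's observed POC flux with the fitted coefficients.

    The identity poc_pic + poc_bsi + poc_lith + poc_nonassoc + residual =
    observed f_poc holds to machine precision.  With ``clip_negative``,
    negative associated components are floored at 0 for the percentage
    columns only (the flux columns stay untouched); by default nothing is
    clipped and negative components are flagged.
    """
    n = len(table)
    coefs = _coefficient_arrays(fit, n)
    f_pic = table.column("f_pic")
    f_bsi = table.column("f_bsi")
    f_lith = table.column("f_lith")
    f_poc = table.column("f_poc")

    poc_pic = coefs[:, 0] * f_pic
    poc_bsi = coefs[:, 1] * f_bsi
    poc_lith = coefs[:, 2] * f_lith
    poc_nonassoc = coefs[:, 3].copy()
    residual = f_poc - (poc_pic + poc_bsi + poc_lith + poc_nonassoc)

    flags: list[str] = []
    for i, sid in enumerate(table.station_ids):
        neg = [
            name
            for name, v in (("pic", poc_pic[i]), ("bsi", poc_bsi[i]), ("lith", poc_lith[i]))
            if v < 0
        ]
        if neg:
            flags.append(f"{sid}: negative associated flux ({', '.join(neg)})")
        if f_poc[i] == 0:
            flags.append(f"{sid}: observed POC flux is 0, percentages undefined")

    def pct(component: np.ndarray) -> np.ndarray:
        comp = np.maximum(component, 0.0) if clip_negative else component
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * comp / f_poc
        out[f_poc == 0] = np.nan
        return out

    pct_pic = pct(poc_pic)
    pct_bsi = pct(poc_bsi)
    pct_lith = pct(poc_lith)
    return PartitionResult(
        station_ids=table.station_ids,
        poc_pic=poc_pic,
        poc_bsi=poc_bsi,
        poc_lith=poc_lith,
        poc_nonassoc=poc_nonassoc,
        residual=residual,
        pct_pic=pct_pic,
        pct_bsi=pct_bsi,
        pct_lith=pct_lith,
        pct_ballasted=pct_pic + pct_bsi + pct_lith,
        pct_nonassoc=pct(poc_nonassoc),
        flags=flags,
    )


def assign_regions(table: StationTable, regions: tuple[RegionSpec, ...] | list[RegionSpec]) -> list[str]:
    """First-match region name per station; unmatched stations get 'other'."""
    out = []
    for rec in table:
        for region in regions:
            if region.contains(rec.lat, rec.lon):
                out.append(region.name)
                break
        else:
            out.append("other")
    return out


def regional_summary(
    partition: PartitionResult,
    table: StationTable,
    regions: tuple[RegionSpec, ...] | list[RegionSpec] = DEFAULT_REGIONS,
    flux_weighted: bool = False,
) -> pd.DataFrame:
    """Per-region means of the partition percentages and fluxes.

    Default aggregation is the unweighted station mean; ``flux_weighted``
    weights stations by their observed POC flux instead.  Stations matching
    no region are pooled under "other"; declared regions with no stations
    appear with count 0 and NaN means.
    """
    if len(partition.station_ids) != len(table):
        raise ValueError("partition and table are misaligned")
    df = partition.to_dataframe()
    df["region"] = assign_regions(table, regions)
    df["f_poc"] = table.column("f_poc")

    value_cols = [
        "pct_pic", "pct_bsi", "pct_lith", "pct_ballasted", "pct_nonassoc",
        "poc_pic", "poc_bsi", "poc_lith", "poc_nonassoc",
    ]
    rows = []
    names = [r.name for r in regions] + ["other"]
    for name in names:
        sub = df[df["region"] == name]
        row: dict[str, object] = {"region": name, "n_stations": len(sub)}
        for col in value_cols:
            if len(sub) == 0:
                row[col] = np.nan
            elif flux_weighted:
                w = sub["f_poc"].to_numpy()
                v = sub[col].to_numpy()
                ok = np.isfinite(v)
                row[col] = float(np.average(v[ok], weights=w[ok])) if w[ok].sum() > 0 else np.nan
            else:
                row[col] = float(sub[col].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
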