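"""Shared fixtures: small hand-built tables and synthetic-table factories."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pytest

from ballastgwr.data_io import StationRecord, StationTable
from ballastgwr.synthetic import (
    BasinBox,
    CoefficientField,
    SyntheticConfig,
    default_study_config,
    generate_table,
)


def make_random_table(n: int, seed: int, scatter_deg: float = 60.0) -> StationTable:
    """Random valid station table: uniform coordinates, lognormal fluxes."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(
            StationRecord(
                station_id=f"R{i:03d}",
                date=dt.date(2012, 1, 1) + dt.timedelta(days=i),
                lat=float(rng.uniform(-scatter_deg, scatter_deg)),
                lon=float(rng.uniform(-180.0, 180.0)),
                f_poc=float(rng.lognormal(4.0, 0.6)),
                f_pic=float(rng.lognormal(2.5, 1.0)),
                f_bsi=float(rng.lognormal(3.0, 1.0)),
                f_lith=float(rng.lognormal(1.0, 1.0)),
            )
        )
    return StationTable(recs)


def make_exact_table(
    n: int, seed: int, coefs=(0.3, 0.2, 0.1, 50.0)
) -> StationTable:
    """Table whose POC flux satisfies the linear ballast model exactly."""
    rng = np.random.default_rng(seed)
    a, b, c, d = coefs
    recs = []
    for i in range(n):
        f_pic = float(rng.lognormal(2.5, 1.0))
        f_bsi = float(rng.lognormal(3.0, 1.0))
        f_lith = float(rng.lognormal(1.0, 1.0))
        recs.append(
            StationRecord(
                station_id=f"E{i:03d}",
                date=dt.date(2012, 6, 1),
                lat=float(rng.uniform(-70, 70)),
                lon=float(rng.uniform(-180, 180)),
                f_poc=a * f_pic + b * f_bsi + c * f_lith + d,
                f_pic=f_pic,
                f_bsi=f_bsi,
                f_lith=f_lith,
            )
        )
    return StationTable(recs)


def calibration_config(varying: bool, seed: int, n_stations: int = 100) -> SyntheticConfig:
    """Synthetic config for variability-test calibration.

    When ``varying``, the PIC coefficient follows a logistic front at 45°N
    (0.1 south, 0.6 north); all other coefficients are constant everywhere.
    """
    fields = {
        "a": (
            CoefficientField(kind="logistic_lat", south=0.1, north=0.6, front_lat=45.0, width=6.0)
            if varying
            else CoefficientField(kind="constant", value=0.35)
        ),
        "b": CoefficientField(kind="constant", value=0.2),
        "c": CoefficientField(kind="constant", value=0.1),
        "d": CoefficientField(kind="constant", value=50.0),
    }
    boxes = [
        BasinBox("N", 50.0, 70.0, -60.0, 0.0, 1.0),
        BasinBox("S", -65.0, -45.0, -60.0, 20.0, 1.0),
        BasinBox("Mid", -40.0, 40.0, -45.0, 10.0, 1.0),
    ]
    return SyntheticConfig(
        n_stations=n_stations,
        boxes=boxes,
        coefficient_fields=fields,
        mineral_flux_logmeans={"pic": math.log(15.0), "bsi": math.log(25.0), "lith": math.log(2.0)},
        mineral_flux_logsds={"pic": 1.0, "bsi": 1.1, "lith": 1.2},
        noise_sd=10.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def studylike():
    """Default study-like table (seed 0) with its truth table."""
    return generate_table(default_study_config(seed=0))


@pytest.fixture
def small_table() -> StationTable:
    return make_random_table(8, seed=3)
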