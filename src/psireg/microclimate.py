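"""Microclimate processing and dendrometer calibration.

Converts raw temperature/relative-humidity records to vapour pressure
deficit using the Buck (1981) over-water saturation vapour pressure, and
calibrates branchlet-width signals to stem water potential with per-plant
ordinary least squares against pressure-chamber observations.

Tabular series are plain :class:`pandas.DataFrame` objects with fixed column
names (see :data:`CLIMATE_COLUMNS`, :data:`WIDTH_COLUMNS`); loaders accept
the CSV dialects documented there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "saturation_vapour_pressure",
    "compute_vpd",
    "load_climate_csv",
    "load_width_csv",
    "make_climate_series",
    "fit_width_calibration",
    "apply_calibration",
]

#: climate CSV / DataFrame columns (ISO-8601 timestamps, site-local time)
CLIMATE_COLUMNS = ("timestamp", "temp_c", "rh_pct")
#: dendrometer CSV / DataFrame columns
WIDTH_COLUMNS = ("timestamp", "plant_id", "width_um")

_TEMP_RANGE = (-20.0, 60.0)
_MAX_GAP_MINUTES = 30.0


class CalibrationError(ValueError):
    """Raised when a width-to-potential calibration cannot be fitted."""


@dataclass(frozen=True)
class CalibrationModel:
    """Per-plant linear map from branchlet width (um) to stem potential (MPa)."""

    plant_id: str
    slope: float  # MPa per um
    intercept: float  # MPa
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration requires >= 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def predict(self, width_um):
        return self.slope * np.asarray(width_um, dtype=float) + self.intercept

    def invert(self, psi_mpa):
        """Width that maps to the given potential (used by simulators)."""
        return (np.asarray(psi_mpa, dtype=float) - self.intercept) / self.slope


def saturation_vapour_pressure(temp_c):
    """Buck (1981) saturation vapour pressure over water, kPa.

    ``es = 0.61121 * exp((18.678 - T/234.5) * T / (257.14 + T))`` with T in
    degrees Celsius; strictly increasing on the supported (-20, 60) range.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= _TEMP_RANGE[0]) or np.any(t >= _TEMP_RANGE[1]):
        raise ValueError(
            f"air temperature outside plausible range {_TEMP_RANGE}: "
            f"{t[(t <= _TEMP_RANGE[0]) | (t >= _TEMP_RANGE[1])]}"
        )
    out = 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return out if out.ndim else float(out)


def compute_vpd(air_temp, rh, *, clamp_supersaturation: bool = True):
    """Vapour pressure deficit (kPa) from air temperature (C) and RH (%).

    ``vpd = es(T) * (1 - rh/100)``; exactly zero at saturation.  Records
    with ``rh > 100`` (sensor supersaturation) are clamped to 100 with a
    logged warning so humid nights are kept; negative RH is rejected.
    """
    t = np.asarray(air_temp, dtype=float)
    h = np.asarray(rh, dtype=float)
    if np.any(h < 0):
        raise ValueError(f"relative humidity < 0%: {h[h < 0]}")
    if np.any(h > 100):
        if not clamp_supersaturation:
            raise ValueError(f"relative humidity > 100%: {h[h > 100]}")
        n_bad = int(np.count_nonzero(h > 100))
        logger.warning("clamping %d supersaturated RH record(s) to 100%%", n_bad)
        h = np.minimum(h, 100.0)
    out = saturation_vapour_pressure(t) * (1.0 - h / 100.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def make_climate_series(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw climate table and append the ``vpd_kpa`` column.

    Requires strictly increasing timestamps; sampling gaps longer than 30
    minutes are permitted but counted and logged.  Rows with RH outside
    [0, 100] after supersaturation clamping are dropped with a logged reason.
    """
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    if not out["timestamp"].is_monotonic_increasing or out["timestamp"].duplicated().any():
        raise ValueError("climate timestamps must be strictly increasing")
    bad = out["rh_pct"] < 0
    if bad.any():
        logger.warning("dropping %d record(s) with negative RH", int(bad.sum()))
        out = out.loc[~bad].reset_index(drop=True)
    dt = out["timestamp"].diff().dt.total_seconds() / 60.0
    n_gaps = int((dt > _MAX_GAP_MINUTES).sum())
    if n_gaps:
        logger.info("climate series has %d gap(s) longer than 30 min", n_gaps)
    out["vpd_kpa"] = compute_vpd(out["temp_c"].to_numpy(), out["rh_pct"].to_numpy())
    return out


def load_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(CLIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing column(s): {sorted(missing)}")
    return make_climate_series(df)


def load_width_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(WIDTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"width CSV missing column(s): {sorted(missing)}")
    for pid, grp in df.groupby("plant_id"):
        if not grp["timestamp"].is_monotonic_increasing or grp["timestamp"].duplicated().any():
            raise ValueError(f"width timestamps not strictly increasing for {pid!r}")
    return df


def fit_width_calibration(obs: pd.DataFrame) -> CalibrationModel:
    """OLS line ``psi = slope * width + intercept`` for one plant.

    ``obs`` needs columns ``plant_id``, ``width_um``, ``psi_bomb_mpa``.
    Degenerate input (fewer than two points, several plants, or constant
    width) raises :class:`CalibrationError`.
    """
    plants = obs["plant_id"].unique()
    if len(plants) != 1:
        raise CalibrationError(
            f"calibration is per-plant; got plant_ids {sorted(map(str, plants))}"
        )
    w = obs["width_um"].to_numpy(dtype=float)
    psi = obs["psi_bomb_mpa"].to_numpy(dtype=float)
    if np.any(psi > 0):
        raise CalibrationError("pressure-chamber potentials must be <= 0 MPa")
    if len(w) < 2:
        raise CalibrationError("calibration requires >= 2 paired observations")
    if np.ptp(w) == 0:
        raise CalibrationError("degenerate calibration: width range is zero")
    fit = stats.linregress(w, psi)
    # linregress leaves rvalue nan for zero-variance psi; a flat line is valid
    r2 = 1.0 if np.ptp(psi) == 0 else float(fit.rvalue**2)
    return CalibrationModel(
        plant_id=str(plants[0]),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_points=len(w),
    )


def apply_calibration(widths: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Map a width series through a calibration line to stem potential.

    Returns columns ``timestamp, plant_id, psi_stem_mpa, clipped``; positive
    potentials (sensor drift above the zero bound) are clipped to 0 and
    flagged.  The series and model must refer to the same plant.
    """
    plants = set(map(str, widths["plant_id"].unique()))
    if plants and plants != {model.plant_id}:
        raise ValueError(
            f"plant mismatch: series has {sorted(plants)}, model is {model.plant_id!r}"
        )
    psi = model.predict(widths["width_um"].to_numpy()) if len(widths) else np.array([])
    clipped = psi > 0
    if clipped.any():
        logger.warning(
            "%s: clipped %d positive potential(s) to 0 MPa (sensor drift)",
            model.plant_id,
            int(clipped.sum()),
        )
    return pd.DataFrame(
        {
            "timestamp": widths["timestamp"].to_numpy(),
            "plant_id": widths["plant_id"].to_numpy() if len(widths) else [],
            "psi_stem_mpa": np.minimum(psi, 0.0),
            "clipped": clipped,
        }
    )
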