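"""From diurnal stem-potential series to one steady-state record per tree-day.

The unit of observation downstream is a daily maximum soil-to-stem water
potential gradient: the difference between the interpolated daytime soil
water potential and the steady-state daytime minimum stem potential
(a 2-h window mean around the daytime minimum that stays within a 5%
relative band for at least an hour).  Soil water potential is tracked per
plant by linear interpolation between predawn stem-potential anchors taken
on humid nights (VPD below 0.05 kPa from midnight to sunrise), when
nocturnal transpiration is negligible and the stem equilibrates with the
rooting zone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "SteadyStateWindow",
    "sunrise_sunset",
    "find_steady_state_min",
    "select_predawn_anchors",
    "interpolate_soil_psi",
    "build_daily_records",
    "diurnal_window_slice",
    "write_records_csv",
    "read_records_csv",
]

#: site coordinates of the reference study (southeastern Tasmania)
DEFAULT_LATITUDE = -43.051
DEFAULT_LONGITUDE = 147.104


@dataclass
class ExtractionConfig:
    """Tunable thresholds; defaults follow the reference protocol."""

    latitude: float = DEFAULT_LATITUDE
    longitude: float = DEFAULT_LONGITUDE
    steady_tolerance: float = 0.05  # relative band for the plateau test
    min_hold_hours: float = 1.0  # plateau must persist at least this long
    window_hours: float = 2.0  # averaging window around the daytime minimum
    night_vpd_threshold: float = 0.05  # kPa; humid-night selection rule
    diurnal_window: tuple[float, float] = (11.0, 15.0)  # hours, civil time
    season_offset_days: int = 184  # shift so austral seasons don't split at Jan 1
    max_anchor_gap_days: float = 21.0  # longer gaps are flagged
    daytime_override: tuple[float, float] | None = None  # (sunrise, sunset) hours


@dataclass(frozen=True)
class SteadyStateWindow:
    start: datetime
    end: datetime
    mean_psi: float
    n_points: int

    @property
    def midpoint(self) -> datetime:
        return self.start + (self.end - self.start) / 2


def _solar_declination(day_of_year: int) -> float:
    return math.radians(23.45) * math.sin(2 * math.pi * (284 + day_of_year) / 365.0)


def sunrise_sunset(day: _date, latitude: float = DEFAULT_LATITUDE) -> tuple[float, float]:
    """Sunrise and sunset as fractional hours of local civil time.

    Standard solar-geometry approximation with solar noon taken at 12:00
    local; adequate for daytime/night classification at mid-latitudes.
    """
    decl = _solar_declination(day.timetuple().tm_yday)
    lat = math.radians(latitude)
    cos_omega = -math.tan(lat) * math.tan(decl)
    cos_omega = min(1.0, max(-1.0, cos_omega))
    half_day = math.degrees(math.acos(cos_omega)) / 15.0
    return 12.0 - half_day, 12.0 + half_day


def _daytime_bounds(day: _date, cfg: ExtractionConfig) -> tuple[datetime, datetime]:
    if cfg.daytime_override is not None:
        rise, set_ = cfg.daytime_override
    else:
        rise, set_ = sunrise_sunset(day, cfg.latitude)
    base = datetime.combine(day, datetime.min.time())
    return base + timedelta(hours=rise), base + timedelta(hours=set_)


def find_steady_state_min(
    day_psi: pd.DataFrame,
    daytime: tuple[datetime, datetime],
    cfg: ExtractionConfig | None = None,
) -> SteadyStateWindow | None:
    """Minimum-mean 2-h window at the steady daytime minimum, if any.

    Among rolling ``window_hours`` windows of daytime points that contain
    the (earliest) pointwise daytime minimum, takes the one with the most
    negative mean, then accepts the day only if some contiguous stretch of
    at least ``min_hold_hours`` containing the minimum varies by less than
    ``steady_tolerance`` relative to the window mean.  Returns ``None``
    (day excluded) when no qualifying window exists or daytime data are too
    sparse.
    """
    cfg = cfg or ExtractionConfig()
    ts = pd.to_datetime(day_psi["timestamp"])
    mask = (ts >= daytime[0]) & (ts <= daytime[1])
    sub = day_psi.loc[mask.to_numpy()]
    if len(sub) < 4:
        logger.info("steady-state scan: only %d daytime point(s); day excluded", len(sub))
        return None
    t = pd.to_datetime(sub["timestamp"]).to_numpy()
    psi = sub["psi_stem_mpa"].to_numpy(dtype=float)
    n = len(t)

    i_min = int(np.argmin(psi))  # argmin returns the first (earliest) minimum
    width = np.timedelta64(int(cfg.window_hours * 3600), "s")
    hold = np.timedelta64(int(cfg.min_hold_hours * 3600), "s")

    best: tuple[float, int, int] | None = None  # (mean, a, b) inclusive bounds
    for a in range(0, i_min + 1):
        b = int(np.searchsorted(t, t[a] + width, side="left")) - 1
        if b < i_min:
            continue
        if b - a + 1 < 4 or t[b] - t[a] < hold:
            continue
        m = float(psi[a : b + 1].mean())
        if best is None or m < best[0]:
            best = (m, a, b)
    if best is None:
        return None
    wmean, a, b = best
    wpsi = psi[a : b + 1]
    denom = abs(wmean)
    j_min = i_min - a

    for lo in range(0, j_min + 1):
        for hi in range(j_min, b - a + 1):
            if t[a + hi] - t[a + lo] < hold:
                continue
            seg = wpsi[lo : hi + 1]
            spread = float(seg.max() - seg.min())
            ok = spread == 0.0 if denom == 0 else spread / denom < cfg.steady_tolerance
            if ok:
                return SteadyStateWindow(
                    start=pd.Timestamp(t[a]).to_pydatetime(),
                    end=pd.Timestamp(t[b]).to_pydatetime(),
                    mean_psi=wmean,
                    n_points=b - a + 1,
                )
    return None


def select_predawn_anchors(
    psi: pd.DataFrame,
    climate: pd.DataFrame,
    cfg: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Predawn soil-potential anchors from humid-night equilibrium.

    A night qualifies when every VPD record between midnight and sunrise is
    below ``night_vpd_threshold``.  The anchor is the mean stem potential
    over the 2-h window around the pre-sunrise maximum.  Returns a frame
    with ``plant_id, date, anchor_time, psi_predawn, night_max_vpd``; raises
    if no night qualifies (the soil track cannot be built).
    """
    cfg = cfg or ExtractionConfig()
    climate = climate.copy()
    climate["timestamp"] = pd.to_datetime(climate["timestamp"])
    rows = []
    for pid, grp in psi.groupby("plant_id"):
        ts = pd.to_datetime(grp["timestamp"])
        for day in sorted(ts.dt.date.unique()):
            night_start = datetime.combine(day, datetime.min.time())
            sunrise_dt, _ = _daytime_bounds(day, cfg)
            cmask = (climate["timestamp"] >= night_start) & (climate["timestamp"] < sunrise_dt)
            night_vpd = climate.loc[cmask, "vpd_kpa"]
            if night_vpd.empty:
                continue
            vmax = float(night_vpd.max())
            if vmax >= cfg.night_vpd_threshold:
                continue
            pmask = (ts >= night_start) & (ts < sunrise_dt)
            night_psi = grp.loc[pmask.to_numpy()]
            if night_psi.empty:
                continue
            t = pd.to_datetime(night_psi["timestamp"]).to_numpy()
            p = night_psi["psi_stem_mpa"].to_numpy(dtype=float)
            i_max = int(np.argmax(p))
            half = np.timedelta64(int(cfg.window_hours * 1800), "s")
            in_win = (t >= t[i_max] - half) & (t <= t[i_max] + half)
            rows.append(
                {
                    "plant_id": pid,
                    "date": day,
                    "anchor_time": pd.Timestamp(
                        t[in_win].astype("datetime64[ns]").astype("int64").mean()
                    ),
                    "psi_predawn": float(p[in_win].mean()),
                    "night_max_vpd": vmax,
                }
            )
    if not rows:
        raise ValueError(
            "no night satisfied the humid-night rule "
            f"(VPD < {cfg.night_vpd_threshold} kPa all night); "
            "soil water potential cannot be tracked"
        )
    return pd.DataFrame(rows)


def interpolate_soil_psi(
    anchors: pd.DataFrame,
    times,
    max_gap_days: float = 21.0,
) -> pd.DataFrame:
    """Piecewise-linear soil-potential track through predawn anchors.

    Exact at anchor times; queries outside the anchor span are dropped with
    a logged count (no extrapolation).  Gaps between consecutive anchors
    longer than ``max_gap_days`` are flagged in the log.
    """
    if len(anchors) < 2:
        raise ValueError("need >= 2 predawn anchors to interpolate a soil track")
    anchors = anchors.sort_values("anchor_time")
    at = pd.to_datetime(anchors["anchor_time"]).to_numpy().astype("datetime64[ns]")
    av = anchors["psi_predawn"].to_numpy(dtype=float)
    gaps = np.diff(at).astype("timedelta64[s]").astype(float) / 86400.0
    n_long = int((gaps > max_gap_days).sum())
    if n_long:
        logger.warning(
            "%d anchor gap(s) exceed %.0f d; interpolation may be unreliable there",
            n_long,
            max_gap_days,
        )
    t = pd.to_datetime(pd.Series(times)).to_numpy().astype("datetime64[ns]")
    inside = (t >= at[0]) & (t <= at[-1])
    if (~inside).any():
        logger.info(
            "dropping %d quer(ies) outside the anchor span", int((~inside).sum())
        )
    tf = t[inside].astype("int64").astype(float)
    af = at.astype("int64").astype(float)
    vals = np.interp(tf, af, av)
    return pd.DataFrame({"timestamp": t[inside], "psi_soil_mpa": vals})


def _season_label(pid, day: _date, offset_days: int) -> str:
    season_year = (pd.Timestamp(day) + pd.Timedelta(days=offset_days)).year
    return f"{pid}:{season_year}"


def build_daily_records(
    psi: pd.DataFrame,
    anchors: pd.DataFrame,
    climate: pd.DataFrame,
    cfg: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble one steady-state daily-maximum record per tree-day.

    Returns ``(records, exclusions)`` where records has columns
    ``plant_id, date, season_label, delta_psi_max, vpd_max_day,
    psi_soil_day, window_mean_vpd`` and exclusions counts dropped days by
    reason (``no_steady_state``, ``negative_delta``, ``missing_soil``,
    ``missing_climate``).  The gradient is the interpolated soil potential
    at the steady-state window midpoint minus the window-mean stem
    potential; days where it comes out negative are excluded.
    """
    cfg = cfg or ExtractionConfig()
    climate = climate.copy()
    climate["timestamp"] = pd.to_datetime(climate["timestamp"])
    records: list[dict] = []
    excl = {
        "no_steady_state": 0,
        "negative_delta": 0,
        "missing_soil": 0,
        "missing_climate": 0,
    }
    for pid, grp in psi.groupby("plant_id"):
        plant_anchors = anchors[anchors["plant_id"] == pid]
        if len(plant_anchors) < 2:
            logger.warning("plant %s: < 2 anchors, all days dropped", pid)
            excl["missing_soil"] += len(pd.to_datetime(grp["timestamp"]).dt.date.unique())
            continue
        ts = pd.to_datetime(grp["timestamp"])
        for day in sorted(ts.dt.date.unique()):
            daytime = _daytime_bounds(day, cfg)
            day_mask = (ts >= daytime[0] - timedelta(hours=12)) & (
                ts <= daytime[1] + timedelta(hours=12)
            )
            win = find_steady_state_min(grp.loc[day_mask.to_numpy()], daytime, cfg)
            if win is None:
                excl["no_steady_state"] += 1
                continue
            cmask = (climate["timestamp"] >= daytime[0]) & (
                climate["timestamp"] <= daytime[1]
            )
            day_climate = climate.loc[cmask]
            if day_climate.empty:
                excl["missing_climate"] += 1
                continue
            soil = interpolate_soil_psi(
                plant_anchors, [win.midpoint], max_gap_days=cfg.max_anchor_gap_days
            )
            if soil.empty:
                excl["missing_soil"] += 1
                continue
            psi_soil_day = float(soil["psi_soil_mpa"].iloc[0])
            delta = psi_soil_day - win.mean_psi
            if delta < 0:
                excl["negative_delta"] += 1
                continue
            wmask = (day_climate["timestamp"] >= win.start) & (
                day_climate["timestamp"] <= win.end
            )
            records.append(
                {
                    "plant_id": pid,
                    "date": day,
                    "season_label": _season_label(pid, day, cfg.season_offset_days),
                    "delta_psi_max": delta,
                    "vpd_max_day": float(day_climate["vpd_kpa"].max()),
                    "psi_soil_day": psi_soil_day,
                    "window_mean_vpd": float(day_climate.loc[wmask, "vpd_kpa"].mean())
                    if wmask.any()
                    else np.nan,
                }
            )
    for reason, count in excl.items():
        if count:
            logger.info("excluded %d day(s): %s", count, reason)
    return pd.DataFrame(records), excl


def diurnal_window_slice(
    psi: pd.DataFrame,
    climate: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
    window: tuple[float, float] = (11.0, 15.0),
    join_tolerance_min: float = 10.0,
) -> pd.DataFrame:
    """Time-aligned (stem potential, VPD[, soil potential]) diurnal points.

    Restricts both series to the daily clock window, joins them at the
    nearest timestamp within ``join_tolerance_min`` minutes, and (when
    anchors are given) adds the interpolated soil potential and the
    resulting instantaneous gradient.  Exploratory output; no steady-state
    requirement.
    """
    psi = psi.copy()
    psi["timestamp"] = pd.to_datetime(psi["timestamp"])
    climate = climate.copy()
    climate["timestamp"] = pd.to_datetime(climate["timestamp"])

    def _in_window(ts: pd.Series) -> pd.Series:
        hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
        return (hours >= window[0]) & (hours <= window[1])

    psi = psi.loc[_in_window(psi["timestamp"])]
    climate = climate.loc[_in_window(climate["timestamp"]), ["timestamp", "vpd_kpa"]]
    if psi.empty or climate.empty:
        return pd.DataFrame(
            columns=["timestamp", "plant_id", "psi_stem_mpa", "vpd_kpa", "psi_soil_mpa", "delta_psi"]
        )
    out = []
    for pid, grp in psi.groupby("plant_id"):
        joined = pd.merge_asof(
            grp.sort_values("timestamp"),
            climate.sort_values("timestamp"),
            on="timestamp",
            direction="nearest",
            tolerance=pd.Timedelta(minutes=join_tolerance_min),
        ).dropna(subset=["vpd_kpa"])
        if anchors is not None:
            plant_anchors = anchors[anchors["plant_id"] == pid]
            if len(plant_anchors) >= 2:
                soil = interpolate_soil_psi(plant_anchors, joined["timestamp"])
                joined = joined.merge(soil, on="timestamp", how="inner")
                joined["delta_psi"] = joined["psi_soil_mpa"] - joined["psi_stem_mpa"]
        out.append(joined)
    return pd.concat(out, ignore_index=True)


_CSV_RENAME = {
    "delta_psi_max": "delta_psi_max_mpa",
    "vpd_max_day": "vpd_max_kpa",
    "psi_soil_day": "psi_soil_mpa",
    "season_label": "season",
}


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.rename(columns=_CSV_RENAME).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={v: k for k, v in _CSV_RENAME.items()})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
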