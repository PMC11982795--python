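"""Synthetic studies with known parameters.

Generates complete multi-season studies — daily records straight from the
generative model, and optionally the raw 15/30-min microclimate, stem
potential and dendrometer-width series beneath them — so the whole pipeline
(calibration, extraction, inference) is testable by parameter recovery
without any external data.

Each plant-season occupies its own austral-summer block starting on 1
December of consecutive years, so plant-year season labels are unambiguous
and the solar geometry at the default site gives long daylight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .extraction import ExtractionConfig, _daytime_bounds, _season_label
from .microclimate import CalibrationModel, saturation_vapour_pressure
from .model import PopulationParams, RandomEffectSpec, mean_delta_psi

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_climate_and_soil",
           "simulate_daily_records", "simulate_raw_series"]

#: generator defaults: changepoint parameters at the reference study's
#: posterior means; theta0/lambda0/sigma chosen to give a ~1.94 kPa
#: 95%-saturation VPD and realistic gradient magnitudes.
DEFAULT_TRUTH = PopulationParams(
    theta0=1.2,
    lambda0=1.5,
    alpha=0.29,
    beta=-0.22,
    psi_threshold=-0.83,
    sigma=0.08,
)


@dataclass
class SimulationConfig:
    n_plants: int = 4
    seasons_per_plant: tuple[int, ...] = (3, 2, 1, 1)
    days_per_season: int = 85
    params: PopulationParams = field(default_factory=lambda: DEFAULT_TRUTH)
    sd_log_theta0: float = 0.12
    sd_log_lambda0: float = 0.12
    correlation: float = 0.3
    vpd_max_range: tuple[float, float] = (0.34, 4.09)  # kPa, daily daytime max
    temp_range: tuple[float, float] = (10.0, 32.0)  # C, mean daytime
    psi_soil_min: float = -3.6  # MPa, driest allowed seasonal target
    psi_soil_wet_min: float = -1.2  # MPa, wettest allowed seasonal target
    rain_rate_per_day: float = 0.04  # Poisson recharge events
    drydown_rate: float = 0.04  # per-day relaxation toward the seasonal target
    humid_night_prob: float = 0.8  # fraction of nights meeting the anchor rule
    raw_noise_sd: float = 0.0  # MPa, optional white noise on the raw stem signal
    cadence_min: int = 15
    start_year: int = 2021
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.seasons_per_plant) != self.n_plants:
            raise ValueError("seasons_per_plant must have n_plants entries")
        if not (0 > self.psi_soil_wet_min >= self.psi_soil_min >= -3.6 - 1e-9):
            raise ValueError("seasonal soil targets must lie within [-3.6, 0) MPa")
        lo, hi = self.vpd_max_range
        if not (0.34 - 1e-9 <= lo < hi <= 4.09 + 1e-9):
            raise ValueError("vpd_max_range must stay within [0.34, 4.09] kPa")


@dataclass
class SimulatedStudy:
    """A synthetic study together with its generating truth."""

    records: pd.DataFrame  # observation table (same schema as extraction output)
    latent: pd.DataFrame  # per-day true mean gradient
    level_params: dict[str, tuple[float, float]]  # true (theta0, lambda0) per level
    random_effects: RandomEffectSpec
    params: PopulationParams
    climate: pd.DataFrame | None = None
    psi_stem: pd.DataFrame | None = None
    widths: pd.DataFrame | None = None
    calibration_obs: pd.DataFrame | None = None
    calibrations: dict[str, CalibrationModel] = field(default_factory=dict)
    soil_tracks: dict[str, pd.DataFrame] = field(default_factory=dict)


def _plant_ids(cfg: SimulationConfig) -> list[str]:
    return [f"tree{i + 1}" for i in range(cfg.n_plants)]


def _season_blocks(cfg: SimulationConfig) -> list[tuple[str, _date]]:
    """(plant_id, season start date) with one austral summer per season."""
    blocks = []
    year = cfg.start_year
    for pid, n_seasons in zip(_plant_ids(cfg), cfg.seasons_per_plant):
        for _ in range(n_seasons):
            blocks.append((pid, _date(year, 12, 1)))
            year += 1
    return blocks


def _draw_offsets(rng: np.random.Generator, cfg: SimulationConfig, levels) -> dict:
    cov = RandomEffectSpec(
        sd_log_theta0=cfg.sd_log_theta0,
        sd_log_lambda0=cfg.sd_log_lambda0,
        correlation=cfg.correlation,
    ).covariance
    draws = rng.multivariate_normal(np.zeros(2), cov, size=len(levels))
    return {lvl: draws[i] for i, lvl in enumerate(levels)}


def _simulate_season_daily(rng: np.random.Generator, cfg: SimulationConfig):
    """Daily forcing for one season: max VPD, daytime temperature, soil
    potential at each midnight (length days+1), humid-night flags."""
    days = cfg.days_per_season
    lo, hi = cfg.vpd_max_range
    season_phase = np.sin(np.pi * (np.arange(days) + 1) / days)  # peak mid-season
    vpd_max = np.exp(rng.normal(np.log(1.1), 0.55, size=days)) * (0.7 + 0.6 * season_phase)
    vpd_max = np.clip(vpd_max, lo, hi)
    temp_day = np.clip(
        21.0 + 8.0 * season_phase + rng.normal(0.0, 3.0, size=days),
        cfg.temp_range[0],
        cfg.temp_range[1],
    )
    target = rng.uniform(cfg.psi_soil_min, cfg.psi_soil_wet_min)
    psi_mid = np.empty(days + 1)
    psi_mid[0] = rng.uniform(-0.15, -0.02)
    for d in range(days):
        if rng.random() < cfg.rain_rate_per_day:
            # recharge most of the way back toward saturation
            psi_mid[d + 1] = min(psi_mid[d] * 0.25, -0.02)
        else:
            decay = np.exp(-cfg.drydown_rate)
            psi_mid[d + 1] = target + (psi_mid[d] - target) * decay
    humid = rng.random(days + 1) < cfg.humid_night_prob
    return vpd_max, temp_day, psi_mid, humid


def simulate_climate_and_soil(cfg: SimulationConfig):
    """Per-plant daily climate forcing and soil-potential track.

    Returns ``{plant_id: (climate, soil)}`` where climate has one row per
    monitored day (``date, vpd_max_kpa, temp_day_c, humid_night``) and soil
    one row per midnight (``timestamp, psi_soil_mpa``).  With a zero rain
    rate each track is monotone non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for pid, start in _season_blocks(cfg):
        vpd_max, temp_day, psi_mid, humid = _simulate_season_daily(rng, cfg)
        dates = [start + timedelta(days=d) for d in range(cfg.days_per_season)]
        clim = pd.DataFrame(
            {
                "date": dates,
                "vpd_max_kpa": vpd_max,
                "temp_day_c": temp_day,
                "humid_night": humid[: cfg.days_per_season],
            }
        )
        soil = pd.DataFrame(
            {
                "timestamp": [
                    datetime.combine(start + timedelta(days=d), datetime.min.time())
                    for d in range(cfg.days_per_season + 1)
                ],
                "psi_soil_mpa": psi_mid,
            }
        )
        if pid in out:
            clim = pd.concat([out[pid][0], clim], ignore_index=True)
            soil = pd.concat([out[pid][1], soil], ignore_index=True)
        out[pid] = (clim, soil)
    if not any(c["humid_night"].any() for c, _ in out.values()):
        raise ValueError("configuration produced no humid nights; no soil anchors possible")
    return out


def simulate_daily_records(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw a study straight at the daily-record level.

    Correlated log-scale offsets per plant-year level, then one record per
    day from the mean surface at (daily max VPD, midday soil potential) plus
    Gaussian residual noise.
    """
    rng = np.random.default_rng(cfg.seed)
    env_rng = np.random.default_rng(rng.integers(2**63))
    p = cfg.params
    rows, latent_rows = [], []
    blocks = _season_blocks(cfg)
    levels = [_season_label(pid, start + timedelta(days=40), 184) for pid, start in blocks]
    offsets = _draw_offsets(rng, cfg, levels)
    for (pid, start), level in zip(blocks, levels):
        vpd_max, _temp, psi_mid, _humid = _simulate_season_daily(env_rng, cfg)
        off = offsets[level]
        level_p = replace(p, theta0=p.theta0 * np.exp(off[0]), lambda0=p.lambda0 * np.exp(off[1]))
        for d in range(cfg.days_per_season):
            day = start + timedelta(days=d)
            psi_soil = 0.5 * (psi_mid[d] + psi_mid[d + 1])  # midday value
            mu = mean_delta_psi(vpd_max[d], psi_soil, level_p)
            obs = mu + rng.normal(0.0, p.sigma)
            rows.append(
                {
                    "plant_id": pid,
                    "date": day,
                    "season_label": level,
                    "delta_psi_max": obs,
                    "vpd_max_day": vpd_max[d],
                    "psi_soil_day": psi_soil,
                }
            )
            latent_rows.append(
                {"plant_id": pid, "date": day, "season_label": level, "mu_true": mu}
            )
    re = RandomEffectSpec(
        sd_log_theta0=cfg.sd_log_theta0,
        sd_log_lambda0=cfg.sd_log_lambda0,
        correlation=cfg.correlation,
        offsets=offsets,
    )
    level_params = {
        lvl: (p.theta0 * float(np.exp(o[0])), p.lambda0 * float(np.exp(o[1])))
        for lvl, o in offsets.items()
    }
    return SimulatedStudy(
        records=pd.DataFrame(rows),
        latent=pd.DataFrame(latent_rows),
        level_params=level_params,
        random_effects=re,
        params=p,
    )


def _diurnal_vpd_profile(hours, sunrise, sunset, vpd_max, humid_night, threshold=0.05):
    """Broad-domed diurnal VPD: zero (humid) or small nonzero VPD at night
    and a sine raised to a small power during the day, so the midday maximum
    is nearly flat for a couple of hours and the stem-potential minimum
    satisfies the steady-state plateau rule."""
    shape = np.zeros_like(hours)
    day = (hours >= sunrise) & (hours <= sunset)
    phase = (hours[day] - sunrise) / (sunset - sunrise)
    shape[day] = np.sin(np.pi * phase) ** 0.3
    vpd = vpd_max * shape
    if humid_night:
        vpd[~day] = 0.0
    else:
        night_level = max(threshold * 1.5, 0.08 * vpd_max)
        vpd[~day] = night_level
        vpd[day] = np.maximum(vpd[day], night_level)
    return vpd


def simulate_raw_series(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the study down to raw 15/30-min series.

    Stem potential instantaneously tracks the mean-response surface driven
    by a flat-topped diurnal VPD curve (guaranteeing a >= 1 h steady-state
    plateau at the daytime minimum), equals the soil potential on humid
    (zero-VPD) nights, and is emitted as a dendrometer width series through
    a known per-plant calibration line.  By default the raw signal is
    noise-free (residual noise enters only at the daily-record level of the
    returned truth table), so extraction round-trips are exact up to
    interpolation error; ``raw_noise_sd`` adds optional white noise for
    realistic end-to-end fits.
    """
    rng = np.random.default_rng(cfg.seed)
    env_rng = np.random.default_rng(rng.integers(2**63))
    p = cfg.params
    blocks = _season_blocks(cfg)
    levels = [_season_label(pid, start + timedelta(days=40), 184) for pid, start in blocks]
    offsets = _draw_offsets(rng, cfg, levels)
    calibrations = {
        pid: CalibrationModel(
            plant_id=pid,
            slope=0.005,
            intercept=-10.0 - 0.5 * i,
            r_squared=1.0,
            n_points=2,
        )
        for i, pid in enumerate(_plant_ids(cfg))
    }
    step = timedelta(minutes=cfg.cadence_min)
    per_day = int(round(24 * 60 / cfg.cadence_min))
    ecfg = ExtractionConfig()

    clim_rows, psi_frames, width_frames, calib_rows = [], [], [], []
    rec_rows, latent_rows = [], []
    soil_tracks: dict[str, list[pd.DataFrame]] = {}

    for (pid, start), level in zip(blocks, levels):
        vpd_max, temp_day, psi_mid, humid = _simulate_season_daily(env_rng, cfg)
        off = offsets[level]
        level_p = replace(
            p, theta0=p.theta0 * np.exp(off[0]), lambda0=p.lambda0 * np.exp(off[1])
        )
        season_ts, season_vpd, season_temp, season_psi_soil = [], [], [], []
        for d in range(cfg.days_per_season):
            day = start + timedelta(days=d)
            base = datetime.combine(day, datetime.min.time())
            rise_dt, set_dt = _daytime_bounds(day, ecfg)
            rise = (rise_dt - base).total_seconds() / 3600.0
            sset = (set_dt - base).total_seconds() / 3600.0
            hours = np.arange(per_day) * (cfg.cadence_min / 60.0)
            vpd = _diurnal_vpd_profile(
                hours, rise, sset, vpd_max[d], humid[d], ecfg.night_vpd_threshold
            )
            temp_t = temp_day[d] + 4.0 * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
            # keep VPD below saturation so the RH inversion round-trips
            vpd = np.minimum(vpd, 0.98 * saturation_vapour_pressure(temp_t))
            # soil potential is piecewise linear with kinks at the predawn
            # hour (03:00), so nightly anchors sample it on linear segments
            frac = (hours - 3.0) / 24.0
            prev = psi_mid[d - 1] if d > 0 else psi_mid[0] - (psi_mid[1] - psi_mid[0])
            early = hours < 3.0
            psi_soil_t = np.where(
                early,
                psi_mid[d] + frac * (psi_mid[d] - prev),
                psi_mid[d] + frac * (psi_mid[d + 1] - psi_mid[d]),
            )
            season_ts.extend(base + i * step for i in range(per_day))
            season_vpd.append(vpd)
            season_temp.append(temp_t)
            season_psi_soil.append(psi_soil_t)

            psi_soil_midday = psi_mid[d] + 10.0 / 24.0 * (psi_mid[d + 1] - psi_mid[d])
            vmax_day = float(vpd[(hours >= rise) & (hours <= sset)].max())
            mu = mean_delta_psi(vmax_day, psi_soil_midday, level_p)
            rec_rows.append(
                {
                    "plant_id": pid,
                    "date": day,
                    "season_label": level,
                    "delta_psi_max": mu + rng.normal(0.0, p.sigma),
                    "vpd_max_day": vmax_day,
                    "psi_soil_day": psi_soil_midday,
                }
            )
            latent_rows.append(
                {"plant_id": pid, "date": day, "season_label": level, "mu_true": mu}
            )

        vpd_all = np.concatenate(season_vpd)
        temp_all = np.concatenate(season_temp)
        soil_all = np.concatenate(season_psi_soil)
        psi_stem = soil_all - mean_delta_psi(vpd_all, soil_all, level_p)
        if cfg.raw_noise_sd > 0:
            psi_stem = psi_stem + rng.normal(0.0, cfg.raw_noise_sd, psi_stem.shape)
        # invert VPD to RH against the Buck curve so loaders reproduce it
        rh = np.clip(100.0 * (1.0 - vpd_all / saturation_vapour_pressure(temp_all)), 0, 100)
        clim_rows.append(
            pd.DataFrame(
                {"timestamp": season_ts, "temp_c": temp_all, "rh_pct": rh, "vpd_kpa": vpd_all}
            )
        )
        psi_frames.append(
            pd.DataFrame(
                {"timestamp": season_ts, "plant_id": pid, "psi_stem_mpa": psi_stem}
            )
        )
        width_frames.append(
            pd.DataFrame(
                {
                    "timestamp": season_ts,
                    "plant_id": pid,
                    "width_um": calibrations[pid].invert(psi_stem),
                }
            )
        )
        soil_tracks.setdefault(pid, []).append(
            pd.DataFrame({"timestamp": season_ts, "psi_soil_mpa": soil_all})
        )
        # fortnightly pressure-chamber points for calibration refits
        for d in range(7, cfg.days_per_season, 14):
            ts = datetime.combine(start + timedelta(days=d), datetime.min.time()) + timedelta(hours=13)
            idx = season_ts.index(ts)
            calib_rows.append(
                {
                    "plant_id": pid,
                    "timestamp": ts,
                    "psi_bomb_mpa": psi_stem[idx],
                    "width_um": calibrations[pid].invert(psi_stem[idx]),
                }
            )

    climate = (
        pd.concat(clim_rows, ignore_index=True)
        .drop_duplicates(subset="timestamp")
        .sort_values("timestamp")
        .reset_index(drop=True)
    )
    re = RandomEffectSpec(
        sd_log_theta0=cfg.sd_log_theta0,
        sd_log_lambda0=cfg.sd_log_lambda0,
        correlation=cfg.correlation,
        offsets=offsets,
    )
    return SimulatedStudy(
        records=pd.DataFrame(rec_rows),
        latent=pd.DataFrame(latent_rows),
        level_params={
            lvl: (p.theta0 * float(np.exp(o[0])), p.lambda0 * float(np.exp(o[1])))
            for lvl, o in offsets.items()
        },
        random_effects=re,
        params=p,
        climate=climate,
        psi_stem=pd.concat(psi_frames, ignore_index=True),
        widths=pd.concat(width_frames, ignore_index=True),
        calibration_obs=pd.DataFrame(calib_rows),
        calibrations=calibrations,
        soil_tracks={pid: pd.concat(fr, ignore_index=True) for pid, fr in soil_tracks.items()},
    )
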