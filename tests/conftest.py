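import numpy as np
import pandas as pd
import pytest

from psireg.inference import FitConfig, fit_posterior
from psireg.simulate import SimulationConfig, simulate_daily_records, simulate_raw_series


@pytest.fixture(scope="session")
def daily_study():
    """Full-size synthetic study at the daily-record level (~600 records)."""
    return simulate_daily_records(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def raw_study():
    """Small raw-signal study: 2 plants, one 30-day season each."""
    return simulate_raw_series(
        SimulationConfig(n_plants=2, seasons_per_plant=(1, 1), days_per_season=30, seed=3)
    )


@pytest.fixture(scope="session")
def clean_raw_study():
    """Raw study under the extraction idealization: every night humid
    (nightly anchors) and no recharge events."""
    return simulate_raw_series(
        SimulationConfig(
            n_plants=2,
            seasons_per_plant=(1, 1),
            days_per_season=30,
            seed=5,
            humid_night_prob=1.0,
            rain_rate_per_day=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_fit():
    """One compact but real NUTS fit shared across diagnostic tests."""
    cfg = SimulationConfig(
        n_plants=3, seasons_per_plant=(1, 1, 1), days_per_season=70, seed=21
    )
    study = simulate_daily_records(cfg)
    draws = fit_posterior(
        study.records, FitConfig(n_chains=2, n_iterations=700, seed=21)
    )
    return study, draws


def make_day(psi_by_hour, date="2023-01-10", plant="tree1", cadence_min=15):
    """Build a one-day stem-potential frame from (hour, value) breakpoints
    with linear interpolation at the given cadence."""
    hours = np.arange(0, 24, cadence_min / 60.0)
    pts = sorted(psi_by_hour)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    psi = np.interp(hours, xs, ys)
    ts = pd.Timestamp(date) + pd.to_timedelta(hours, unit="h")
    return pd.DataFrame({"timestamp": ts, "plant_id": plant, "psi_stem_mpa": psi})
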