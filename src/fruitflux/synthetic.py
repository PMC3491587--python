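"""Synthetic weather and weighing-campaign generators.

The generators emulate the statistical structure the analysis assumes:
diurnally cycling weather with a seasonal trend, and hourly 24-h gravimetric
weighing series for replicate fruits on a handful of campaign days, whose
weight loss follows E = G'(tau) * delta_pw with a power-law developmental
conductance decline and lognormal fruit-to-fruit variability. Every
generator is a pure function of (scenario, seed).

The campaign generator steps fruit mass hourly using the mean weather over
each hour — the same pairing rule the estimation stage uses — so noiseless
end-to-end recovery of the generating coefficients is exact and serves as
an oracle for the whole pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conductance import interval_mean_weather
from .errors import CoverageError, DomainError
from .vapour import (
    STANDARD_PRESSURE_PA,
    WATER_MOLAR_MASS,
    delta_pw,
    fruit_surface_area,
)

WEATHER_COLUMNS = ["timestamp", "T_C", "RH_pct", "W_ms", "R_kJ_m2"]
WEIGHING_COLUMNS = ["fruit_id", "timestamp", "weight_g", "length_cm", "width_cm"]
TRUTH_COLUMNS = [
    "fruit_id",
    "timestamp",
    "tau_days",
    "multiplier",
    "delta_pw",
    "G_true",
    "E_true",
]


@dataclass(frozen=True)
class WeatherScenario:
    """Parameters of the synthetic weather stream.

    Temperature is a diurnal cosine (daily maximum at ``T_peak_hour``)
    superposed on a half-sine seasonal trend peaking mid-season; relative
    humidity cycles in anti-phase with temperature; radiation follows a
    half-sine over daylight hours and is exactly zero at night.
    """

    season_start: date = date(2022, 6, 2)
    season_days: int = 150
    T_base: float = 20.0
    T_seasonal_amp: float = 6.0
    T_diurnal_amp: float = 6.0
    T_peak_hour: float = 14.0
    RH_base: float = 65.0
    RH_diurnal_amp: float = 20.0
    W_mean: float = 1.5
    R_max: float = 3000.0
    T_noise_sd: float = 0.5
    RH_noise_sd: float = 3.0
    W_noise_sd: float = 0.5
    R_noise_sd: float = 100.0
    sunrise_hour: float = 6.0
    sunset_hour: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class CampaignScenario:
    """Parameters of the synthetic hourly weighing campaigns.

    ``true_alpha``/``true_beta`` define the generating conductance law;
    the defaults are the seasonal-model coefficients used throughout the
    test suite, so recovery targets are well defined. ``fruit_cv`` is the
    standard deviation of the log of the per-fruit conductance multiplier
    (lognormal, median 1).
    """

    full_bloom: date = date(2022, 5, 23)
    campaign_days: tuple[int, ...] = (23, 35, 49, 65, 94, 140)
    fruits_per_day: int = 6
    weighing_hours: int = 24
    start_hour: int = 9
    true_alpha: float = 13400.0
    true_beta: float = -1.90
    fruit_cv: float = 0.2
    weight_noise_sd: float = 0.001
    length_cm_range: tuple[float, float] = (5.0, 6.5)
    width_cm_range: tuple[float, float] = (4.0, 5.0)
    initial_weight_g: float = 80.0
    pressure_Pa: float = STANDARD_PRESSURE_PA
    seed: int = 0


def generate_weather(
    scenario: WeatherScenario = WeatherScenario(), cadence_minutes: int = 60
) -> pd.DataFrame:
    """Generate a gap-free weather stream at the given cadence.

    Returns a DataFrame with columns timestamp, T_C, RH_pct, W_ms, R_kJ_m2.
    Deterministic given ``scenario.seed``; with all noise scales zero the
    output is independent of the seed.
    """
    if cadence_minutes not in (15, 60):
        raise DomainError("cadence_minutes must be 15 or 60")
    if scenario.season_days < 1:
        raise DomainError("season_days must be >= 1")

    s = scenario
    rng = np.random.default_rng(s.seed)
    n = s.season_days * 24 * 60 // cadence_minutes
    start = pd.Timestamp(s.season_start)
    ts = start + pd.to_timedelta(np.arange(n) * cadence_minutes, unit="m")
    hours = np.arange(n) * cadence_minutes / 60.0
    hod = hours % 24.0
    day_frac = hours / 24.0 / s.season_days

    diurnal = np.cos(2.0 * np.pi * (hod - s.T_peak_hour) / 24.0)
    T = (
        s.T_base
        + s.T_seasonal_amp * np.sin(np.pi * day_frac)
        + s.T_diurnal_amp * diurnal
        + s.T_noise_sd * rng.standard_normal(n)
    )
    RH = np.clip(
        s.RH_base
        - s.RH_diurnal_amp * diurnal
        + s.RH_noise_sd * rng.standard_normal(n),
        2.0,
        100.0,
    )
    daylight = (hod >= s.sunrise_hour) & (hod <= s.sunset_hour)
    shape = np.where(
        daylight,
        np.sin(np.pi * (hod - s.sunrise_hour) / (s.sunset_hour - s.sunrise_hour)),
        0.0,
    )
    R = np.clip(
        s.R_max * shape + s.R_noise_sd * rng.standard_normal(n) * (shape > 0), 0.0, None
    )
    W = np.abs(s.W_mean + s.W_noise_sd * rng.standard_normal(n))
    return pd.DataFrame(
        {"timestamp": ts, "T_C": T, "RH_pct": RH, "W_ms": W, "R_kJ_m2": R}
    )


def generate_campaign(
    cs: CampaignScenario,
    weather: pd.DataFrame,
    molar_mass: float = WATER_MOLAR_MASS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate weighing series plus the hidden truth table.

    For each fruit the mass trajectory is integrated hourly:
    dm = E_true * area * molar_mass / 1000 per hour, with
    E_true = true_alpha * tau^true_beta * multiplier * delta_pw(t), tau and
    the hourly-mean weather both taken at the interval start. Balance noise
    is then added to the observed weights. The truth table records the
    per-interval multiplier, delta_pw, G_true and E_true for recovery tests.

    Random draws come from one generator seeded with ``cs.seed`` and are
    consumed in (campaign day, fruit) loop order: length, width, log
    multiplier, then the weight-noise vector.
    """
    bloom = pd.Timestamp(cs.full_bloom)
    rng = np.random.default_rng(cs.seed)
    H = cs.weighing_hours

    weigh_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for d in cs.campaign_days:
        t0 = bloom + pd.Timedelta(days=d, hours=cs.start_hour)
        starts = t0 + pd.to_timedelta(np.arange(H), unit="h")
        ends = starts + pd.Timedelta(hours=1)
        met = interval_mean_weather(weather, starts, ends)
        if met["T_C"].isna().any():
            raise CoverageError(
                f"campaign day {d} AFB ({t0.date()}) not covered by weather"
            )
        dpw = np.asarray(
            delta_pw(met["T_C"].to_numpy(), met["RH_pct"].to_numpy(), cs.pressure_Pa)
        )
        tau = d + (cs.start_hour + np.arange(H)) / 24.0
        g_base = cs.true_alpha * tau**cs.true_beta

        for i in range(cs.fruits_per_day):
            fruit_id = f"d{d:03d}_f{i + 1}"
            length = rng.uniform(*cs.length_cm_range)
            width = rng.uniform(*cs.width_cm_range)
            mult = float(np.exp(rng.normal(0.0, cs.fruit_cv)))
            area = fruit_surface_area(length, width)

            G_true = g_base * mult
            E_true = G_true * dpw
            dm = E_true * area * molar_mass / 1000.0  # g lost per hour
            w = cs.initial_weight_g - np.concatenate([[0.0], np.cumsum(dm)])
            noise = rng.normal(0.0, cs.weight_noise_sd, size=H + 1)
            w_obs = w + noise

            weigh_rows.append(
                pd.DataFrame(
                    {
                        "fruit_id": fruit_id,
                        "timestamp": t0 + pd.to_timedelta(np.arange(H + 1), unit="h"),
                        "weight_g": w_obs,
                        "length_cm": length,
                        "width_cm": width,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "fruit_id": fruit_id,
                        "timestamp": starts,
                        "tau_days": tau,
                        "multiplier": mult,
                        "delta_pw": dpw,
                        "G_true": G_true,
                        "E_true": E_true,
                    }
                )
            )

    weighings = pd.concat(weigh_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    if (weighings["weight_g"] <= 0.0).any():
        raise DomainError("generated fruit weights must stay positive")
    return weighings, truth


def write_fixture(
    directory,
    weather: pd.DataFrame,
    weighings: pd.DataFrame,
    truth: pd.DataFrame,
    weather_scenario: WeatherScenario | None = None,
    campaign_scenario: CampaignScenario | None = None,
) -> dict[str, Path]:
    """Write weather.csv, weighings.csv, truth.csv and a scenario snapshot.

    Plain comma-separated UTF-8 with a header row; floats use shortest
    round-tripping representation so re-reading reproduces the streams
    bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "weather": directory / "weather.csv",
        "weighings": directory / "weighings.csv",
        "truth": directory / "truth.csv",
        "scenario": directory / "scenario.yaml",
    }
    weather.to_csv(paths["weather"], index=False)
    weighings.to_csv(paths["weighings"], index=False)
    truth.to_csv(paths["truth"], index=False)

    snapshot: dict[str, dict] = {}
    for key, scn in (
        ("weather_scenario", weather_scenario),
        ("campaign_scenario", campaign_scenario),
    ):
        if scn is not None:
            d = dataclasses.asdict(scn)
            for k, v in d.items():
                if isinstance(v, date):
                    d[k] = v.isoformat()
                elif isinstance(v, tuple):
                    d[k] = list(v)
            snapshot[key] = d
    with open(paths["scenario"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=False)
    return paths
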