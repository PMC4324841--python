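"""Surrogate daily Tmax/Tmin generator for climate-scenario replicates.

The study design needs, for every location × GCM model × emission scenario
× period cell, 20 replicate years of daily maximum/minimum temperature.
The originals come from a stochastic weather generator downscaling GCM
monthly climatologies; that tool's internal model is not public, and the
downstream degree-day analysis consumes nothing but daily Tmax/Tmin.  We
therefore emulate it with a transparent surrogate:

    T(d) = annual_mean + amplitude * cos(2*pi*(d - peak_day)/year_length)
           + scenario_delta + N(0, daily_noise_sd^2)

The cosine term sums to zero over a whole year, so the realized annual
mean equals ``annual_mean + scenario_delta`` exactly in the noise-free
limit — which is precisely the quantity the published scenario table
constrains.  Replicates share the climatology and differ only in the
noise draws, each from a child seed derived deterministically from
(seed, replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weather_io import WeatherSeries

__all__ = [
    "SCENARIOS",
    "PERIOD_YEARS",
    "LocationClimate",
    "ScenarioOffset",
    "ReplicateSet",
    "offsets_between_rows",
    "generate_weather_series",
    "generate_replicate_set",
]

#: SRES emission scenarios: high, medium, low greenhouse-gas trajectories.
SCENARIOS = ("A2", "A1B", "B1")

#: Period slices and their representative years: baseline, near future,
#: distant future, very distant future.
PERIOD_YEARS = {"BL": 1975, "NF": 2020, "DF": 2050, "VDF": 2080}

_PERIOD_BY_YEAR = {v: k for k, v in PERIOD_YEARS.items()}


def period_label(period: str | int) -> str:
    """Normalise a period given as a label ('VDF') or a year (2080)."""
    if isinstance(period, str) and period in PERIOD_YEARS:
        return period
    try:
        return _PERIOD_BY_YEAR[int(period)]
    except (KeyError, ValueError):
        raise ValueError(
            f"unknown period {period!r}; expected one of {sorted(PERIOD_YEARS)} "
            f"or years {sorted(_PERIOD_BY_YEAR)}"
        ) from None


@dataclass(frozen=True)
class LocationClimate:
    """Sinusoid-plus-noise climatology for one location.

    ``baseline_tmax_mean``/``baseline_tmin_mean`` are the annual means of
    daily maxima/minima (°C) in the baseline period; amplitudes (°C) and
    ``peak_day`` (day-of-year of the warmest day) shape the seasonal
    cycle; ``daily_noise_sd`` (°C) is the day-to-day stochastic spread.
    """

    name: str
    baseline_tmax_mean: float
    baseline_tmin_mean: float
    seasonal_amplitude_tmax: float = 4.0
    seasonal_amplitude_tmin: float = 4.0
    peak_day: int = 135
    daily_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.baseline_tmax_mean > self.baseline_tmin_mean:
            raise ValueError(
                f"{self.name}: baseline_tmax_mean must exceed baseline_tmin_mean"
            )
        if self.seasonal_amplitude_tmax < 0 or self.seasonal_amplitude_tmin < 0:
            raise ValueError(f"{self.name}: seasonal amplitudes must be >= 0")
        if not 1 <= self.peak_day <= 365:
            raise ValueError(f"{self.name}: peak_day must lie in 1..365")
        if self.daily_noise_sd < 0:
            raise ValueError(f"{self.name}: daily_noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioOffset:
    """Uniform warming offsets (°C) for one scenario × period.

    ``delta_tmax``/``delta_tmin`` are added to every daily maximum/minimum.
    The baseline period must carry zero offsets by definition.
    """

    scenario: str
    period: str
    delta_tmax: float = 0.0
    delta_tmin: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "period", period_label(self.period))
        if self.scenario not in SCENARIOS + ("BL",):
            raise ValueError(f"unknown scenario {self.scenario!r}; expected {SCENARIOS}")
        if self.period == "BL" and (self.delta_tmax != 0.0 or self.delta_tmin != 0.0):
            raise ValueError("baseline period must have zero temperature offsets")

    @classmethod
    def baseline(cls) -> "ScenarioOffset":
        return cls(scenario="BL", period="BL", delta_tmax=0.0, delta_tmin=0.0)

    @property
    def year(self) -> int:
        return PERIOD_YEARS[self.period]


@dataclass
class ReplicateSet:
    """Replicate weather series for one study cell.

    ``cell`` carries the (location, model, scenario, period) coordinates
    as a mapping; regeneration with the same seed reproduces the
    identical series.
    """

    cell: Mapping[str, str]
    replicates: list[WeatherSeries]
    seed: int

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError("a replicate set needs at least one replicate")
        ref = self.replicates[0].dates
        for i, s in enumerate(self.replicates[1:], start=1):
            if len(s) != len(ref):
                raise ValueError(f"replicate {i} spans {len(s)} days, expected {len(ref)}")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def offsets_between_rows(
    baseline_row: Mapping[str, float], scenario_row: Mapping[str, float]
) -> dict[str, float]:
    """Per-location deltas: scenario annual mean minus baseline annual mean.

    Both rows map location name -> annual mean (°C) for one variable.
    Deltas may be negative (a scenario can project cooling at a site).

    Raises
    ------
    KeyError
        If the location sets differ (missing locations are named).
    """
    missing = set(baseline_row) ^ set(scenario_row)
    if missing:
        raise KeyError(
            "rows cover different locations; missing on one side: "
            + ", ".join(sorted(missing))
        )
    return {loc: scenario_row[loc] - baseline_row[loc] for loc in baseline_row}


def _seasonal_cycle(mean: float, amplitude: float, peak_day: int, year_length: int) -> np.ndarray:
    d = np.arange(1, year_length + 1, dtype=float)
    return mean + amplitude * np.cos(2.0 * np.pi * (d - peak_day) / year_length)


def generate_weather_series(
    climate: LocationClimate,
    offset: ScenarioOffset | None = None,
    year_length: int = 365,
    seed: int = 0,
    year: int | None = None,
) -> WeatherSeries:
    """Generate one replicate-year of daily Tmax/Tmin.

    Tmax and Tmin noise are drawn independently (Tmax first, then Tmin,
    from a single seeded generator — the draw order is part of the
    determinism contract).  Any day where the noisy Tmin exceeds Tmax is
    repaired by swapping the two values, preserving day count and seed
    determinism.

    ``year`` defaults to the offset's representative period year and
    fixes the calendar used for the date index.
    """
    if year_length <= 0:
        raise ValueError("year_length must be positive")
    if year_length not in (365, 366):
        raise ValueError("year_length must be 365 or 366")
    offset = offset if offset is not None else ScenarioOffset.baseline()
    year = year if year is not None else offset.year

    rng = np.random.default_rng(seed)
    tmax = (
        _seasonal_cycle(
            climate.baseline_tmax_mean,
            climate.seasonal_amplitude_tmax,
            climate.peak_day,
            year_length,
        )
        + offset.delta_tmax
        + rng.normal(0.0, climate.daily_noise_sd, year_length)
    )
    tmin = (
        _seasonal_cycle(
            climate.baseline_tmin_mean,
            climate.seasonal_amplitude_tmin,
            climate.peak_day,
            year_length,
        )
        + offset.delta_tmin
        + rng.normal(0.0, climate.daily_noise_sd, year_length)
    )
    swap = tmin > tmax
    if swap.any():
        tmax[swap], tmin[swap] = tmin[swap].copy(), tmax[swap].copy()

    index = pd.date_range(start=f"{year}-01-01", periods=year_length, freq="D")
    df = pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=index)
    df.index.name = "date"
    return WeatherSeries(data=df, station_id=climate.name)


def child_seed(seed: int, *key: int) -> int:
    """Deterministic child seed for (seed, key...), kept below 2**31."""
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_replicate_set(
    climate: LocationClimate,
    offset: ScenarioOffset | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    year_length: int = 365,
    cell: Mapping[str, str] | None = None,
) -> ReplicateSet:
    """Generate ``n_replicates`` series differing only in noise draws.

    Replicate ``r`` uses the deterministic child seed of ``(seed, r)``,
    so the set regenerates identically under the same seed and any
    single replicate can be regenerated in isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    offset = offset if offset is not None else ScenarioOffset.baseline()
    reps = [
        generate_weather_series(
            climate, offset, year_length=year_length, seed=child_seed(seed, r)
        )
        for r in range(n_replicates)
    ]
    if cell is None:
        cell = {
            "location": climate.name,
            "model": "",
            "scenario": offset.scenario,
            "period": offset.period,
        }
    return ReplicateSet(cell=dict(cell), replicates=reps, seed=seed)
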