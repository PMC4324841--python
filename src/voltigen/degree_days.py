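"""Growing-degree-day accumulation and voltinism prediction.

Daily heat units for *Spodoptera litura* use the simple-average formula
with a lower developmental threshold t0 and a horizontal upper cut-off:

    DD(day) = max(0, min((Tmax + Tmin)/2, t_upper) - t0)

i.e. the daily mean is capped at the upper threshold (heat above it does
not speed development) and days whose mean falls below t0 contribute
nothing.  Accumulating DD over the peanut crop season — standard weeks
26–44, a fixed 133-day window — and dividing by the thermal constant K
(degree-days per egg-to-adult cycle) gives the fractional number of
generations; the default generation time is the window length divided by
that number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .weather_io import WeatherSeries

__all__ = [
    "GDDParams",
    "SeasonWindow",
    "GenerationPrediction",
    "CellSummary",
    "daily_degree_days",
    "standard_week_days",
    "accumulate_generations",
    "generation_time",
    "summarize_cell",
]


@dataclass(frozen=True)
class GDDParams:
    """Thermal-biology constants for the target insect.

    t0 : lower developmental threshold (°C); development ceases below it.
    t_upper : horizontal cut-off (°C); daily means above it are capped.
    k : thermal constant (degree-days per completed generation).
    """

    t0: float = 10.0
    t_upper: float = 37.0
    k: float = 522.7

    def __post_init__(self) -> None:
        if not self.t0 < self.t_upper:
            raise ValueError("t0 must be below t_upper")
        if not self.k > 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive standard-week span of the crop season.

    Standard week w covers days 7(w-1)+1 .. 7w of the year (week 1 =
    Jan 1–7; day 365/366 belongs to no week), so the default 26–44 span
    is days 176–308: 19 weeks, 133 days.
    """

    start_week: int = 26
    end_week: int = 44

    def __post_init__(self) -> None:
        if not (1 <= self.start_week <= self.end_week <= 52):
            raise ValueError("need 1 <= start_week <= end_week <= 52")

    @property
    def n_days(self) -> int:
        return 7 * (self.end_week - self.start_week + 1)

    @property
    def first_day(self) -> int:
        return 7 * (self.start_week - 1) + 1

    @property
    def last_day(self) -> int:
        return 7 * self.end_week


def standard_week_days(window: SeasonWindow) -> tuple[int, int, int]:
    """Day-of-year range covered by a standard-week window.

    Returns ``(first_day, last_day, n_days)``, inclusive on both ends.
    """
    return window.first_day, window.last_day, window.n_days


def daily_degree_days(
    tmax: float | np.ndarray, tmin: float | np.ndarray, params: GDDParams = GDDParams()
) -> float | np.ndarray:
    """Heat units for one day (or elementwise for arrays of days).

    Raises
    ------
    ValueError
        If any tmax < tmin.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin is not a valid day")
    mean = (tmax + tmin) / 2.0
    dd = np.clip(np.minimum(mean, params.t_upper) - params.t0, 0.0, None)
    return float(dd) if dd.ndim == 0 else dd


@dataclass
class GenerationPrediction:
    """Voltinism summary for one replicate series over one window.

    n_generations is fractional (TDD / K); ``boundary_days`` holds the
    day-of-year at which each successive multiple of K is first reached;
    ``mean_gdd`` averages the DD actually accumulated within each
    completed generation span (a self-check: it can only exceed K by the
    sub-daily overshoot of the day that closes a generation).
    """

    n_generations: float
    generation_time: float | None
    tdd: float
    mean_gdd: float | None
    boundary_days: tuple[int, ...]
    window: SeasonWindow
    params: GDDParams

    @property
    def completed_generations(self) -> int:
        return len(self.boundary_days)


def _window_dd(series: WeatherSeries, window: SeasonWindow, params: GDDParams) -> np.ndarray:
    doy = series.dates.dayofyear.to_numpy()
    wanted = np.arange(window.first_day, window.last_day + 1)
    present = np.isin(wanted, doy)
    if not present.all():
        missing = wanted[~present]
        raise ValueError(
            f"series is missing {len(missing)} window day(s), day-of-year "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    mask = (doy >= window.first_day) & (doy <= window.last_day)
    return np.asarray(daily_degree_days(series.tmax[mask], series.tmin[mask], params))


def accumulate_generations(
    series: WeatherSeries,
    window: SeasonWindow = SeasonWindow(),
    params: GDDParams = GDDParams(),
    integer_generations: bool = False,
) -> GenerationPrediction:
    """Accumulate daily heat units over the window and count generations.

    The cumulative sum H(d) runs over the window days; the fractional
    number of generations is H(end)/K (floored if
    ``integer_generations``), boundary days mark where each multiple of
    K is first attained, and the default generation time is
    window.n_days / n_generations (None when no heat accumulates).
    """
    dd = _window_dd(series, window, params)
    cum = np.cumsum(dd)
    tdd = float(cum[-1]) if len(cum) else 0.0
    n_gen = tdd / params.k
    # 1e-9 guards against float round-off when TDD lands exactly on a
    # multiple of K (e.g. constant daily DD = K/7).
    completed = int(math.floor(n_gen + 1e-9))

    days = np.arange(window.first_day, window.last_day + 1)
    targets = params.k * np.arange(1, completed + 1)
    idx = np.searchsorted(cum, targets - 1e-9 * params.k, side="left")
    boundary_days = tuple(int(days[i]) for i in idx)

    if completed >= 1:
        h_at = cum[idx]
        gen_dd = np.diff(np.concatenate(([0.0], h_at)))
        mean_gdd = float(np.mean(gen_dd))
    else:
        mean_gdd = None

    if integer_generations:
        n_gen = float(completed)
    gt = window.n_days / n_gen if n_gen > 0 else None
    return GenerationPrediction(
        n_generations=n_gen,
        generation_time=gt,
        tdd=tdd,
        mean_gdd=mean_gdd,
        boundary_days=boundary_days,
        window=window,
        params=params,
    )


def generation_time(
    prediction: GenerationPrediction,
    window: SeasonWindow | None = None,
    definition: str = "window",
) -> float | None:
    """Days per generation under either definition.

    ``window`` (default): window length divided by the fractional number
    of generations — the definition consistent with the published
    summary tables, where N × GT recovers the window length.
    ``boundary``: mean interval between successive completed-generation
    boundary days (needs >= 1 completed generation; the first interval
    is measured from the window start).

    Returns None when the quantity is undefined (no accumulation /
    no completed generation) rather than raising.
    """
    window = window if window is not None else prediction.window
    if definition == "window":
        if prediction.n_generations <= 0:
            return None
        return window.n_days / prediction.n_generations
    if definition == "boundary":
        if not prediction.boundary_days:
            return None
        starts = (window.first_day - 1,) + prediction.boundary_days[:-1]
        intervals = [b - s for s, b in zip(starts, prediction.boundary_days)]
        return float(np.mean(intervals))
    raise ValueError(f"unknown generation-time definition {definition!r}")


@dataclass(frozen=True)
class CellSummary:
    """Replicate mean ± standard error for one study cell."""

    mean_n: float
    se_n: float
    mean_gt: float
    se_gt: float
    n_replicates: int
    degenerate: bool = False  # single replicate or zero spread: SE is 0 by convention

    def __post_init__(self) -> None:
        if self.se_n < 0 or self.se_gt < 0:
            raise ValueError("standard errors cannot be negative")


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    # identical replicates must report SE exactly 0 (float summation can
    # otherwise leave an O(eps) residual)
    if n <= 1 or np.ptp(values) == 0.0:
        return mean, 0.0
    return mean, float(np.std(values, ddof=1) / np.sqrt(n))


def summarize_cell(predictions: Sequence[GenerationPrediction] | Iterable[GenerationPrediction]) -> CellSummary:
    """Mean and standard error (sd/sqrt(n)) of N and GT over replicates."""
    preds = list(predictions)
    if not preds:
        raise ValueError("summarize_cell needs at least one prediction")
    n_vals = np.array([p.n_generations for p in preds], dtype=float)
    gt_vals = np.array(
        [p.generation_time if p.generation_time is not None else np.nan for p in preds],
        dtype=float,
    )
    mean_n, se_n = _mean_se(n_vals)
    mean_gt, se_gt = _mean_se(gt_vals)
    degenerate = len(preds) == 1 or (se_n == 0.0 and se_gt == 0.0)
    return CellSummary(
        mean_n=mean_n,
        se_n=se_n,
        mean_gt=mean_gt,
        se_gt=se_gt,
        n_replicates=len(preds),
        degenerate=degenerate,
    )
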