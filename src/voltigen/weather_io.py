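"""Daily weather containers and DSSAT-dialect text I/O.

MarkSim-style downloads arrive as DSSAT weather files (``.WTG``/``.WTH``):
a station header followed by a ``@DATE SRAD TMAX TMIN RAIN`` table, one row
per day, with ``-99`` marking missing values.  This module reads and writes
that dialect and flattens replicate collections into the long/wide tables
the degree-day engine and the statistics layer consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "WeatherFormatError",
    "read_wtg",
    "write_wtg",
    "replicates_to_table",
]

log = logging.getLogger(__name__)

MISSING_SENTINEL = -99.0

#: Two-digit years >= this pivot's last two digits map to the 1900s,
#: the rest to the 2000s, so YYDDD tokens cover 1970-2069.
YEAR_PIVOT = 1970


class WeatherFormatError(ValueError):
    """Raised when a weather file cannot be parsed or fails validation."""


@dataclass
class WeatherSeries:
    """One replicate-year of daily weather.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by a daily :class:`~pandas.DatetimeIndex` (strictly
        consecutive days), with float columns ``tmax`` and ``tmin`` (°C)
        and optional ``srad`` (MJ m⁻² day⁻¹) and ``rain`` (mm); NaN marks
        an absent optional value.
    station_id : str
        Free-text station label carried through file round-trips.
    latitude, longitude : float, optional
        Decimal degrees; informational only.
    """

    data: pd.DataFrame
    station_id: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in ("tmax", "tmin"):
            if col not in df.columns:
                raise WeatherFormatError(f"weather data lacks required column {col!r}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise WeatherFormatError("weather data must be indexed by calendar dates")
        if len(df) == 0:
            raise WeatherFormatError("weather series is empty")
        # gaps are tolerated (rejected sentinel rows leave holes); the
        # degree-day engine re-checks coverage of the days it needs
        if not (df.index.is_monotonic_increasing and df.index.is_unique):
            raise WeatherFormatError("dates must be strictly increasing (no repeats)")
        t = df[["tmax", "tmin"]].to_numpy(float)
        if not np.isfinite(t).all():
            raise WeatherFormatError("tmax/tmin must be finite for every day")
        violations = df.index[df["tmax"].to_numpy() < df["tmin"].to_numpy()]
        if len(violations):
            raise WeatherFormatError(
                "tmax < tmin on dates: " + ", ".join(str(d.date()) for d in violations[:10])
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def tmax(self) -> np.ndarray:
        return self.data["tmax"].to_numpy(float)

    @property
    def tmin(self) -> np.ndarray:
        return self.data["tmin"].to_numpy(float)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, WeatherSeries):
            return NotImplemented
        return (
            self.station_id == other.station_id
            and self.data.index.equals(other.data.index)
            and np.array_equal(
                self.data[["tmax", "tmin"]].to_numpy(), other.data[["tmax", "tmin"]].to_numpy()
            )
        )


def _parse_date_token(token: str) -> pd.Timestamp:
    """Decode a DSSAT date token: YYDDD (pivot 1970) or YYYYDDD."""
    if not token.isdigit() or len(token) not in (5, 7):
        raise WeatherFormatError(f"unrecognised date token {token!r} (expected YYDDD or YYYYDDD)")
    if len(token) == 5:
        yy, doy = int(token[:2]), int(token[2:])
        year = 1900 + yy if 1900 + yy >= YEAR_PIVOT else 2000 + yy
    else:
        year, doy = int(token[:4]), int(token[4:])
    return pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=doy - 1)


def _format_date_token(ts: pd.Timestamp) -> str:
    if YEAR_PIVOT <= ts.year < YEAR_PIVOT + 100:
        return f"{ts.year % 100:02d}{ts.dayofyear:03d}"
    return f"{ts.year:04d}{ts.dayofyear:03d}"


def read_wtg(path: str | Path) -> WeatherSeries:
    """Read a DSSAT-dialect daily weather file.

    Rows whose TMAX or TMIN is the ``-99`` missing sentinel are rejected
    (counted in a single log warning); missing SRAD/RAIN become NaN.
    Unknown extra columns are preserved verbatim on the returned frame.

    Raises
    ------
    WeatherFormatError
        If no ``@DATE`` header is found, a row cannot be parsed, or any
        surviving row has TMAX < TMIN (all offending dates are listed).
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    station_id, lat, lon = path.stem, None, None
    header_i = None
    columns: list[str] = []
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("*"):
            station_id = s.lstrip("*").split(":")[-1].strip() or station_id
        if s.startswith("@") and "DATE" in s.upper():
            header_i = i
            columns = [c.upper() for c in s.lstrip("@").split()]
            break
        if s.startswith("@"):  # station-metadata header; grab LAT/LONG if present
            meta_cols = [c.upper() for c in s.lstrip("@").split()]
            if i + 1 < len(lines) and lines[i + 1].strip():
                vals = lines[i + 1].split()
                meta = dict(zip(meta_cols, vals))
                try:
                    lat = float(meta.get("LAT", "nan"))
                    lon = float(meta.get("LONG", meta.get("LON", "nan")))
                except ValueError:
                    pass
    if header_i is None:
        raise WeatherFormatError(f"{path}: no '@DATE ...' header line found")
    if "DATE" not in columns:
        raise WeatherFormatError(f"{path}: header line {header_i + 1} lacks a DATE column")

    records: list[dict] = []
    rejected = 0
    for lineno, line in enumerate(lines[header_i + 1 :], start=header_i + 2):
        s = line.strip()
        if not s or s.startswith(("!", "*", "@")):
            continue
        tokens = s.split()
        if len(tokens) < len(columns):
            raise WeatherFormatError(f"{path}:{lineno}: expected {len(columns)} fields, got {len(tokens)}")
        row = dict(zip(columns, tokens))
        rec: dict = {"date": _parse_date_token(row["DATE"])}
        for col in columns:
            if col == "DATE":
                continue
            try:
                val = float(row[col])
            except ValueError as exc:
                raise WeatherFormatError(f"{path}:{lineno}: bad value for {col}: {row[col]!r}") from exc
            rec[col.lower()] = np.nan if val == MISSING_SENTINEL else val
        if np.isnan(rec.get("tmax", np.nan)) or np.isnan(rec.get("tmin", np.nan)):
            rejected += 1
            continue
        records.append(rec)
    if rejected:
        log.warning("%s: rejected %d row(s) with missing TMAX/TMIN", path, rejected)
    if not records:
        raise WeatherFormatError(f"{path}: no usable data rows")

    df = pd.DataFrame.from_records(records).set_index("date").sort_index()
    bad = df.index[df["tmax"] < df["tmin"]]
    if len(bad):
        raise WeatherFormatError(
            f"{path}: TMAX < TMIN on dates: " + ", ".join(str(d.date()) for d in bad[:10])
        )
    return WeatherSeries(data=df, station_id=station_id, latitude=lat, longitude=lon)


def write_wtg(series: WeatherSeries, path: str | Path) -> Path:
    """Write a series as DSSAT-dialect text (DATE SRAD TMAX TMIN RAIN).

    Temperatures are serialised to one decimal place; absent SRAD/RAIN
    become ``-99.0`` sentinels.  Columns beyond the standard four are
    dropped with a single log notice.
    """
    if len(series) == 0:
        raise ValueError("cannot write an empty weather series")
    path = Path(path)
    extra = [c for c in series.data.columns if c not in ("tmax", "tmin", "srad", "rain")]
    if extra:
        log.info("%s: dropping non-standard columns on write: %s", path, extra)

    lat = series.latitude if series.latitude is not None else MISSING_SENTINEL
    lon = series.longitude if series.longitude is not None else MISSING_SENTINEL
    out = [
        f"*WEATHER DATA : {series.station_id}",
        "",
        "@ INSI      LAT     LONG",
        f"  {(series.station_id or 'XXXX')[:4].upper():<4} {lat:8.3f} {lon:8.3f}",
        "@DATE  SRAD  TMAX  TMIN  RAIN",
    ]
    srad = series.data.get("srad", pd.Series(np.nan, index=series.data.index))
    rain = series.data.get("rain", pd.Series(np.nan, index=series.data.index))
    for ts, tx, tn, sr, rn in zip(series.dates, series.tmax, series.tmin, srad, rain):
        sr = MISSING_SENTINEL if pd.isna(sr) else sr
        rn = MISSING_SENTINEL if pd.isna(rn) else rn
        out.append(f"{_format_date_token(ts)} {sr:5.1f} {tx:5.1f} {tn:5.1f} {rn:5.1f}")
    path.write_text("\n".join(out) + "\n")
    return path


def replicates_to_table(
    replicates: Iterable[WeatherSeries] | Sequence[WeatherSeries] | "object",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten replicate series into a long table plus two wide pivots.

    Mirrors the post-processing step that compiles per-replicate weather
    downloads into one long ``(replicate, date, tmax, tmin)`` table and
    two dates × replicates matrices (one for tmax, one for tmin).

    Accepts any iterable of :class:`WeatherSeries` or an object with a
    ``replicates`` attribute (e.g. a ReplicateSet).

    Raises
    ------
    ValueError
        If replicates do not share an identical date span (the offending
        replicate index is named).
    """
    if hasattr(replicates, "replicates"):
        replicates = replicates.replicates  # type: ignore[union-attr]
    series_list = list(replicates)
    if not series_list:
        raise ValueError("no replicates supplied")
    ref_index = series_list[0].dates
    for i, s in enumerate(series_list[1:], start=1):
        if not s.dates.equals(ref_index):
            raise ValueError(f"replicate {i} has a mismatched date span")

    frames = []
    for i, s in enumerate(series_list):
        frames.append(
            pd.DataFrame(
                {"replicate": i, "date": s.dates, "tmax": s.tmax, "tmin": s.tmin}
            )
        )
    long = pd.concat(frames, ignore_index=True)
    tmax_wide = long.pivot(index="date", columns="replicate", values="tmax")
    tmin_wide = long.pivot(index="date", columns="replicate", values="tmin")
    return long, tmax_wide, tmin_wide
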