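"""Environmental drivers: daily temperature matrices and photoperiod.

The simulator is driven by two environmental time series only: daily mean
air temperature (one row per lattice cell, one column per day) and the
photoperiod derived from latitude and calendar date.  This module parses
and validates temperature tables, fills internal gaps by linear
interpolation (an explicit, separate step — the engine refuses incomplete
matrices), computes astronomical daylength, and synthesises seasonal
weather for fully offline test scenarios.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, UnsupportedLatitudeError

__all__ = [
    "Photoperiod",
    "TemperatureMatrix",
    "compute_photoperiod",
    "daylength_hours",
    "interpolate_gaps",
    "load_temperature_matrix",
    "synthesize_weather",
]

#: Sun-elevation threshold (degrees below horizon) defining day length.
#: 0.8333 deg corresponds to sunrise/sunset with atmospheric refraction,
#: i.e. the moment the top of the solar disk crosses the horizon.
DEFAULT_SUN_ELEVATION_DEG = 0.8333

#: Latitude band supported by the daylength model (no polar day/night).
MAX_ABS_LATITUDE = 66.5


@dataclass(frozen=True)
class Photoperiod:
    """Hours of daylight on a given day plus the day-over-day trend.

    ``increasing`` is True when today's daylength exceeds yesterday's
    (spring regime); diapausing-egg hatching is gated on this flag.
    """

    hours: float
    increasing: bool


def daylength_hours(
    latitude: float,
    day_of_year: int,
    sun_elevation_deg: float = DEFAULT_SUN_ELEVATION_DEG,
) -> float:
    """Astronomical daylength (hours) from the Forsythe et al. (1995) model.

    Parameters
    ----------
    latitude
        Geographic latitude in decimal degrees, ``|latitude| <= 66.5``.
    day_of_year
        1-366 (proleptic Gregorian; leap days allowed).
    sun_elevation_deg
        Degrees below the horizon at which the day is considered to
        start/end.  The default reproduces standard sunrise-to-sunset
        daylength including refraction.
    """
    if abs(latitude) > MAX_ABS_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} outside supported band |lat| <= {MAX_ABS_LATITUDE}"
        )
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError(f"day_of_year must be in 1..366, got {day_of_year}")
    # revolution angle of the Earth around the Sun
    theta = 0.2163108 + 2.0 * math.atan(
        0.9671396 * math.tan(0.00860 * (int(day_of_year) - 186))
    )
    # solar declination
    decl = math.asin(0.39795 * math.cos(theta))
    lat = math.radians(latitude)
    p = math.radians(sun_elevation_deg)
    cos_ha = (math.sin(p) + math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    return 24.0 - (24.0 / math.pi) * math.acos(cos_ha)


def compute_photoperiod(
    latitude: float,
    day_of_year: int,
    sun_elevation_deg: float = DEFAULT_SUN_ELEVATION_DEG,
) -> Photoperiod:
    """Daylength plus trend relative to the previous calendar day."""
    hours = daylength_hours(latitude, day_of_year, sun_elevation_deg)
    prev_day = day_of_year - 1 if day_of_year > 1 else 365
    prev = daylength_hours(latitude, prev_day, sun_elevation_deg)
    return Photoperiod(hours=hours, increasing=hours > prev)


@dataclass
class TemperatureMatrix:
    """Daily mean temperatures: one row per lattice cell, one column per day.

    The first column corresponds to ``start_date``.  Construction fails on
    any missing value: gap-filling must be done explicitly beforehand via
    :func:`interpolate_gaps`.
    """

    values: np.ndarray
    start_date: dt.date
    cell_ids: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None  # (cells, 2) projected x/y in metres

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if isinstance(self.start_date, str):
            self.start_date = dt.date.fromisoformat(self.start_date)
        if not self.cell_ids:
            self.cell_ids = [f"c{i}" for i in range(self.values.shape[0])]
        if len(self.cell_ids) != self.values.shape[0]:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} rows"
            )
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"missing/non-finite temperature at cell row {r} "
                f"({self.cell_ids[r]}), day column {c}; interpolate gaps first"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.values.shape[0], 2):
                raise FormatError(
                    f"coords shape {self.coords.shape} does not match "
                    f"{self.values.shape[0]} cells"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.n_days - 1)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def subset(self, cell_index: int) -> "TemperatureMatrix":
        """Single-cell view, e.g. to re-run one regional cell punctually."""
        return TemperatureMatrix(
            values=self.values[cell_index : cell_index + 1].copy(),
            start_date=self.start_date,
            cell_ids=[self.cell_ids[cell_index]],
            coords=None,
        )

    def window(self, start: dt.date | str, end: dt.date | str | None = None) -> "TemperatureMatrix":
        """Restrict the matrix to [start, end], e.g. to align a mid-May
        introduction with a January-starting weather table."""
        if isinstance(start, str):
            start = dt.date.fromisoformat(start)
        if isinstance(end, str):
            end = dt.date.fromisoformat(end)
        end = end or self.end_date
        i = (start - self.start_date).days
        j = (end - self.start_date).days
        if i < 0 or j >= self.n_days or j < i:
            raise FormatError(
                f"window [{start} .. {end}] outside table range "
                f"[{self.start_date} .. {self.end_date}]"
            )
        return TemperatureMatrix(
            values=self.values[:, i : j + 1].copy(),
            start_date=start,
            cell_ids=list(self.cell_ids),
            coords=None if self.coords is None else self.coords.copy(),
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.cell_ids)
        df.to_csv(path, header=False)


def interpolate_gaps(series) -> np.ndarray:
    """Linearly interpolate internal missing values of a daily series.

    Endpoints must be present (no extrapolation).  Observed values are
    preserved exactly, so the operation is idempotent.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        return np.vstack([interpolate_gaps(row) for row in arr])
    if arr.ndim != 1:
        raise FormatError("expected a 1-D daily series or a 2-D cells x days table")
    if arr.size == 0:
        return arr
    missing = ~np.isfinite(arr)
    if not missing.any():
        return arr.copy()
    if missing[0] or missing[-1]:
        raise FormatError("leading/trailing gaps cannot be interpolated (no extrapolation)")
    idx = np.arange(arr.size)
    out = arr.copy()
    out[missing] = np.interp(idx[missing], idx[~missing], arr[~missing])
    return out


def load_temperature_matrix(
    source,
    start_date,
    delimiter: str = ",",
    cell_ids: list[str] | None = None,
    coords: np.ndarray | None = None,
    round_to_int: bool = False,
) -> TemperatureMatrix:
    """Read a cells x days delimited-text temperature table.

    Each row is one lattice cell, each column one day; the first column
    must match ``start_date``.  Rows must all have the same length and
    every entry must parse as a real number — a missing value is an error
    here (run :func:`interpolate_gaps` and rebuild explicitly).

    ``round_to_int`` optionally rounds temperatures to whole degrees, a
    preprocessing convention sometimes applied to gridded climate exports;
    the engine itself accepts real-valued degrees Celsius.
    """
    with open(source) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{source}: empty temperature table")
    rows: list[list[float]] = []
    ids: list[str] = []
    has_labels = None
    for r, ln in enumerate(lines):
        fields = ln.split(delimiter)
        if has_labels is None:
            has_labels = not _is_number(fields[0])
        if has_labels:
            ids.append(fields[0])
            fields = fields[1:]
        vals = []
        for c, tok in enumerate(fields):
            tok = tok.strip()
            if tok == "" or tok.upper() in {"NA", "NAN"}:
                raise FormatError(
                    f"{source}: missing temperature at row {r}, column {c}; "
                    "gap-filling is a separate explicit step"
                )
            try:
                vals.append(float(tok))
            except ValueError:
                raise FormatError(
                    f"{source}: unparsable value {tok!r} at row {r}, column {c}"
                ) from None
        rows.append(vals)
        if len(vals) != len(rows[0]):
            raise FormatError(
                f"{source}: ragged table — row {r} has {len(vals)} columns, "
                f"row 0 has {len(rows[0])}"
            )
    values = np.asarray(rows, dtype=float)
    if round_to_int:
        values = np.rint(values)
    return TemperatureMatrix(
        values=values,
        start_date=start_date,
        cell_ids=cell_ids or ids,
        coords=coords,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def synthesize_weather(
    n_cells: int,
    n_days: int,
    mean: float = 15.0,
    amplitude: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    start_date: dt.date | str = dt.date(2010, 1, 1),
    cell_offsets=None,
    coords: np.ndarray | None = None,
) -> TemperatureMatrix:
    """Sinusoidal annual temperature cycle plus seeded Gaussian noise.

    The cycle is coldest on 1 January (day 0 of the series), so with
    ``noise_sd = 0`` the series minimum equals ``mean - amplitude``.
    ``cell_offsets`` shifts each cell's mean, e.g. to build a cold-to-warm
    regional gradient.  Deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    days = np.arange(n_days)
    base = mean - amplitude * np.cos(2.0 * np.pi * days / 365.25)
    values = np.tile(base, (n_cells, 1))
    if cell_offsets is not None:
        offsets = np.asarray(cell_offsets, dtype=float)
        if offsets.shape != (n_cells,):
            raise ValueError(f"cell_offsets must have shape ({n_cells},)")
        values = values + offsets[:, None]
    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if isinstance(start_date, str):
        start_date = dt.date.fromisoformat(start_date)
    return TemperatureMatrix(values=values, start_date=start_date, coords=coords)
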