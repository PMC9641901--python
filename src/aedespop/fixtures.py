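"""Deterministic toy scenarios so the whole pipeline runs offline.

Each bundle packs synthetic seasonal weather, optional lattice geometry
and road network, and a canned ovitrap-like observation series, together
with a manifest from which it can be regenerated bit-identically.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dispersal import RoadNetwork
from .environment import TemperatureMatrix, synthesize_weather

__all__ = ["FixtureBundle", "SCENARIOS", "make_toy_scenario"]

SCENARIOS = ("punctual_warm", "lattice_3x3", "regional_10cell")

_TRIP_MEAN_M = 9000.0  # toy road trips: France-like mean


@dataclass
class FixtureBundle:
    temps: TemperatureMatrix
    roads: RoadNetwork | None = None
    observations: pd.Series | None = None
    manifest: dict = field(default_factory=dict)


def _cross_road_network(side: int, cellsize: float) -> RoadNetwork:
    """Road crossing through the middle row and column of a side x side grid."""
    mid = side // 2
    cells = sorted(
        {r * side + mid for r in range(side)} | {mid * side + c for c in range(side)}
    )
    coords = {c: (c % side, c // side) for c in cells}
    n = len(cells)
    dmat = np.zeros((n, n))
    for i, a in enumerate(cells):
        ax, ay = coords[a]
        for j, b in enumerate(cells):
            bx, by = coords[b]
            # along-road (through the crossing) manhattan distance
            if ax == bx or ay == by:
                d = abs(ax - bx) + abs(ay - by)
            else:
                d = abs(ax - mid) + abs(ay - by) + abs(bx - mid)
                d2 = abs(ay - mid) + abs(ax - bx) + abs(by - mid)
                d = min(d, d2)
            dmat[i, j] = d * cellsize
    return RoadNetwork(
        road_cells=np.array(cells),
        distance_matrix=dmat,
        country_trip_mean_m=_TRIP_MEAN_M,
    )


def _grid_coords(side: int, cellsize: float) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    return np.column_stack([xs.ravel() * cellsize, ys.ravel() * cellsize]).astype(float)


def _toy_observations(dates: pd.DatetimeIndex, seed: int) -> pd.Series:
    """Fortnightly ovitrap-like counts: seasonal bell plus seeded noise."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7])))
    doy = dates.dayofyear.to_numpy()
    season = np.clip(np.sin((doy - 100) / 365.25 * 2 * np.pi) * 80, 0, None)
    counts = rng.poisson(season + 1.0)
    s = pd.Series(counts.astype(float), index=dates, name="observed_eggs")
    return s[::14]  # inspected fortnightly


def make_toy_scenario(name: str, seed: int = 1) -> FixtureBundle:
    """Deterministic fixture bundle for one of the known scenarios.

    * ``punctual_warm`` — 1 cell, 3 years, sinusoid mean 15 °C amplitude 10;
    * ``lattice_3x3`` — 9-cell local lattice (250 m cells) with a road
      crossing through the centre;
    * ``regional_10cell`` — 10 independent cells spanning a cold-to-warm
      gradient, 1 year.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIOS}")
    start = dt.date(2014, 1, 1)
    if name == "punctual_warm":
        n_days = 3 * 365
        temps = synthesize_weather(
            1, n_days, mean=15.0, amplitude=10.0, noise_sd=1.0,
            seed=seed, start_date=start,
        )
        obs = _toy_observations(temps.dates(), seed)
        roads = None
    elif name == "lattice_3x3":
        cellsize = 250.0
        coords = _grid_coords(3, cellsize)
        temps = synthesize_weather(
            9, 365, mean=16.0, amplitude=9.0, noise_sd=1.0,
            seed=seed, start_date=start, coords=coords,
        )
        roads = _cross_road_network(3, cellsize)
        obs = None
    else:  # regional_10cell
        offsets = np.linspace(-11.0, 7.0, 10)  # cell means 4 .. 22 degC
        temps = synthesize_weather(
            10, 365, mean=15.0, amplitude=10.0, noise_sd=1.0,
            seed=seed, start_date=start, cell_offsets=offsets,
        )
        roads = None
        obs = None
    manifest = {
        "scenario": name,
        "seed": seed,
        "start_date": str(start),
        "n_cells": temps.n_cells,
        "n_days": temps.n_days,
    }
    return FixtureBundle(temps=temps, roads=roads, observations=obs, manifest=manifest)
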