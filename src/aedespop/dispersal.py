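"""Adult movement on the lattice (local scale only).

Active dispersal: each adult independently either stays or flies a
distance drawn from a species-specific log-normal kernel discretised into
distance bins between the cell size and the maximum daily dispersal;
direction is isotropic (uniform choice among cells whose centre falls in
the drawn distance annulus).

Passive (car-mediated) dispersal: adults in cells intersecting the road
network board a car with a small probability and are released at the road
cell whose along-road distance from the origin best matches a trip length
drawn from an exponential distribution with the country-specific mean.

Both steps conserve the total adult count exactly and never move eggs or
juveniles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, FormatError

__all__ = [
    "DispersalKernel",
    "RoadNetwork",
    "build_kernel",
    "active_dispersal_step",
    "passive_dispersal_step",
    "dispersed_area_km2",
]


@dataclass(frozen=True)
class DispersalKernel:
    """Discretised log-normal distance kernel.

    ``bin_edges`` has ``dispbins + 1`` entries spanning [cellsize,
    maxadisp]; ``bin_probabilities`` and ``stay_probability`` form a
    simplex.  Mass below the cell size becomes "stay"; mass beyond the
    maximum daily dispersal is truncated and the rest renormalised.
    """

    bin_edges: np.ndarray
    bin_probabilities: np.ndarray
    stay_probability: float
    meanlog: float
    sdlog: float

    @property
    def bin_distances(self) -> np.ndarray:
        """Lower edge of each bin; element 0 equals the cell size."""
        return self.bin_edges[:-1]

    def mean_displacement(self) -> float:
        """Expected displacement using bin midpoints (stay counts as 0 m)."""
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(np.dot(mids, self.bin_probabilities))


def build_kernel(
    cellsize: float,
    maxadisp: float,
    dispbins: int,
    meanlog: float,
    sdlog: float,
) -> DispersalKernel:
    """Discretise the log-normal flight-distance density into distance bins."""
    if not 0 < cellsize <= maxadisp:
        raise ConfigurationError(
            f"cellsize ({cellsize}) must be in (0, maxadisp={maxadisp}]"
        )
    if dispbins < 1:
        raise ConfigurationError("dispbins must be >= 1")
    dist = stats.lognorm(s=sdlog, scale=np.exp(meanlog))
    edges = np.linspace(cellsize, maxadisp, dispbins + 1)
    cdf = dist.cdf(edges)
    stay = dist.cdf(cellsize)
    masses = np.diff(cdf)
    total = stay + masses.sum()  # mass beyond maxadisp truncated
    return DispersalKernel(
        bin_edges=edges,
        bin_probabilities=masses / total,
        stay_probability=float(stay / total),
        meanlog=meanlog,
        sdlog=sdlog,
    )


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def active_dispersal_step(
    counts: dict,
    kernel: DispersalKernel,
    coords: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Redistribute adults according to the kernel (in place).

    Every adult sub-compartment is dispersal-eligible.  Movers whose drawn
    distance bin contains no lattice cell (edge effects) stay put, so the
    total adult count is conserved exactly.
    """
    if coords is None:
        raise ConfigurationError("active dispersal requires cell coordinates")
    a = counts["A"]
    n_cells = a.shape[0]
    if n_cells == 1 or kernel.stay_probability >= 1.0:
        return
    dmat = _pairwise_distances(np.asarray(coords, dtype=float))
    probs = np.concatenate([[kernel.stay_probability], kernel.bin_probabilities])
    edges = kernel.bin_edges
    for c in range(n_cells):
        for sub in range(a.shape[1]):
            n = int(a[c, sub])
            if n == 0:
                continue
            alloc = rng.multinomial(n, probs)
            for b in range(len(kernel.bin_probabilities)):
                movers = int(alloc[b + 1])
                if movers == 0:
                    continue
                lo, hi = edges[b], edges[b + 1]
                last = b == len(kernel.bin_probabilities) - 1
                in_bin = (dmat[c] >= lo) & (
                    (dmat[c] <= hi) if last else (dmat[c] < hi)
                )
                targets = np.flatnonzero(in_bin)
                if targets.size == 0:
                    continue  # nowhere to go at that distance: stay
                a[c, sub] -= movers
                dest = rng.multinomial(movers, np.full(targets.size, 1.0 / targets.size))
                for tgt, k in zip(targets, dest):
                    a[tgt, sub] += int(k)


@dataclass(frozen=True)
class RoadNetwork:
    """Lattice cells intersecting the road network.

    ``road_cells`` are lattice cell indices; ``distance_matrix`` holds
    pairwise along-road distances in metres (symmetric, zero diagonal).
    """

    road_cells: np.ndarray
    distance_matrix: np.ndarray
    country_trip_mean_m: float

    def __post_init__(self) -> None:
        rc = np.asarray(self.road_cells, dtype=int)
        dm = np.asarray(self.distance_matrix, dtype=float)
        object.__setattr__(self, "road_cells", rc)
        object.__setattr__(self, "distance_matrix", dm)
        if dm.shape != (rc.size, rc.size):
            raise FormatError(
                f"distance matrix {dm.shape} does not match {rc.size} road cells"
            )
        if rc.size and (not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0)):
            raise FormatError("road distance matrix must be symmetric with zero diagonal")
        if self.country_trip_mean_m <= 0:
            raise ConfigurationError("country trip mean must be positive")


def passive_dispersal_step(
    counts: dict,
    roads: RoadNetwork,
    car_entry_probability: float,
    rng: np.random.Generator,
) -> None:
    """Car-mediated relocation of adults along the road network (in place).

    Each adult in a road cell boards a car with ``car_entry_probability``;
    the trip length is exponential with the country mean, truncated to the
    network extent, and the passenger alights at the road cell whose
    along-road distance from the origin is nearest to the drawn length.
    """
    if car_entry_probability == 0.0:
        return
    if roads.road_cells.size == 0:
        raise ConfigurationError(
            "passive dispersal enabled but the road network is empty"
        )
    a = counts["A"]
    max_extent = float(roads.distance_matrix.max()) if roads.road_cells.size else 0.0
    for i, cell in enumerate(roads.road_cells):
        row = roads.distance_matrix[i]
        for sub in range(a.shape[1]):
            n = int(a[cell, sub])
            if n == 0:
                continue
            passengers = int(rng.binomial(n, car_entry_probability))
            if passengers == 0:
                continue
            trips = rng.exponential(roads.country_trip_mean_m, size=passengers)
            if max_extent > 0:
                trips = np.minimum(trips, max_extent)
            a[cell, sub] -= passengers
            for trip in trips:
                j = int(np.argmin(np.abs(row - trip)))
                a[roads.road_cells[j], sub] += 1


def dispersed_area_km2(occupied_cells, cellsize_m: float):
    """Occupied-cell counts converted to invaded area in square kilometres."""
    occ = np.asarray(occupied_cells)
    return occ * (cellsize_m / 1000.0) ** 2
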