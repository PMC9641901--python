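"""Scale-aware simulation driver.

Three spatial scales:

* ``ws`` (punctual / weather station): one cell, no dispersal;
* ``lc`` (local): lattice with active (log-normal kernel) and optional
  passive (road network) adult dispersal;
* ``rg`` (regional): lattice of closed cells — introductions happen
  separately but simultaneously in every cell and no dispersal occurs, so
  each cell's trajectory is exactly a punctual run of that cell.

Randomness: one master seed; each iteration gets a deterministic stream
seed (:func:`schedule_seeds`), and within an iteration every cell gets its
own generator keyed by the cell id.  Cross-cell processes (dispersal) use
a separate per-iteration stream, so iterations are embarrassingly parallel
and regional per-cell trajectories are bitwise-reproducible by matched
punctual runs.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersal import (
    DispersalKernel,
    RoadNetwork,
    active_dispersal_step,
    build_kernel,
    passive_dispersal_step,
)
from .environment import TemperatureMatrix, compute_photoperiod
from .errors import ConfigurationError
from .lifecycle import STAGES, PopulationState, daily_step, introduce
from .registry import get_species_params

__all__ = [
    "SCALES",
    "SimulationConfig",
    "SimulationResult",
    "run",
    "schedule_seeds",
    "read_result",
    "write_result",
]

SCALES = ("ws", "lc", "rg")

_DISPERSAL_STREAM_TAG = 0xD15B0  # distinct child key for cross-cell draws


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation experiment.

    Argument names mirror the conventions of the original field tool
    (species, scale, intro.*, jhwv, startd/endd, iter, lat/long, cellsize,
    maxadisp, dispbins, country).
    """

    species: str = "aegypti"
    scale: str = "ws"
    intro_eggs: int = 100
    intro_deggs: int = 0
    intro_juveniles: int = 0
    intro_adults: int = 0
    intro_cells: tuple | None = None  # None: every cell
    jhwv: float = 2.0  # litres of larval habitat per cell
    start_date: str = "2010-05-15"
    end_date: str = "2010-12-31"
    iterations: int = 1
    latitude: float = 45.0
    longitude: float = 0.0  # kept for interface parity; unused by the engine
    seed: int = 1
    cellsize: float = 250.0
    maxadisp: float = 600.0
    dispbins: int = 10
    country: str | None = None
    compressed_output: bool = True
    n_jobs: int = 1
    # diagnostic hook: force every event probability (structural skeleton)
    force_probability: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ConfigurationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.end <= self.start:
            raise ConfigurationError("end_date must be after start_date")
        if self.jhwv <= 0:
            raise ConfigurationError("jhwv must be positive litres")

    @property
    def start(self) -> dt.date:
        return dt.date.fromisoformat(str(self.start_date))

    @property
    def end(self) -> dt.date:
        return dt.date.fromisoformat(str(self.end_date))

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["intro_cells"] is not None:
            d["intro_cells"] = list(d["intro_cells"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("intro_cells") is not None:
            d["intro_cells"] = tuple(d["intro_cells"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def schedule_seeds(master_seed: int, iterations: int) -> list[int]:
    """Deterministic, collision-free per-iteration stream seeds.

    Derived through ``numpy.random.SeedSequence([master_seed, i])`` and
    independent of execution order or worker count.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    out = []
    for i in range(iterations):
        words = np.random.SeedSequence([int(master_seed), i]).generate_state(2)
        out.append(int((int(words[0]) << 31) ^ int(words[1])))
    return out


def _cell_rng(iter_seed: int, cell_id: str) -> np.random.Generator:
    key = zlib.crc32(cell_id.encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([iter_seed, key])))


@dataclass
class SimulationResult:
    """Per-iteration, per-day, per-cell stage abundances plus bookkeeping.

    ``counts`` has shape (iterations, days, cells, 4) in stage order
    E, Ed, J, A (Ed always present, zero for non-diapausing species).
    ``eggs_laid`` and ``host_seeking`` expose the sub-compartment-level
    series needed for trap-data comparisons without a full uncompressed
    dump.  ``sub_counts`` (stage -> (iterations, days, cells, subs)) is
    populated only when ``compressed_output`` is off.
    """

    counts: np.ndarray
    eggs_laid: np.ndarray
    host_seeking: np.ndarray
    dates: pd.DatetimeIndex
    cell_ids: list[str]
    config: SimulationConfig
    iteration_seeds: list[int]
    sub_counts: dict | None = None
    stage_names: tuple = STAGES

    @property
    def n_iterations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[2]

    @property
    def is_spatial(self) -> bool:
        return self.config.scale in ("lc", "rg")

    def day_index(self, date) -> int:
        ts = pd.Timestamp(date)
        idx = self.dates.get_indexer([ts])
        if idx[0] == -1:
            raise ValueError(f"date {date} outside simulated range "
                             f"[{self.dates[0].date()} .. {self.dates[-1].date()}]")
        return int(idx[0])

    def totals(self) -> np.ndarray:
        """(iterations, days) total individuals across stages and cells."""
        return self.counts.sum(axis=(2, 3))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: iteration, date, cell, stage counts + extras."""
        it, nd, nc, _ = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [range(it), self.dates, self.cell_ids],
            names=["iteration", "date", "cell"],
        )
        df = pd.DataFrame(
            self.counts.reshape(it * nd * nc, 4),
            index=idx,
            columns=list(self.stage_names),
        )
        df["eggs_laid"] = self.eggs_laid.reshape(-1)
        df["host_seeking"] = self.host_seeking.reshape(-1)
        return df.reset_index()


def _run_iteration(
    iter_seed: int,
    config: SimulationConfig,
    temps: TemperatureMatrix,
    roads: RoadNetwork | None,
    kernel: DispersalKernel | None,
    photoperiods: list,
):
    params = get_species_params(config.species)
    n_cells = temps.n_cells
    n_days = config.n_days
    rngs = [_cell_rng(iter_seed, cid) for cid in temps.cell_ids]
    disp_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([iter_seed, _DISPERSAL_STREAM_TAG]))
    )

    state = PopulationState.empty(n_cells, params)
    cells = list(config.intro_cells) if config.intro_cells is not None else None
    for stage, n in (
        ("E", config.intro_eggs),
        ("Ed", config.intro_deggs),
        ("J", config.intro_juveniles),
        ("A", config.intro_adults),
    ):
        if n > 0:
            state = introduce(state, stage, n, cells, params)

    counts = np.zeros((n_days, n_cells, 4), dtype=np.int64)
    eggs_laid = np.zeros((n_days, n_cells), dtype=np.int64)
    host_seeking = np.zeros((n_days, n_cells), dtype=np.int64)
    sub_counts = None
    if not config.compressed_output:
        sub_counts = {
            s: np.zeros((n_days, n_cells, arr.shape[1]), dtype=np.int64)
            for s, arr in state.counts.items()
            if arr is not None
        }

    def record(day: int, st: PopulationState) -> None:
        counts[day] = st.stage_totals()
        if sub_counts is not None:
            for s, arr in st.counts.items():
                if arr is not None:
                    sub_counts[s][day] = arr

    record(0, state)

    dispersal_fn = None
    if config.scale == "lc":
        def dispersal_fn(cnt):  # noqa: E306 - closure over run context
            active_dispersal_step(cnt, kernel, temps.coords, disp_rng)
            if roads is not None:
                passive_dispersal_step(
                    cnt, roads, params.dispersal.car_entry_probability, disp_rng
                )

    extinct = False
    for d in range(1, n_days):
        if extinct:
            record(d, state)  # absorbing: nothing to simulate
            continue
        state, stats = daily_step(
            state,
            temps.values[:, d],
            photoperiods[d],
            params,
            rngs,
            jhwv_litres=config.jhwv,
            probability_override=config.force_probability,
            dispersal_fn=dispersal_fn,
        )
        record(d, state)
        eggs_laid[d] = stats.eggs_laid
        host_seeking[d] = stats.host_seeking
        if state.total() == 0:
            extinct = True
    return counts, eggs_laid, host_seeking, sub_counts


def _validate(config: SimulationConfig, temps: TemperatureMatrix,
              roads: RoadNetwork | None) -> None:
    if config.scale == "ws" and temps.n_cells != 1:
        raise ConfigurationError(
            f"punctual (ws) scale requires a 1-row temperature matrix, "
            f"got {temps.n_cells} rows"
        )
    if config.scale == "lc" and temps.coords is None:
        raise ConfigurationError("local (lc) scale requires per-cell coordinates")
    if config.scale == "rg" and roads is not None:
        raise ConfigurationError(
            "regional (rg) scale has no dispersal; road network not allowed"
        )
    if temps.start_date != config.start:
        raise ConfigurationError(
            f"temperature matrix starts {temps.start_date}, "
            f"config starts {config.start}"
        )
    if temps.n_days < config.n_days:
        raise ConfigurationError(
            f"temperature matrix covers {temps.n_days} days, "
            f"simulation needs {config.n_days}"
        )
    if config.intro_deggs > 0 and not get_species_params(config.species).has_diapause:
        raise ConfigurationError("diapausing-egg introduction is invalid for aegypti")
    if config.intro_cells is not None:
        bad = [c for c in config.intro_cells if not 0 <= c < temps.n_cells]
        if bad:
            raise ConfigurationError(f"introduction cells out of range: {bad}")


def run(
    config: SimulationConfig,
    temps: TemperatureMatrix,
    roads: RoadNetwork | None = None,
) -> SimulationResult:
    """Run the full multi-iteration simulation."""
    _validate(config, temps, roads)
    params = get_species_params(config.species)
    kernel = None
    if config.scale == "lc":
        kernel = build_kernel(
            config.cellsize,
            config.maxadisp,
            config.dispbins,
            params.dispersal.meanlog,
            params.dispersal.sdlog,
        )
    dates = pd.date_range(config.start, config.end, freq="D")
    photoperiods = [
        compute_photoperiod(config.latitude, int(d.dayofyear)) for d in dates
    ]
    seeds = schedule_seeds(config.seed, config.iterations)

    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        pieces = Parallel(n_jobs=config.n_jobs)(
            delayed(_run_iteration)(s, config, temps, roads, kernel, photoperiods)
            for s in seeds
        )
    else:
        pieces = [
            _run_iteration(s, config, temps, roads, kernel, photoperiods)
            for s in seeds
        ]

    counts = np.stack([p[0] for p in pieces])
    eggs = np.stack([p[1] for p in pieces])
    host = np.stack([p[2] for p in pieces])
    sub_counts = None
    if not config.compressed_output:
        sub_counts = {
            s: np.stack([p[3][s] for p in pieces]) for s in pieces[0][3]
        }
    return SimulationResult(
        counts=counts,
        eggs_laid=eggs,
        host_seeking=host,
        dates=dates,
        cell_ids=list(temps.cell_ids),
        config=config,
        iteration_seeds=seeds,
        sub_counts=sub_counts,
    )


def write_result(result: SimulationResult, out_dir) -> Path:
    """Persist a result as delimited text plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "counts.csv", index=False)
    manifest = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "iteration_seeds": result.iteration_seeds,
        "cell_ids": result.cell_ids,
        "stage_names": list(result.stage_names),
        "dates": [str(result.dates[0].date()), str(result.dates[-1].date())],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_result(in_dir) -> SimulationResult:
    """Load a result written by :func:`write_result` (compressed form)."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    df = pd.read_csv(src / "counts.csv", parse_dates=["date"])
    dates = pd.date_range(manifest["dates"][0], manifest["dates"][1], freq="D")
    cell_ids = [str(c) for c in manifest["cell_ids"]]
    it = int(df["iteration"].max()) + 1
    nd, nc = len(dates), len(cell_ids)
    stages = manifest["stage_names"]
    df = df.sort_values(["iteration", "date", "cell"], kind="stable")
    # cell order must follow the manifest, not lexicographic order
    cell_order = {c: i for i, c in enumerate(cell_ids)}
    df["_cell_idx"] = df["cell"].astype(str).map(cell_order)
    df = df.sort_values(["iteration", "date", "_cell_idx"], kind="stable")
    counts = df[stages].to_numpy(dtype=np.int64).reshape(it, nd, nc, 4)
    eggs = df["eggs_laid"].to_numpy(dtype=np.int64).reshape(it, nd, nc)
    host = df["host_seeking"].to_numpy(dtype=np.int64).reshape(it, nd, nc)
    return SimulationResult(
        counts=counts,
        eggs_laid=eggs,
        host_seeking=host,
        dates=dates,
        cell_ids=cell_ids,
        config=config,
        iteration_seeds=list(manifest["iteration_seeds"]),
    )
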