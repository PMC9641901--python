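"""Daily stochastic update of the stage-structured population.

The population in each lattice cell is split into four compartments —
eggs (E), diapausing eggs (Ed, absent for Ae. aegypti), juveniles (J,
larvae + pupae pooled) and adult females (A) — and each compartment into
daily sub-compartments that enforce the species' minimum stage durations.
Every event is a binomial draw: survivors ~ Binomial(n, p) with p the
temperature- (or photoperiod-) dependent daily probability.

Within-day event order (fixed, documented):

1. survival draws for every sub-compartment (J with the density-dependent
   component, density = juveniles in the cell / habitat water volume);
2. transition draws from terminal sub-compartments: egg hatch -> J,
   diapausing-egg hatch -> J (only while the spring photoperiod gate is
   open), juvenile emergence -> A (thinned by the 1:1 sex ratio and the
   emergence-to-maturity probability);
3. sub-compartment aging: shift by one day, terminal sub-compartment pools
   (minimum residence is a floor, not a fixed duration), entrants from
   step 2 land in the youngest sub-compartment afterwards;
4. (optional dispersal hook, local scale only);
5. oviposition by gonotrophically competent females (terminal adult
   sub-compartment): each layer deposits a fixed clutch, split between E
   and Ed by the photoperiod-dependent diapause fraction, and re-enters
   the start of the gonotrophic chain (adult sub-compartment 1).

New eggs therefore appear after all other events and cannot hatch on the
day they are laid, which preserves the structural development minima
(first emergence no earlier than the sum of the E and J chain lengths:
day 11 for aegypti/albopictus, day 21 for japonicus/koreicus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import Photoperiod
from .errors import ConfigurationError, NoDiapauseError
from .physiology import (
    degg_hatch_allowed,
    degg_survival_probability,
    diapause_fraction,
    event_probability,
    juvenile_survival_probability,
)
from .registry import SpeciesParams

__all__ = [
    "STAGES",
    "DayStats",
    "PopulationState",
    "binomial_event",
    "daily_step",
    "introduce",
    "min_emergence_day",
]

STAGES = ("E", "Ed", "J", "A")


def binomial_event(n: int, p: float, rng: np.random.Generator) -> int:
    """Survivors of one stochastic event: a draw from Binomial(n, p)."""
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {p} (upstream clamping failed)")
    if n == 0 or p == 0.0:
        return 0
    if p == 1.0:
        return int(n)
    return int(rng.binomial(n, p))


@dataclass
class PopulationState:
    """Integer counts indexed by (cell, stage, sub-compartment).

    ``counts`` maps stage name to an int64 array of shape
    (n_cells, n_sub_compartments); the Ed entry is ``None`` for species
    without diapause.  Sub-compartment 0 is the youngest.
    """

    counts: dict = field(default_factory=dict)
    day_index: int = 0

    @classmethod
    def empty(cls, n_cells: int, params: SpeciesParams) -> "PopulationState":
        c = {
            "E": np.zeros((n_cells, params.stage_durations["E"]), dtype=np.int64),
            "Ed": (
                np.zeros((n_cells, 1), dtype=np.int64)
                if params.has_diapause
                else None
            ),
            "J": np.zeros((n_cells, params.stage_durations["J"]), dtype=np.int64),
            "A": np.zeros((n_cells, params.stage_durations["A"]), dtype=np.int64),
        }
        return cls(counts=c, day_index=0)

    @property
    def n_cells(self) -> int:
        return self.counts["E"].shape[0]

    def stage_totals(self) -> np.ndarray:
        """(n_cells, 4) totals in stage order E, Ed, J, A (Ed zero if absent)."""
        out = np.zeros((self.n_cells, 4), dtype=np.int64)
        for i, stage in enumerate(STAGES):
            arr = self.counts.get(stage)
            if arr is not None:
                out[:, i] = arr.sum(axis=1)
        return out

    def total(self) -> int:
        return int(self.stage_totals().sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            counts={
                k: (v.copy() if v is not None else None)
                for k, v in self.counts.items()
            },
            day_index=self.day_index,
        )


@dataclass
class DayStats:
    """Per-cell bookkeeping emitted by one daily step."""

    eggs_laid: np.ndarray  # total eggs deposited per cell
    eggs_to_e: np.ndarray
    eggs_to_ed: np.ndarray
    host_seeking: np.ndarray  # gonotrophically competent females pre-oviposition


def introduce(
    state: PopulationState,
    stage: str,
    n: int,
    cells=None,
    params: SpeciesParams | None = None,
) -> PopulationState:
    """Add ``n`` propagules to the youngest sub-compartment of ``stage``.

    ``cells`` is an iterable of cell indices (default: all cells); each
    listed cell receives ``n`` individuals.
    """
    if n < 0:
        raise ValueError("introduction count must be >= 0")
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    if stage == "Ed" and state.counts["Ed"] is None:
        sp = params.species if params is not None else "this species"
        raise NoDiapauseError(f"cannot introduce diapausing eggs for {sp}")
    out = state.copy()
    idx = range(out.n_cells) if cells is None else cells
    for c in idx:
        out.counts[stage][c, 0] += n
    return out


def min_emergence_day(params: SpeciesParams) -> int:
    """Structural minimum days from egg laying to adult emergence.

    The sum of the egg and juvenile sub-compartment chain lengths: 11 for
    aegypti/albopictus, 21 for japonicus/koreicus.
    """
    return params.stage_durations["E"] + params.stage_durations["J"]


def _survive_row(row: np.ndarray, p: float, rng: np.random.Generator) -> None:
    for i in range(row.shape[0]):
        if row[i] > 0:
            row[i] = binomial_event(int(row[i]), p, rng)


def _age_row(row: np.ndarray, entrants: int = 0) -> None:
    """Shift one day; terminal sub-compartment pools; entrants land at 0."""
    k = row.shape[0]
    if k > 1:
        row[k - 1] += row[k - 2]
        row[1 : k - 1] = row[0 : k - 2]
        row[0] = 0
    row[0] += entrants


def daily_step(
    state: PopulationState,
    temperature_by_cell,
    photoperiod: Photoperiod,
    params: SpeciesParams,
    rngs,
    jhwv_litres: float = 2.0,
    probability_override: float | None = None,
    dispersal_fn=None,
) -> tuple[PopulationState, DayStats]:
    """Advance the population by one day.

    ``rngs`` is a sequence of per-cell ``numpy.random.Generator`` streams —
    every draw concerning cell ``c`` consumes only ``rngs[c]``, which makes
    a multi-cell regional run bitwise-reproducible cell by cell.
    ``probability_override`` replaces every event probability (a testing
    hook for the deterministic structural skeleton).  ``dispersal_fn``,
    when given, is called between aging and oviposition with the mutable
    counts dict (local scale only).
    """
    temps = np.atleast_1d(np.asarray(temperature_by_cell, dtype=float))
    n_cells = state.n_cells
    if temps.shape[0] != n_cells:
        raise ConfigurationError(
            f"temperature for {temps.shape[0]} cells but state has {n_cells}"
        )
    if not np.all(np.isfinite(temps)):
        raise ConfigurationError("temperature missing (non-finite) for some cell")
    if len(rngs) != n_cells:
        raise ConfigurationError("need one RNG stream per cell")

    out = state.copy()
    cnt = out.counts
    has_dia = cnt["Ed"] is not None
    gate_open = has_dia and degg_hatch_allowed(photoperiod, params)
    ovi = probability_override

    stats = DayStats(
        eggs_laid=np.zeros(n_cells, dtype=np.int64),
        eggs_to_e=np.zeros(n_cells, dtype=np.int64),
        eggs_to_ed=np.zeros(n_cells, dtype=np.int64),
        host_seeking=np.zeros(n_cells, dtype=np.int64),
    )

    new_j = np.zeros(n_cells, dtype=np.int64)
    new_a = np.zeros(n_cells, dtype=np.int64)

    for c in range(n_cells):
        t = float(temps[c])
        g = rngs[c]

        if ovi is not None:
            p_e = p_ed = p_j = p_a = p_hatch = p_dev = p_mature = ovi
        else:
            p_e = event_probability("egg_survival", t, params)
            p_ed = degg_survival_probability(t, params) if has_dia else 0.0
            density = float(cnt["J"][c].sum()) / jhwv_litres
            p_j = juvenile_survival_probability(t, density, params)
            p_a = event_probability("adult_survival", t, params)
            p_hatch = event_probability("egg_hatch", t, params)
            p_dev = event_probability("juvenile_development", t, params)
            p_mature = event_probability("adult_emergence_to_mature", t, params)

        # 1. survival
        _survive_row(cnt["E"][c], p_e, g)
        if has_dia:
            _survive_row(cnt["Ed"][c], p_ed, g)
        _survive_row(cnt["J"][c], p_j, g)
        _survive_row(cnt["A"][c], p_a, g)

        # 2. transitions from terminal sub-compartments
        e_term = int(cnt["E"][c, -1])
        hatched = binomial_event(e_term, p_hatch, g)
        cnt["E"][c, -1] -= hatched

        d_hatched = 0
        if gate_open:
            d_hatched = binomial_event(int(cnt["Ed"][c, 0]), p_hatch, g)
            cnt["Ed"][c, 0] -= d_hatched

        emerged = binomial_event(int(cnt["J"][c, -1]), p_dev, g)
        cnt["J"][c, -1] -= emerged
        females = binomial_event(emerged, params.sex_ratio, g)
        matured = binomial_event(females, p_mature, g)

        new_j[c] = hatched + d_hatched
        new_a[c] = matured

        # 3. aging (entrants land in the youngest sub-compartment afterwards)
        _age_row(cnt["E"][c])
        _age_row(cnt["J"][c], entrants=int(new_j[c]))
        _age_row(cnt["A"][c], entrants=int(new_a[c]))

    # 4. dispersal hook (adults only; local scale)
    if dispersal_fn is not None:
        dispersal_fn(cnt)

    # 5. oviposition
    for c in range(n_cells):
        t = float(temps[c])
        g = rngs[c]
        p_ovi = ovi if ovi is not None else event_probability("oviposition", t, params)
        competent = int(cnt["A"][c, -1])
        stats.host_seeking[c] = competent
        layers = binomial_event(competent, p_ovi, g)
        if layers == 0:
            continue
        eggs = layers * params.clutch_size
        frac = diapause_fraction(photoperiod.hours, params) if has_dia else 0.0
        to_ed = binomial_event(eggs, frac, g) if frac > 0.0 else 0
        cnt["E"][c, 0] += eggs - to_ed
        if to_ed:
            cnt["Ed"][c, 0] += to_ed
        # layers re-enter the gonotrophic chain (sub-compartment 1)
        cnt["A"][c, -1] -= layers
        cnt["A"][c, 1] += layers
        stats.eggs_laid[c] = eggs
        stats.eggs_to_e[c] = eggs - to_ed
        stats.eggs_to_ed[c] = to_ed

    out.day_index = state.day_index + 1
    return out, stats
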