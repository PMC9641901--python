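"""Species parameter registry.

All biological constants live in a human-readable YAML file shipped with
the package (``data/species_params_synthetic.yaml``) and are loaded into
frozen dataclasses here.  The engine treats them as opaque configuration:
an updated calibration drops in without code changes.  The shipped file is
a synthetic reconstruction — see its header for which entries are exact
printed constants and which are plausible stand-ins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import RegistryError

__all__ = [
    "SPECIES",
    "Defaults",
    "DiapauseParams",
    "DispersalParams",
    "DensityParams",
    "Registry",
    "SpeciesParams",
    "ThermalFunction",
    "load_registry",
    "get_species_params",
]

SPECIES = ("aegypti", "albopictus", "japonicus", "koreicus")

#: life-cycle events with a temperature-dependent stored function
THERMAL_EVENTS = (
    "egg_hatch",
    "egg_survival",
    "juvenile_survival",
    "juvenile_development",
    "adult_survival",
    "adult_emergence_to_mature",
    "oviposition",
)


@dataclass(frozen=True)
class ThermalFunction:
    """One stored rate/probability curve: beta, polynomial or exponential."""

    form: str
    coefficients: tuple[float, ...] = ()
    rmax: float | None = None
    t_opt: float | None = None
    t_min: float | None = None
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.form not in {"beta", "polynomial", "exponential"}:
            raise RegistryError(f"unknown thermal function form {self.form!r}")
        if self.form == "beta":
            if None in (self.rmax, self.t_opt, self.t_min, self.t_max):
                raise RegistryError("beta form requires rmax, t_opt, t_min, t_max")
            if not self.t_min < self.t_opt < self.t_max:
                raise RegistryError(
                    f"beta thresholds must satisfy t_min < t_opt < t_max, got "
                    f"({self.t_min}, {self.t_opt}, {self.t_max})"
                )
        elif not self.coefficients:
            raise RegistryError(f"{self.form} form requires coefficients")


@dataclass(frozen=True)
class DiapauseParams:
    """Photoperiod-driven diapause block (absent for Ae. aegypti)."""

    induction_a: float
    induction_b: float  # < 0: longer days induce less diapause
    hatch_threshold_hours: float
    degg_survival: ThermalFunction

    def __post_init__(self) -> None:
        if self.induction_b >= 0:
            raise RegistryError("diapause induction slope must be negative")


@dataclass(frozen=True)
class DispersalParams:
    meanlog: float
    sdlog: float
    car_entry_probability: float


@dataclass(frozen=True)
class DensityParams:
    """Log-linear density-dependent juvenile mortality: ln m = a + b*density."""

    intercept: float
    slope: float
    reference_volume_litres: float = 2.0


@dataclass(frozen=True)
class SpeciesParams:
    """Everything the engine needs to simulate one species."""

    species: str
    stage_durations: dict  # {"E": int, "J": int, "A": int}; Ed is a single pool
    sex_ratio: float
    clutch_size: int
    thermal_functions: dict  # event -> ThermalFunction
    diapause: DiapauseParams | None
    dispersal: DispersalParams
    density: DensityParams

    def __post_init__(self) -> None:
        for stage in ("E", "J", "A"):
            d = self.stage_durations.get(stage, 0)
            if not isinstance(d, int) or d < 1:
                raise RegistryError(f"{self.species}: stage duration {stage} must be >= 1")
        if self.stage_durations["A"] < 2:
            raise RegistryError(
                f"{self.species}: adult chain needs >= 2 sub-compartments "
                "(maturation + gonotrophic)"
            )
        for ev in THERMAL_EVENTS:
            if ev not in self.thermal_functions:
                raise RegistryError(f"{self.species}: missing thermal function {ev!r}")
        if self.species == "aegypti" and self.diapause is not None:
            raise RegistryError("aegypti must not carry a diapause block")

    @property
    def has_diapause(self) -> bool:
        return self.diapause is not None

    def replace(self, **changes) -> "SpeciesParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Defaults:
    jhwv_litres: float = 2.0
    intro_eggs: int = 100
    intro_deggs: int = 0
    intro_juveniles: int = 0
    intro_adults: int = 0
    cellsize_m: float = 250.0
    maxadisp_m: float = 600.0
    dispbins: int = 10
    sun_elevation_deg: float = 0.8333


@dataclass(frozen=True)
class Registry:
    species: dict  # name -> SpeciesParams
    defaults: Defaults
    country_trip_mean_m: dict

    def __getitem__(self, name: str) -> SpeciesParams:
        try:
            return self.species[name]
        except KeyError:
            raise RegistryError(
                f"unknown species {name!r}; known: {sorted(self.species)}"
            ) from None


def _parse_thermal(raw: dict) -> ThermalFunction:
    return ThermalFunction(
        form=raw["form"],
        coefficients=tuple(raw.get("coefficients", ())),
        rmax=raw.get("rmax"),
        t_opt=raw.get("t_opt"),
        t_min=raw.get("t_min"),
        t_max=raw.get("t_max"),
    )


def _parse_species(name: str, raw: dict, density: DensityParams) -> SpeciesParams:
    dia = None
    if raw.get("diapause"):
        d = raw["diapause"]
        ind = d["induction"]
        if ind.get("form") != "exponential_photoperiod":
            raise RegistryError(f"{name}: unsupported diapause induction form")
        dia = DiapauseParams(
            induction_a=float(ind["a"]),
            induction_b=float(ind["b"]),
            hatch_threshold_hours=float(d["hatch_threshold_hours"]),
            degg_survival=_parse_thermal(d["degg_survival"]),
        )
    disp = raw["dispersal"]
    return SpeciesParams(
        species=name,
        stage_durations=dict(raw["stage_durations"]),
        sex_ratio=float(raw["sex_ratio"]),
        clutch_size=int(raw["clutch_size"]),
        thermal_functions={
            ev: _parse_thermal(tf) for ev, tf in raw["thermal_functions"].items()
        },
        diapause=dia,
        dispersal=DispersalParams(
            meanlog=float(disp["meanlog"]),
            sdlog=float(disp["sdlog"]),
            car_entry_probability=float(disp["car_entry_probability"]),
        ),
        density=density,
    )


def load_registry(path: str | Path | None = None) -> Registry:
    """Load and validate the parameter registry (the shipped file by default)."""
    if path is None:
        ref = resources.files("aedespop").joinpath("data/species_params_synthetic.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    density = DensityParams(**raw["density_mortality"])
    species = {
        name: _parse_species(name, block, density)
        for name, block in raw["species"].items()
    }
    return Registry(
        species=species,
        defaults=Defaults(**raw.get("defaults", {})),
        country_trip_mean_m=dict(raw.get("country_trip_mean_m", {})),
    )


_DEFAULT_REGISTRY: Registry | None = None


def _default_registry() -> Registry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def get_species_params(species: str) -> SpeciesParams:
    """Resolved parameters for one species from the shipped registry."""
    return _default_registry()[species]
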