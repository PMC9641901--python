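"""Temperature-, density- and photoperiod-dependent event probabilities.

Every life-cycle event (hatching, development, survival, oviposition) is a
daily probability obtained by evaluating a stored curve from the species
registry and clamping the result to [0, 1].  Three curve families are
supported:

* Beta threshold curves (Yin parameterisation): zero at and outside a
  minimum/maximum temperature, unimodal with maximum ``rmax`` at ``t_opt``;
* polynomials in temperature (which may stray outside the unit interval at
  extreme temperatures — hence the clamp);
* exponentials ``a * exp(b * T)``.

Density-dependent juvenile mortality follows a log-linear law fitted to
container-experiment data: the natural log of the daily mortality rate is
linear in density (juveniles per litre).  The temperature and density daily
mortality *rates* are summed and converted to a survival probability as
``exp(-(m_T + m_D))``, the standard rate-to-probability mapping; this
conversion is isolated in :func:`juvenile_survival_probability` so an
alternative mapping can be swapped in one place.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .environment import Photoperiod
from .errors import NoDiapauseError, RegistryError
from .registry import SpeciesParams, ThermalFunction

__all__ = [
    "EVENTS",
    "beta_response",
    "event_probability",
    "density_mortality_rate",
    "fit_density_mortality",
    "juvenile_survival_probability",
    "diapause_fraction",
    "degg_hatch_allowed",
    "degg_survival_probability",
]

EVENTS = (
    "egg_hatch",
    "egg_survival",
    "degg_survival",
    "degg_hatch",
    "juvenile_development",
    "juvenile_survival",
    "adult_emergence_to_mature",
    "oviposition",
    "adult_survival",
)

_MIN_SURVIVAL_P = 1e-12  # floor before taking logs


def beta_response(
    t: float, rmax: float, t_opt: float, t_min: float, t_max: float
) -> float:
    """Beta threshold curve: 0 at/outside [t_min, t_max], maximum rmax at t_opt.

    Yin parameterisation:
    ``rmax * ((t_max - T)/(t_max - t_opt)) * ((T - t_min)/(t_opt - t_min))**c``
    with ``c = (t_opt - t_min)/(t_max - t_opt)``; continuous, unimodal, and
    exactly zero at both thresholds.
    """
    if t_min >= t_max:
        raise RegistryError(f"t_min ({t_min}) must be < t_max ({t_max})")
    if not t_min < t_opt < t_max:
        raise RegistryError("t_opt must lie strictly inside (t_min, t_max)")
    if t <= t_min or t >= t_max:
        return 0.0
    c = (t_opt - t_min) / (t_max - t_opt)
    return float(
        rmax
        * ((t_max - t) / (t_max - t_opt))
        * ((t - t_min) / (t_opt - t_min)) ** c
    )


def _evaluate(tf: ThermalFunction, t: float) -> float:
    if tf.form == "beta":
        return beta_response(t, tf.rmax, tf.t_opt, tf.t_min, tf.t_max)
    if tf.form == "polynomial":
        return float(np.polyval(tf.coefficients[::-1], t))
    if tf.form == "exponential":
        a, b = tf.coefficients
        return float(a * math.exp(b * t))
    raise RegistryError(f"unknown form {tf.form!r}")  # pragma: no cover


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def event_probability(event: str, t: float, params: SpeciesParams) -> float:
    """Daily probability of a life-cycle event at temperature ``t`` (deg C).

    Evaluates the stored registry curve for the event and clamps to [0, 1].
    ``degg_hatch`` shares the egg-hatch machinery (the photoperiod gate is
    applied by the caller); ``degg_survival`` dispatches to the
    species-specific diapausing-egg rule.  ``juvenile_survival`` here is the
    temperature-only component — density enters through
    :func:`juvenile_survival_probability`.
    """
    if event not in EVENTS:
        raise RegistryError(f"unknown event {event!r}; known: {EVENTS}")
    if event == "degg_survival":
        return degg_survival_probability(t, params)
    key = "egg_hatch" if event == "degg_hatch" else event
    tf = params.thermal_functions.get(key)
    if tf is None:
        raise RegistryError(f"{params.species}: no stored function for {event!r}")
    return _clamp01(_evaluate(tf, t))


def density_mortality_rate(density: float, params: SpeciesParams) -> float:
    """Daily juvenile mortality rate from larval density (per litre).

    ``exp(intercept + slope * density)`` — the fitted log-linear regression
    of daily mortality rates on rearing density.  At density 0 this is the
    regression intercept, a small baseline rate.
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    d = params.density
    return float(math.exp(d.intercept + d.slope * density))


def fit_density_mortality(
    density_per_litre, proportion_surviving, development_days
) -> tuple[float, float]:
    """Re-run the density-mortality calibration chain; returns (intercept, slope).

    Chain: whole-stage survival proportion -> cumulative mortality rate
    ``-ln(p)`` -> daily rate (divide by development time) -> linear
    regression of ``ln(rate)`` on density.
    """
    d = np.asarray(density_per_litre, dtype=float)
    p = np.asarray(proportion_surviving, dtype=float)
    t = np.asarray(development_days, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("proportions must be in (0, 1]")
    daily_rate = -np.log(p) / t
    slope, intercept = np.polyfit(d, np.log(daily_rate), 1)
    return float(intercept), float(slope)


def load_density_calibration() -> pd.DataFrame:
    """The shipped synthetic density-calibration table."""
    from importlib import resources

    ref = resources.files("aedespop").joinpath(
        "data/density_calibration_synthetic.csv"
    )
    with ref.open() as fh:
        return pd.read_csv(fh)


def juvenile_survival_probability(
    t: float, density: float, params: SpeciesParams
) -> float:
    """Daily juvenile survival combining temperature and density mortality.

    ``p = exp(-(m_T + m_D))`` where ``m_T = -ln(p_T)`` from the stored
    temperature survival curve and ``m_D`` is the log-linear density rate.
    Monotone non-increasing in density; in [0, 1] by construction.
    """
    p_t = event_probability("juvenile_survival", t, params)
    if p_t <= 0.0:
        return 0.0
    m_t = -math.log(max(p_t, _MIN_SURVIVAL_P))
    m_d = density_mortality_rate(density, params)
    return float(math.exp(-(m_t + m_d)))


def diapause_fraction(photoperiod_hours: float, params: SpeciesParams) -> float:
    """Fraction of newly laid eggs routed to the diapausing-egg compartment.

    Species-specific exponential in maternal photoperiod, clamped to [0, 1]:
    short autumn days route (nearly) the whole clutch to diapause, long
    summer days essentially none.
    """
    if not params.has_diapause:
        raise NoDiapauseError(f"{params.species} has no diapause block")
    d = params.diapause
    return _clamp01(math.exp(d.induction_a + d.induction_b * photoperiod_hours))


def degg_hatch_allowed(photoperiod: Photoperiod, params: SpeciesParams) -> bool:
    """Spring gate for diapausing-egg hatching.

    Open only under an increasing photoperiod regime at or above the
    species threshold (11.44 h albopictus; 10.71 h japonicus/koreicus).
    While closed, diapausing eggs never hatch regardless of temperature.
    """
    if not params.has_diapause:
        raise NoDiapauseError(f"{params.species} has no diapause block")
    return bool(
        photoperiod.increasing
        and photoperiod.hours >= params.diapause.hatch_threshold_hours
    )


def degg_survival_probability(t: float, params: SpeciesParams) -> float:
    """Daily survival of diapausing eggs.

    Constant 0.99 for japonicus/koreicus; a temperature exponential for
    albopictus (clamped to [0, 1]).
    """
    if not params.has_diapause:
        raise NoDiapauseError(f"{params.species} has no diapause block")
    return _clamp01(_evaluate(params.diapause.degg_survival, t))
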