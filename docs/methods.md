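# Methods

## Model structure

The simulator is a discrete-time (daily), discrete-space (lattice cell),
stage-structured stochastic model of container-breeding *Aedes* mosquito
populations. Four compartments per cell — eggs (E), diapausing eggs (Ed,
absent for *Ae. aegypti*), juveniles (J; larvae and pupae pooled, since
their thermal requirements are similar) and adult females (A) — are split
into daily sub-compartments whose number equals the species' minimum stage
duration. Every demographic event is a binomial draw
`Binomial(n, π)` with π the daily event probability. Only females are
modelled: a 1:1 sex-ratio thinning (registry constant) is applied at adult
emergence.

### Within-day event order

The daily update applies, in this fixed order:

1. **Survival** draws for every sub-compartment (egg, diapausing-egg,
   juvenile, adult survival probabilities at the cell's temperature).
2. **Transitions** from terminal sub-compartments: egg hatch → J,
   diapausing-egg hatch → J (only while the spring photoperiod gate is
   open; the same hatch probability machinery as E), juvenile emergence →
   A (thinned by sex ratio and an emergence-to-maturity probability).
3. **Aging**: sub-compartments shift by one day; the terminal
   sub-compartment pools individuals that completed the minimum residence
   but failed the transition draw — minimum durations are floors, not
   fixed durations. Transition entrants land in the youngest
   sub-compartment afterwards, so they cannot transition again the same day.
4. **Dispersal** (local scale only), active then passive.
5. **Oviposition** by gonotrophically competent females (terminal adult
   sub-compartment): each layer deposits a fixed clutch, split between E
   and Ed by the diapause-induction fraction, and re-enters the start of
   the gonotrophic chain (adult sub-compartment 1; sub-compartment 0 is
   the post-emergence maturation day). With an adult chain of length
   `d_A`, consecutive ovipositions are therefore at least `d_A - 2` days
   apart.

New eggs appear after all other events, which preserves the structural
development minima: with all probabilities forced to 1 the first adults
emerge exactly on day `d_E + d_J` (11 for *aegypti*/*albopictus*, 21 for
*japonicus*/*koreicus*) — this is what `scripts/acceptance.py` measures.
The within-day order itself is a documented design choice; alternatives
(e.g. oviposition before aging) would shift event timing by at most one
day but are not claimed equivalent.

## Event probabilities

Stored per species in a YAML registry, three functional forms:

* **Beta threshold** (Yin parameterisation): zero at and outside
  `[T_min, T_max]`, unimodal with maximum `rmax` at `T_opt`. Used for
  hatching, juvenile development and oviposition — processes with hard
  thermal limits.
* **Polynomial** in T (quadratics here): used for daily survival curves;
  polynomials can stray outside the unit interval at extreme temperatures,
  so every evaluated probability is clamped to [0, 1].
* **Exponential** `a·exp(bT)`: the *albopictus* diapausing-egg survival.

**Density-dependent juvenile mortality.** The natural log of the daily
juvenile mortality rate is linear in larval density (juveniles per litre):
`m_D = exp(intercept + slope·density)`, with density computed as juveniles
in the cell divided by the habitat water volume `jhwv` (default 2 L, the
volume of the calibration container experiments). The temperature and
density mortality *rates* are summed and converted to a survival
probability as `p = exp(-(m_T + m_D))` where `m_T = -ln(p_T)`. This
standard rate→probability mapping guarantees [0, 1] and is isolated in one
function (`juvenile_survival_probability`) so an alternative such as
`1 - min(1, m_T + m_D)` can be swapped. Note `m_D(0) = exp(intercept)` is
a small nonzero baseline (≈9·10⁻⁴/day with the shipped registry), so
survival at zero density is within ~0.1% of the pure temperature curve.
The shipped calibration table
(`data/density_calibration_synthetic.csv`) is generated exactly from this
log-linear law, so re-running the calibration chain (survival proportion →
cumulative mortality rate → daily rate → log regression on density)
recovers the registry coefficients to machine precision; this is a
consistency check of the transformation chain, not an independent
empirical calibration.

**Diapause.** Induction: the fraction of a clutch laid as diapausing eggs
is `min(1, exp(a + b·h))` in daylength *h*, decreasing in *h* —
essentially 1 below ~10 h and ≤1% above 16 h, with 50% induction near
13.5 h for *albopictus* and near 11 h for *japonicus* (reused unchanged
for *koreicus*). Termination: diapausing eggs may hatch only under an
increasing day-over-day photoperiod at or above the species threshold
(11.44 h *albopictus*; 10.71 h *japonicus*/*koreicus*); while the gate is
closed they never hatch regardless of temperature. Diapausing-egg daily
survival is constant 0.99 for *japonicus*/*koreicus* and an exponential in
temperature for *albopictus*.

## Photoperiod

Daylength comes from the Forsythe et al. (1995) model with a configurable
sun-elevation threshold, default 0.8333° below the horizon (standard
sunrise/sunset including refraction). The supported band is |lat| ≤ 66.5°
(no polar day/night handling). The tests verify agreement within 0.1 h
against an independent oracle (Spencer declination + minute-scan of solar
elevation) over a |lat| ≤ 60° grid; the measured worst-case discrepancy is
~0.02 h. The day-over-day trend (increasing/decreasing) drives the diapause
hatching gate; it flips exactly twice a year at non-polar latitudes. A
civil-twilight threshold (6°) would lengthen daylength by roughly 0.8 h and
shift diapause phenology by 1–2 weeks; the threshold is a registry constant
precisely so it can be recalibrated.

## Spatial scales and dispersal

* `ws` — one cell, no space, no dispersal.
* `rg` — many closed cells; introductions happen in every cell at the same
  time; no dispersal. Each cell's trajectory is bitwise identical to a
  punctual run of that cell under the shared stream (verified in the
  acceptance suite).
* `lc` — lattice with dispersal. **Active**: flight distances follow a
  species log-normal, discretised into `dispbins` bins between `cellsize`
  (250 m default) and `maxadisp` (600 m default); mass below the cell size
  is "stay", mass beyond the maximum is truncated and the simplex
  renormalised. Direction is isotropic: movers pick uniformly among cells
  whose centre distance falls in the drawn bin; if the annulus is empty
  (lattice edge) they stay, so adult counts are conserved exactly.
  **Passive**: adults in road-network cells board a car with a small
  probability (registry constant, generalised from *albopictus* data);
  trip length is exponential with the country-specific mean (France,
  Germany, Italy, Poland, Spain, UK, or a numeric override), truncated to
  the network extent, and the passenger alights at the road cell with the
  nearest along-road distance. The exponential family is a pragmatic
  one-parameter choice matching the available "mean trip distance"
  information; it is a config switch, not a claim about trip-length tails.
  All adult sub-compartments are dispersal-eligible daily; dispersal runs
  after aging and before oviposition, so eggs are laid where the female
  ends her day. Eggs and juveniles never move.

## Randomness and reproducibility

One master seed. Per-iteration stream seeds come from
`SeedSequence([master, iteration])`; within an iteration each cell has its
own generator keyed by `SeedSequence([iteration_seed, crc32(cell_id)])`,
and cross-cell dispersal uses a separate per-iteration stream. Hence
(i) iterations are embarrassingly parallel and results are independent of
worker count, (ii) regional per-cell trajectories are reproducible by
punctual runs sharing the cell id, and (iii) a local-scale run whose
kernel collapses onto "stay" (cellsize = maxadisp) with no road network
equals the matching regional run bitwise. Extinction is absorbing: once
the total count is zero the day loop short-circuits (a zero-count cell
consumes no random draws, so the shortcut does not perturb streams).

## Synthetic inputs and what they do not show

The weather generator is a sinusoidal annual cycle (coldest on 1 January)
plus i.i.d. Gaussian noise, optionally with per-cell mean offsets. It
emulates the seasonality and day-to-day variability of temperate daily
mean temperatures but **not** autocorrelated weather regimes, heat waves,
urban heat islands, inter-annual variability or spatial covariance —
passing tests demonstrate the engine's internal correctness and the
qualitative phenology (spring hatch, summer peak, autumn diapause,
overwinter survival), not calibrated predictions for any real location.
Likewise the parameter registry is a labelled synthetic reconstruction:
quantities printed in the primary literature (stage-duration minima,
diapause thresholds, diapausing-egg survival constant, tool defaults) are
exact, while curve coefficients are literature-shaped stand-ins, so
absolute abundances are indicative only.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [0, 1] after every curve evaluation;
  `binomial_event` rejects p outside [0, 1] as an upstream failure.
* Temperature tables must be complete; gap-filling is an explicit linear
  interpolation step that refuses leading/trailing gaps (no extrapolation).
* Dates are proleptic Gregorian with leap days; day-of-year comes from the
  actual calendar date. Integer-rounding of temperatures is an optional
  load flag, never engine behaviour.
* Quantile summaries use linear interpolation (numpy default); ROC AUC uses
  average ranks (ties get half credit) with a DeLong normal-approximation
  CI clipped to [0, 1].
* An empty annulus or empty multinomial bin in dispersal degrades to
  "stay"; a single-cell lattice short-circuits dispersal entirely.
* `SimulationConfig` validation is fail-fast before any computation
  (scale/matrix consistency, date alignment, introduction stages valid for
  the species).

## Problem sizes

The test and acceptance workloads are deliberately desk-scale: the
regional consistency check uses 80 iterations × 1 year × 10 cells
(≈7 s), kernel checks use 10⁵ movers on a 21×21 lattice, and the binomial
engine check uses 10⁴ draws. Multi-year, many-cell runs scale linearly in
cells × days × iterations and parallelise across iterations (`n_jobs`).

## Known limitations

Precipitation, humidity-driven egg desiccation, inter-specific
competition, predation, male dynamics, explicit blood-meal hosts and
evolutionary processes are out of scope by design. The within-day event
order and the oviposition re-entry point in the gonotrophic chain are
documented conventions, not field-validated facts. Passive dispersal
ignores traffic volume and rail/air pathways. The model is best suited to
temperate climates where temperature seasonality is the binding
constraint.
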