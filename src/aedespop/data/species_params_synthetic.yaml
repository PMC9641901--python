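# Species parameter registry — SYNTHETIC reconstruction.
#
# Values printed in the primary literature are exact and marked [printed]:
# stage-duration sums (minimum egg-to-adult development of 11 days for
# Ae. aegypti / Ae. albopictus and 21 days for Ae. japonicus / Ae. koreicus),
# the constant 0.99 daily survival of diapausing eggs for japonicus/koreicus,
# the spring hatching photoperiod thresholds (11.44 h albopictus, 10.71 h
# japonicus/koreicus), the reuse of the japonicus diapause-induction function
# for koreicus, and the package defaults (jhwv 2 L, cellsize 250 m,
# maxadisp 600 m, dispbins 10, intro.eggs 100).
#
# All remaining curve coefficients are SYNTHETIC: plausible values shaped by
# the thermal-biology literature for each species (warm-adapted aegypti /
# albopictus, cool-adapted japonicus / koreicus) but NOT transcriptions of
# any published calibration.  They are config, not code: drop in an updated
# calibration without touching the engine.
#
# Thermal function forms:
#   beta        — Yin/Beta threshold curve: zero at/outside [t_min, t_max],
#                 maximum rmax at t_opt.
#   polynomial  — coefficients [c0, c1, c2, ...] of c0 + c1*T + c2*T^2 + ...
#   exponential — a * exp(b * T).
# Every evaluated probability is clamped to [0, 1] downstream.

defaults:
  jhwv_litres: 2.0          # [printed] juvenile-habitat water volume default
  intro_eggs: 100           # [printed]
  intro_deggs: 0            # [printed]
  intro_juveniles: 0        # [printed]
  intro_adults: 0           # [printed]
  cellsize_m: 250.0         # [printed] kernel minimum distance / cell size
  maxadisp_m: 600.0         # [printed] maximum daily active dispersal
  dispbins: 10              # [printed] kernel resolution
  sun_elevation_deg: 0.8333 # daylength threshold (sunrise/sunset w/ refraction)

# Mean distance of a single car trip (metres), used by passive dispersal.
# Country list is [printed]; the numeric means are synthetic approximations.
country_trip_mean_m:
  France: 9000.0
  Germany: 10200.0
  Italy: 8100.0
  Poland: 7700.0
  Spain: 8600.0
  UK: 9500.0

# Density-dependent juvenile mortality (shared across species; calibrated on
# Ae. aegypti and generalised).  ln(daily mortality rate) = intercept +
# slope * density, density in juveniles per litre, reference habitat 2 L.
# Coefficients are the exact fit to data/density_calibration_synthetic.csv.
density_mortality:
  intercept: -7.0
  slope: 0.03
  reference_volume_litres: 2.0

species:
  aegypti:
    stage_durations: {E: 3, J: 8, A: 4}   # E+J = 11 [printed]
    sex_ratio: 0.5
    clutch_size: 60
    diapause: null                        # no diapause block [printed]
    thermal_functions:
      egg_hatch:        {form: beta, rmax: 0.68, t_opt: 30.0, t_min: 14.0, t_max: 42.0}
      egg_survival:     {form: polynomial, coefficients: [0.4492, 0.0416, -0.0008]}
      juvenile_survival: {form: polynomial, coefficients: [-0.3622, 0.0972, -0.0018]}
      juvenile_development: {form: beta, rmax: 0.35, t_opt: 30.0, t_min: 12.0, t_max: 40.0}
      adult_survival:   {form: polynomial, coefficients: [0.0352, 0.0648, -0.0012]}
      adult_emergence_to_mature: {form: polynomial, coefficients: [0.2439, 0.0486, -0.0009]}
      oviposition:      {form: beta, rmax: 0.80, t_opt: 29.0, t_min: 15.0, t_max: 40.0}
    dispersal: {meanlog: 4.60, sdlog: 0.70, car_entry_probability: 0.0051}

  albopictus:
    stage_durations: {E: 3, J: 8, A: 4}   # E+J = 11 [printed]
    sex_ratio: 0.5
    clutch_size: 55
    diapause:
      induction: {form: exponential_photoperiod, a: 20.43, b: -1.5648}
      hatch_threshold_hours: 11.44        # [printed]
      degg_survival: {form: exponential, coefficients: [0.98, 0.005]}
    thermal_functions:
      egg_hatch:        {form: beta, rmax: 0.62, t_opt: 28.0, t_min: 11.0, t_max: 38.0}
      egg_survival:     {form: polynomial, coefficients: [0.5868, 0.0336, -0.0007]}
      juvenile_survival: {form: polynomial, coefficients: [-0.1316, 0.0832, -0.0016]}
      juvenile_development: {form: beta, rmax: 0.32, t_opt: 28.0, t_min: 10.5, t_max: 38.0}
      adult_survival:   {form: polynomial, coefficients: [0.1764, 0.0572, -0.0011]}
      adult_emergence_to_mature: {form: polynomial, coefficients: [0.2916, 0.0468, -0.0009]}
      oviposition:      {form: beta, rmax: 0.78, t_opt: 27.0, t_min: 13.0, t_max: 38.0}
    dispersal: {meanlog: 4.95, sdlog: 0.80, car_entry_probability: 0.0051}

  japonicus:
    stage_durations: {E: 7, J: 14, A: 5}  # E+J = 21 [printed]
    sex_ratio: 0.5
    clutch_size: 45
    diapause:
      induction: {form: exponential_photoperiod, a: 13.65, b: -1.304}
      hatch_threshold_hours: 10.71        # [printed]
      degg_survival: {form: polynomial, coefficients: [0.99]}  # constant [printed]
    thermal_functions:
      egg_hatch:        {form: beta, rmax: 0.50, t_opt: 24.0, t_min: 6.0, t_max: 36.0}
      egg_survival:     {form: polynomial, coefficients: [0.75, 0.024, -0.0006]}
      juvenile_survival: {form: polynomial, coefficients: [0.2724, 0.0616, -0.0014]}
      juvenile_development: {form: beta, rmax: 0.25, t_opt: 25.0, t_min: 7.0, t_max: 35.0}
      adult_survival:   {form: polynomial, coefficients: [0.436, 0.044, -0.0010]}
      adult_emergence_to_mature: {form: polynomial, coefficients: [0.5128, 0.0352, -0.0008]}
      oviposition:      {form: beta, rmax: 0.70, t_opt: 24.0, t_min: 10.0, t_max: 34.0}
    dispersal: {meanlog: 4.95, sdlog: 0.80, car_entry_probability: 0.0051}

  koreicus:
    stage_durations: {E: 7, J: 14, A: 5}  # E+J = 21 [printed]
    sex_ratio: 0.5
    clutch_size: 45
    diapause:
      # induction reuses the japonicus function exactly [printed]
      induction: {form: exponential_photoperiod, a: 13.65, b: -1.304}
      hatch_threshold_hours: 10.71        # [printed]
      degg_survival: {form: polynomial, coefficients: [0.99]}  # constant [printed]
    thermal_functions:
      egg_hatch:        {form: beta, rmax: 0.50, t_opt: 23.0, t_min: 5.0, t_max: 35.0}
      egg_survival:     {form: polynomial, coefficients: [0.7734, 0.0228, -0.0006]}
      juvenile_survival: {form: polynomial, coefficients: [0.3326, 0.0588, -0.0014]}
      juvenile_development: {form: beta, rmax: 0.25, t_opt: 24.0, t_min: 6.0, t_max: 34.0}
      adult_survival:   {form: polynomial, coefficients: [0.479, 0.042, -0.0010]}
      adult_emergence_to_mature: {form: polynomial, coefficients: [0.5472, 0.0336, -0.0008]}
      oviposition:      {form: beta, rmax: 0.70, t_opt: 23.0, t_min: 9.0, t_max: 34.0}
    dispersal: {meanlog: 4.95, sdlog: 0.80, car_entry_probability: 0.0051}
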