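"""Daily engine: binomial events, stage structure, conservation, diapause routing."""

from collections import Counter

import numpy as np
import pytest

import aedespop as ap
from aedespop.errors import NoDiapauseError
from aedespop.lifecycle import PopulationState, daily_step

WARM = ap.Photoperiod(hours=15.0, increasing=True)
AUTUMN = ap.Photoperiod(hours=9.0, increasing=False)


def rng_for(n_cells=1, seed=0):
    return [np.random.default_rng([seed, c]) for c in range(n_cells)]


class TestBinomialEvent:
    def test_certain_death_and_certain_survival(self):
        rng = np.random.default_rng(0)
        assert ap.binomial_event(1000, 0.0, rng) == 0
        assert ap.binomial_event(1000, 1.0, rng) == 1000

    def test_invalid_probability_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ap.binomial_event(10, 1.5, rng)
        with pytest.raises(ValueError):
            ap.binomial_event(10, -0.1, rng)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ap.binomial_event(-1, 0.5, np.random.default_rng(0))

    def test_monte_carlo_mean_and_variance(self):
        rng = np.random.default_rng(123)
        draws = np.array([ap.binomial_event(100, 0.3, rng) for _ in range(10_000)])
        mean_se = np.sqrt(100 * 0.3 * 0.7 / 10_000)
        assert abs(draws.mean() - 30.0) < 3 * mean_se
        assert abs(draws.var() - 21.0) < 0.1 * 21.0


class TestIntroduce:
    def test_total_matches_introduction(self, aegypti):
        st = PopulationState.empty(1, aegypti)
        st = ap.introduce(st, "E", 100, params=aegypti)
        assert st.total() == 100
        assert st.counts["E"][0, 0] == 100

    def test_zero_introduction_is_noop(self, aegypti):
        st = PopulationState.empty(1, aegypti)
        assert ap.introduce(st, "E", 0, params=aegypti).total() == 0

    def test_per_cell_introduction(self, albopictus):
        st = PopulationState.empty(5, albopictus)
        st = ap.introduce(st, "E", 500, cells=[0, 2, 4], params=albopictus)
        np.testing.assert_array_equal(st.counts["E"][:, 0], [500, 0, 500, 0, 500])

    def test_diapausing_eggs_rejected_for_aegypti(self, aegypti):
        st = PopulationState.empty(1, aegypti)
        with pytest.raises(NoDiapauseError):
            ap.introduce(st, "Ed", 10, params=aegypti)


class TestStructuralMinima:
    @pytest.mark.parametrize(
        "species,expected",
        [("aegypti", 11), ("albopictus", 11), ("japonicus", 21), ("koreicus", 21)],
    )
    def test_min_emergence_day(self, species, expected):
        assert ap.min_emergence_day(ap.get_species_params(species)) == expected

    @pytest.mark.parametrize("species", ["aegypti", "koreicus"])
    def test_first_emergence_in_forced_simulation(self, species):
        """With every probability forced to 1, the first adults appear exactly
        on the structural minimum day."""
        params = ap.get_species_params(species)
        st = ap.introduce(PopulationState.empty(1, params), "E", 100, params=params)
        rngs = rng_for()
        first = None
        for day in range(1, 30):
            st, _ = daily_step(st, [25.0], WARM, params, rngs, probability_override=1.0)
            if first is None and st.counts["A"].sum() > 0:
                first = day
        assert first == ap.min_emergence_day(params)


def cohort_oracle(params, n_eggs: int, days: int) -> list:
    """Independent deterministic ledger of the forced (p = 1) skeleton.

    Tracks (stage, age-in-stage) cohorts with plain dict arithmetic and the
    documented rules: transition from the terminal age, then aging, then
    oviposition by terminal adults (clutch into new eggs, layer returns to
    adult age 1).  Returns per-day [E, J, A] totals.
    """
    d_e, d_j, d_a = (params.stage_durations[s] for s in ("E", "J", "A"))
    state = Counter({("E", 0): n_eggs})
    out = []
    for _ in range(days):
        nxt = Counter()
        entrants = Counter()
        for (stage, age), n in state.items():
            if stage == "E" and age == d_e - 1:
                entrants[("J", 0)] += n
            elif stage == "J" and age == d_j - 1:
                entrants[("A", 0)] += n  # sex ratio forced to 1 in this check
            else:
                cap = {"E": d_e, "J": d_j, "A": d_a}[stage] - 1
                nxt[(stage, min(age + 1, cap))] += n
        nxt.update(entrants)
        layers = nxt.pop(("A", d_a - 1), 0)
        if layers:
            nxt[("E", 0)] += layers * params.clutch_size
            nxt[("A", 1)] += layers
        state = nxt
        out.append([
            sum(n for (s, _), n in state.items() if s == "E"),
            sum(n for (s, _), n in state.items() if s == "J"),
            sum(n for (s, _), n in state.items() if s == "A"),
        ])
    return out


class TestDeterministicSkeleton:
    def test_forced_engine_matches_cohort_ledger(self, aegypti):
        """The p=1 engine reproduces an independently coded cohort ledger
        (including two oviposition generations) over 30 days."""
        params = aegypti.replace(sex_ratio=1.0)
        expected = cohort_oracle(params, 100, 30)
        st = ap.introduce(PopulationState.empty(1, params), "E", 100, params=params)
        rngs = rng_for()
        for day in range(30):
            st, _ = daily_step(st, [25.0], WARM, params, rngs, probability_override=1.0)
            got = [int(st.counts["E"].sum()), int(st.counts["J"].sum()),
                   int(st.counts["A"].sum())]
            assert got == expected[day], f"day {day + 1}"


class TestDailyStepBehaviour:
    def test_empty_state_is_absorbing(self, albopictus):
        st = PopulationState.empty(2, albopictus)
        rngs = rng_for(2)
        for _ in range(10):
            st, _ = daily_step(st, [20.0, 25.0], WARM, albopictus, rngs)
        assert st.total() == 0

    def test_lethal_cold_extinguishes_eggs(self, albopictus):
        st = ap.introduce(PopulationState.empty(1, albopictus), "E", 1000, params=albopictus)
        rngs = rng_for()
        for _ in range(10):
            st, _ = daily_step(st, [-30.0], AUTUMN, albopictus, rngs)
        assert st.total() == 0

    def test_missing_temperature_rejected(self, albopictus):
        st = PopulationState.empty(2, albopictus)
        with pytest.raises(Exception):
            daily_step(st, [20.0], WARM, albopictus, rng_for(2))

    def test_counts_stay_integer_and_nonnegative(self, albopictus):
        st = ap.introduce(PopulationState.empty(1, albopictus), "E", 5000, params=albopictus)
        st = ap.introduce(st, "A", 200, params=albopictus)
        rngs = rng_for(seed=7)
        for day in range(60):
            st, _ = daily_step(st, [24.0], WARM, albopictus, rngs)
            for arr in st.counts.values():
                if arr is not None:
                    assert arr.dtype == np.int64
                    assert (arr >= 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_survival_and_transition_conservation(self, albopictus, seed):
        """No stage gains more than its sources lose; adults only grow via
        juvenile emergence; eggs only via oviposition."""
        rng = np.random.default_rng(seed)
        st = PopulationState.empty(1, albopictus)
        for stage, hi in (("E", 3000), ("Ed", 500), ("J", 800), ("A", 300)):
            st.counts[stage][0] = rng.integers(0, hi, size=st.counts[stage].shape[1])
        pre = {s: int(a.sum()) for s, a in st.counts.items()}
        pre_j_term = int(st.counts["J"][0, -1])
        new, stats = daily_step(st, [22.0], WARM, albopictus, rng_for(seed=seed))
        post = {s: int(a.sum()) for s, a in new.counts.items()}
        assert post["A"] <= pre["A"] + pre_j_term  # emergence bounded by source
        assert post["J"] <= pre["J"] + pre["E"] + pre["Ed"]
        assert post["E"] <= pre["E"] + int(stats.eggs_to_e.sum())
        assert post["Ed"] <= pre["Ed"] + int(stats.eggs_to_ed.sum())

    @pytest.mark.parametrize("photoperiod", [WARM, AUTUMN, ap.Photoperiod(12.5, True)])
    def test_diapause_routing_conserves_clutches(self, albopictus, photoperiod):
        st = PopulationState.empty(1, albopictus)
        st.counts["A"][0, -1] = 500  # gonotrophically competent females
        _, stats = daily_step(st, [25.0], photoperiod, albopictus, rng_for(seed=3))
        assert (stats.eggs_laid == stats.eggs_to_e + stats.eggs_to_ed).all()
        if photoperiod.hours <= 9.0:
            assert stats.eggs_to_e.sum() == 0  # deep autumn: everything diapauses
        if photoperiod.hours >= 15.0:
            # long days: induction is a small tail fraction, not a route
            assert stats.eggs_to_ed.sum() <= 0.1 * stats.eggs_laid.sum()

    def test_diapausing_eggs_never_hatch_while_gate_closed(self, albopictus):
        st = PopulationState.empty(1, albopictus)
        st.counts["Ed"][0, 0] = 10_000
        closed = ap.Photoperiod(hours=14.0, increasing=False)  # warm but decreasing
        new, _ = daily_step(st, [28.0], closed, albopictus, rng_for(seed=1))
        assert new.counts["J"].sum() == 0

    def test_diapausing_eggs_hatch_when_gate_opens(self, albopictus):
        st = PopulationState.empty(1, albopictus)
        st.counts["Ed"][0, 0] = 10_000
        opened = ap.Photoperiod(hours=12.0, increasing=True)
        new, _ = daily_step(st, [28.0], opened, albopictus, rng_for(seed=1))
        assert new.counts["J"].sum() > 0
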