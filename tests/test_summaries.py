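"""Post-processing summaries against brute-force oracles on toy trajectories."""

import numpy as np
import pandas as pd
import pytest

import aedespop as ap
from aedespop.errors import ConfigurationError
from conftest import make_result


class TestPsi:
    def test_all_extinct(self):
        r = make_result(np.zeros((4, 3, 2, 4)))
        assert ap.psi(r, "2014-01-03") == 0.0

    def test_all_viable(self):
        counts = np.ones((4, 3, 2, 4))
        assert ap.psi(make_result(counts), "2014-01-02") == 1.0

    def test_fraction_viable(self):
        counts = np.zeros((80, 2, 1, 4))
        counts[:40, 1, 0, 3] = 5  # 40 of 80 iterations viable on day 2
        assert ap.psi(make_result(counts), "2014-01-02") == 0.5

    def test_per_cell_mode(self):
        counts = np.zeros((4, 2, 3, 4))
        counts[:2, 1, 0, 0] = 1  # cell 0 viable in half the iterations
        s = ap.psi(make_result(counts), "2014-01-02", per_cell=True)
        assert list(s) == [0.5, 0.0, 0.0]

    def test_date_out_of_range(self):
        with pytest.raises(ValueError):
            ap.psi(make_result(np.zeros((2, 3, 1, 4))), "2015-01-01")

    def test_monotone_non_increasing_without_reintroduction(self, punctual_warm):
        """Extinction is absorbing, so the viable fraction can only fall."""
        temps = punctual_warm.temps.window("2014-05-15", "2015-05-14")
        cfg = ap.SimulationConfig(species="albopictus", start_date="2014-05-15",
                                  end_date="2015-05-14", iterations=10, seed=2,
                                  latitude=45.0, intro_eggs=50)
        r = ap.run(cfg, temps)
        series = [ap.psi(r, d) for d in r.dates[::14]]
        assert all(a >= b for a, b in zip(series, series[1:]))


class TestAdci:
    def test_identical_iterations_collapse_to_the_trajectory(self):
        one = np.arange(24).reshape(1, 3, 2, 4)
        r = make_result(np.repeat(one, 5, axis=0))
        out = ap.adci(r)
        for stage_idx, stage in enumerate(("E", "Ed", "J", "A")):
            block = out[out["stage"] == stage]
            expected = one[0, :, :, stage_idx].sum(axis=1)
            for col in ("q25", "q50", "q75"):
                np.testing.assert_allclose(block[col].to_numpy(), expected)

    def test_default_quantiles_are_interquartile(self):
        r = make_result(np.zeros((3, 2, 1, 4)))
        assert list(ap.adci(r).columns) == ["stage", "q25", "q50", "q75"]

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(5, 4, 2, 4))
        r = make_result(counts)
        out = ap.adci(r, quantiles=(0.5,), stage="J")
        j = counts[:, :, :, 2].sum(axis=2)  # (iterations, days)
        for d in range(4):
            med = sorted(j[:, d])[2]  # exact median of 5 values
            assert out["q50"].iloc[d] == med

    def test_invalid_quantiles_rejected(self):
        r = make_result(np.zeros((2, 2, 1, 4)))
        with pytest.raises(ValueError):
            ap.adci(r, quantiles=(0.0, 0.5))


class TestIcci:
    def test_counts_occupied_cells_against_brute_force(self):
        rng = np.random.default_rng(1)
        counts = (rng.random((6, 5, 9, 4)) < 0.3).astype(np.int64)
        r = make_result(counts)
        out = ap.icci(r, quantiles=(0.5,))
        for d in range(5):
            occ = sorted(
                sum(counts[i, d, c].sum() > 0 for c in range(9)) for i in range(6)
            )
            med = 0.5 * (occ[2] + occ[3])
            assert out["q50"].iloc[d] == med

    def test_single_viable_cell(self):
        counts = np.zeros((2, 2, 3, 4))
        counts[:, :, 1, 0] = 7
        out = ap.icci(make_result(counts), quantiles=(0.5,))
        assert (out["q50"] == 1).all()

    def test_non_spatial_result_rejected(self):
        with pytest.raises(ConfigurationError):
            ap.icci(make_result(np.zeros((2, 2, 1, 4)), scale="ws"))


class TestDici:
    def test_invaded_area_quantiles(self):
        counts = np.zeros((2, 2, 20, 4))
        counts[:, 1, :16, 0] = 1  # 16 occupied cells on day 2
        out = ap.dici(make_result(counts, scale="lc", cellsize=250.0), quantiles=(0.5,))
        assert out["q50"].iloc[0] == 0.0
        assert out["q50"].iloc[1] == pytest.approx(1.0)  # 16 * 0.0625 km^2

    def test_requires_local_scale(self):
        with pytest.raises(ConfigurationError):
            ap.dici(make_result(np.zeros((2, 2, 4, 4)), scale="rg"))


class TestEstablishmentMap:
    def test_threshold_classification(self):
        counts = np.zeros((80, 2, 2, 4))
        counts[0, 1, 0, 0] = 3  # cell 0 viable in exactly 1 of 80 iterations
        m = ap.establishment_map(make_result(counts))
        assert m.loc["c0", "psi"] == pytest.approx(0.0125)
        assert bool(m.loc["c0", "positive"]) is True  # 1.25% >= 1%
        assert m.loc["c1", "psi"] == 0.0
        assert bool(m.loc["c1", "positive"]) is False

    def test_values_equal_per_cell_psi(self):
        rng = np.random.default_rng(3)
        counts = (rng.random((10, 3, 4, 4)) < 0.4).astype(np.int64)
        r = make_result(counts)
        m = ap.establishment_map(r)
        expected = ap.psi(r, r.dates[-1], per_cell=True)
        np.testing.assert_allclose(m["psi"].to_numpy(), expected.to_numpy())


class TestValidateRanking:
    def test_perfect_separation(self):
        out = ap.validate_ranking([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert out["auc"] == 1.0

    def test_constant_scores_give_half(self):
        out = ap.validate_ranking([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert out["auc"] == 0.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.random(10), 1)  # rounded: forces some ties
        labels = np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 0], dtype=bool)
        out = ap.validate_ranking(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert out["auc"] == pytest.approx(wins / (pos.size * neg.size))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.random(30) < 0.4
        a = ap.validate_ranking(scores, labels)["auc"]
        b = ap.validate_ranking(np.exp(5 * scores), labels)["auc"]
        assert a == pytest.approx(b)

    def test_operating_threshold_metrics(self):
        out = ap.validate_ranking([0.5, 0.005, 0.2, 0.001], [1, 1, 0, 0],
                                  operating_threshold=0.01)
        assert out["sensitivity"] == 0.5
        assert out["specificity"] == 0.5
        assert out["sensitivity_at_1pct"] == 0.5

    def test_ci_contains_point_estimate(self):
        out = ap.validate_ranking([0.9, 0.7, 0.4, 0.1, 0.3, 0.8], [1, 1, 0, 0, 0, 1])
        lo, hi = out["auc_ci"]
        assert lo <= out["auc"] <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ap.validate_ranking([0.1, 0.2], [1, 1])


class TestCompareSeries:
    def _series(self, values, start="2014-01-01", freq="D"):
        return pd.Series(values, index=pd.date_range(start, periods=len(values), freq=freq))

    def test_identical_series_give_rho_one(self):
        sim = self._series(np.arange(12, dtype=float) % 7 + 1, freq="W")
        out = ap.compare_series(sim, sim.copy())
        assert out["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        sim = self._series(np.arange(12, dtype=float), freq="W")
        obs = self._series(np.arange(12, 0, -1, dtype=float), freq="W")
        out = ap.compare_series(sim, obs, aggregation="weekly")
        assert out["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(6)
        sim = self._series(rng.random(12), freq="W")
        obs = self._series(rng.random(12), freq="W")
        out = ap.compare_series(sim, obs)
        # definition: Pearson correlation of the rank vectors
        from scipy.stats import rankdata

        rs, ro = rankdata(sim.to_numpy()), rankdata(obs.to_numpy())
        expected = np.corrcoef(rs, ro)[0, 1]
        assert out["rho"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        sim = self._series(np.arange(5, dtype=float))
        obs = self._series(np.arange(5, dtype=float), start="2019-01-01")
        with pytest.raises(ValueError):
            ap.compare_series(sim, obs)

    def test_monthly_aggregation_and_catch_rate(self):
        sim = self._series(np.arange(180, dtype=float))
        obs = self._series(np.arange(180, dtype=float))
        out = ap.compare_series(sim, obs, aggregation="monthly", catch_rate=0.157)
        assert out["rho"] == pytest.approx(1.0)
        assert out["n_periods"] >= 5
        assert out["catch_rate"] == 0.157
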