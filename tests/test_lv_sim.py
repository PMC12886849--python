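import numpy as np
import pytest

from lagturn import lv_sim
from lagturn.lv_sim import (
    LVTrajectory,
    competition_moments,
    factorial_experiment,
    factorial_plan,
    fit_surface,
    integrate,
    s_esi,
    sample_params,
    sim_turnover,
    suitability,
)
from lagturn.similarity import mean_similarity_by_lag, rarefied_pair_similarities
from lagturn.turnover import turnover_rate


class TestStructuralInstabilityThreshold:
    def test_reference_competition_ensemble(self):
        mean, var = competition_moments()
        assert mean == pytest.approx(0.16)
        assert var == pytest.approx(0.0384)
        assert s_esi(mean, var) == pytest.approx(18.375, abs=1e-9)

    def test_unit_case(self):
        assert s_esi(0.0, 1.0) == 1.0

    def test_pool_size_eighty_fold(self):
        assert 80 * s_esi(*competition_moments()) == pytest.approx(1470.0, abs=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            s_esi(0.16, 0.0)
        with pytest.raises(ValueError):
            s_esi(1.1, 0.5)


class TestSampleParams:
    def test_ensemble_moments(self):
        p = sample_params(2000, seed=0)
        off = p.A[~np.eye(2000, dtype=bool)]
        frac = (off > 0).mean()
        assert frac == pytest.approx(0.4, abs=0.01)  # binomial tolerance
        assert set(np.unique(off)) <= {0.0, 0.4}
        assert np.all(np.diag(p.A) == 1.0)
        assert p.r.mean() == pytest.approx(1.0, abs=0.02)
        assert p.r.std(ddof=1) == pytest.approx(0.25, abs=0.02)
        assert np.allclose(p.x, np.arange(2000) / 2000)
        assert np.all((p.b0 > 0) & (p.b0 <= 1))

    def test_same_seed_identical(self):
        p1, p2 = sample_params(50, seed=9), sample_params(50, seed=9)
        assert np.array_equal(p1.A, p2.A) and np.array_equal(p1.r, p2.r)
        assert not np.array_equal(p1.A, sample_params(50, seed=10).A)


class TestSuitability:
    def test_peak_and_period(self):
        assert suitability(0.3, 0.3) == pytest.approx(1.0)
        assert suitability(0.8, 0.3) == pytest.approx(0.0, abs=1e-12)  # opposite side
        assert suitability(0.1, 0.0) == pytest.approx(suitability(0.9, 0.0))  # circular


class TestIntegrate:
    def test_single_species_logistic_fixed_point(self):
        p = sample_params(1, seed=0, t_total=300.0, t_burnin=200.0)
        p.r[:] = 1.0
        p.x[:] = 0.0  # at the environmental optimum, f = 1
        p.A[:] = 1.0
        traj = integrate(p)
        assert traj.biomass[-1, 0] == pytest.approx(1.0, abs=1e-5)

    def test_universal_degradation_empties_community(self):
        p = sample_params(6, seed=1, d=3.0, t_total=600.0, t_burnin=200.0)
        traj = integrate(p)
        assert all(len(s) == 0 for s in traj.presence_sets)
        assert np.all(traj.biomass >= 0.0)

    def test_zero_propagule_rain_keeps_zero_state_invariant(self):
        p = sample_params(4, seed=2, t_total=500.0, t_burnin=100.0, epsilon=0.0)
        p.b0 = np.zeros(4)
        traj = integrate(p)
        assert np.all(traj.biomass == 0.0)

    def test_burnin_discarded_and_sampling_interval(self):
        p = sample_params(3, seed=3, t_total=700.0, t_burnin=300.0, dt_sample=25.0)
        traj = integrate(p)
        assert traj.times[0] == 325.0 and traj.times[-1] == 700.0
        assert len(traj.times) == 16


def rotating_presence_trajectory(n_species_pool=30, richness=10, n_years=14):
    """Hand-built trajectory replacing exactly one of 10 species per year."""
    biomass = np.zeros((n_years, n_species_pool))
    for t in range(n_years):
        biomass[t, t : t + richness] = 1.0
    params = lv_sim.LVParams(
        S=n_species_pool, r=np.ones(n_species_pool), x=np.arange(n_species_pool) / n_species_pool,
        A=np.eye(n_species_pool), t_total=n_years * 25.0, t_burnin=0.0,
    )
    return LVTrajectory(params=params, times=np.arange(n_years) * 25.0, biomass=biomass)


class TestSimTurnover:
    def test_frozen_community_zero_rate(self):
        traj = rotating_presence_trajectory()
        traj.biomass[:, :] = 0.0
        traj.biomass[:, :5] = 1.0  # same 5 species every year
        est = sim_turnover(traj)
        assert est.rate == 0.0 and est.se == 0.0

    def test_rotating_replacement_matches_closed_form_slope(self):
        # One of 10 species replaced per year: Ochiai at lag l is (10 - l)/10,
        # an exact linear decline of 0.1 per year.
        est = sim_turnover(rotating_presence_trajectory())
        assert est.rate == pytest.approx(0.1, abs=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_code_path_identical_to_turnover_module(self):
        traj = rotating_presence_trajectory()
        est = sim_turnover(traj)
        series = traj.to_series()
        sims = rarefied_pair_similarities(series, index="ochiai", max_lag=5)
        ref = turnover_rate(mean_similarity_by_lag(sims, max_lag=5))
        assert (est.rate, est.se, est.n_lags) == (ref.rate, ref.se, ref.n_lags)

    def test_empty_years_become_gaps(self):
        traj = rotating_presence_trajectory(n_years=12)
        traj.biomass[5, :] = 0.0  # nothing above threshold that year
        series = traj.to_series()
        assert 5 not in series.years


class TestFactorialDesign:
    def test_reduced_plan_row_count(self):
        assert len(factorial_plan(2, 2, 2)) == 8

    def test_reference_design_enumerates_8000_runs(self):
        plan = factorial_plan()
        assert len(plan) == 8000
        assert plan["d"].max() == 0.5 and plan["v"].max() == 0.6
        assert plan["d"].nunique() == 20 and plan["v"].nunique() == 20

    def test_experiment_table_complete_and_reproducible(self):
        plan = factorial_plan(2, 2, 1, d_max=0.2, v_max=0.3)
        kwargs = dict(t_total=600.0, t_burnin=200.0)
        t1 = factorial_experiment(24, plan, seed=0, lags=range(1, 4), **kwargs)
        t2 = factorial_experiment(24, plan, seed=0, lags=range(1, 4), **kwargs)
        assert len(t1) == 4
        assert t1["turnover_rate"].equals(t2["turnover_rate"])


class TestFitSurface:
    @staticmethod
    def _grid(n=20):
        d, v = np.meshgrid(np.linspace(0, 0.5, n), np.linspace(0, 0.6, n))
        return d.ravel(), v.ravel()

    def _table(self, y, d, v):
        import pandas as pd

        return pd.DataFrame({"d": d, "v": v, "turnover_rate": y})

    def test_cubic_surface_selects_order_three(self):
        d, v = self._grid()
        rng = np.random.default_rng(0)
        y = 0.01 + 0.05 * v - 0.04 * d + 0.3 * d * v**2 - 0.2 * d**3 + rng.normal(0, 1e-3, d.size)
        fits, selected = fit_surface(self._table(y, d, v))
        assert selected == 3

    def test_planar_surface_selects_order_two(self):
        d, v = self._grid()
        rng = np.random.default_rng(1)
        y = 0.02 + 0.05 * v - 0.04 * d + rng.normal(0, 1e-3, d.size)
        fits, selected = fit_surface(self._table(y, d, v))
        assert selected == 2

    def test_constant_data_gives_flat_surface(self):
        d, v = self._grid(10)
        fits, _ = fit_surface(self._table(np.full(d.size, 0.37), d, v))
        coeffs = fits[2].coefficients
        assert coeffs["d^0 v^0"] == pytest.approx(0.37, abs=1e-10)
        for name, val in coeffs.items():
            if name != "d^0 v^0":
                assert val == pytest.approx(0.0, abs=1e-8)

    def test_too_few_rows_is_error(self):
        import pandas as pd

        table = pd.DataFrame({"d": [0.0, 0.1], "v": [0.0, 0.1], "turnover_rate": [0.1, 0.2]})
        with pytest.raises(ValueError, match="order-4"):
            fit_surface(table, orders=(4,))
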