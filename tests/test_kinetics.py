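"""Cleavage/repair ODE model: trajectories, derived statistics, recurrence."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dpcrkit import (
    ConditionRates,
    InputError,
    derive_kinetics,
    recurrence_profile,
    simulate_model,
)


def _oracle_trajectory(rates, t_grid):
    """Independent high-accuracy integration of the same vector field."""
    K = rates.K

    def rhs(t, y):
        d = 1.0 - math.exp(-t / rates.tau) if rates.tau > 1e-12 else 1.0
        a = rates.k_dsb * d
        w, b = y[0], y[1]
        return [
            -a * w + rates.k_pr * b,
            a * w - K * b,
            rates.k_in * b,
            rates.k_ld * b,
            rates.k_ti * b,
            a * w,
            rates.k_pr * b,
        ]

    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), [100.0, 0, 0, 0, 0, 0, 0],
        t_eval=t_grid, method="Radau", rtol=1e-10, atol=1e-10,
    )
    return sol.y.T


class TestSimulateModel:
    def test_all_rates_zero_is_static(self):
        r = ConditionRates(k_pr=0, k_in=0, k_ld=0, k_ti=0, k_dsb=0, tau=1.0)
        traj = simulate_model(r, np.linspace(0, 24, 25))
        assert np.allclose(traj.WT, 100.0)
        assert np.allclose(traj.DSB, 0.0)
        assert np.allclose(traj.DSB_cum, 0.0)

    def test_equal_rate_linear_chain_closed_form(self):
        """With no delay and a single repair channel at the cleavage rate,
        the model is the classic equal-rate linear chain."""
        r = ConditionRates(k_pr=0, k_in=1.0, k_ld=0, k_ti=0, k_dsb=1.0, tau=0.0)
        t = np.linspace(0, 5, 51)
        traj = simulate_model(r, t)
        wt = 100 * np.exp(-t)
        dsb = 100 * t * np.exp(-t)
        indel = 100 * (1 - np.exp(-t) * (1 + t))
        assert np.max(np.abs(traj.WT - wt)) < 1e-6
        assert np.max(np.abs(traj.DSB - dsb)) < 1e-6
        assert np.max(np.abs(traj.IN - indel)) < 1e-6

    def test_conservation_over_random_coefficients(self, random_rate_sets):
        t = np.linspace(0, 24, 49)
        worst = 0.0
        for kw in random_rate_sets:
            traj = simulate_model(ConditionRates(**kw), t)
            worst = max(worst, float(np.max(np.abs(traj.total - 100.0))))
        assert worst < 1e-6

    def test_matches_independent_integrator(self, random_rate_sets):
        """Fixed-step trajectories agree with an adaptive implicit solver
        run at tight tolerance."""
        t = np.linspace(0, 24, 25)
        for kw in random_rate_sets[:10]:
            r = ConditionRates(**kw)
            mine = simulate_model(r, t)
            oracle = _oracle_trajectory(r, t)
            stacked = np.column_stack(
                [mine.WT, mine.DSB, mine.IN, mine.LD, mine.TI,
                 mine.DSB_cum, mine.PR_cum]
            )
            assert np.max(np.abs(stacked - oracle)) < 1e-5

    def test_cumulative_counters_nondecreasing(self, reconstructed_rates):
        traj = simulate_model(
            reconstructed_rates.condition("untreated"), np.linspace(0, 24, 97)
        )
        assert np.all(np.diff(traj.DSB_cum) >= 0)
        assert np.all(np.diff(traj.PR_cum) >= 0)

    def test_recurrent_cleavage_regime_exceeds_100(self, reconstructed_rates):
        """Under the reconstructed coefficients, cumulative cleavage and
        precise repairs both pass 100% of genome copies within 24 h."""
        traj = simulate_model(
            reconstructed_rates.condition("untreated"), np.linspace(0, 24, 97)
        )
        assert traj.DSB_cum[-1] > 100.0
        assert traj.PR_cum[-1] > 100.0

    def test_higher_precise_repair_raises_late_wildtype(self):
        base = dict(k_in=0.1, k_ld=0.05, k_ti=0.0, k_dsb=0.6, tau=0.5)
        t = np.linspace(0, 48, 49)
        lo = simulate_model(ConditionRates(k_pr=0.1, **base), t)
        hi = simulate_model(ConditionRates(k_pr=0.8, **base), t)
        assert hi.WT[-1] > lo.WT[-1]
        assert (hi.IN + hi.LD + hi.TI)[-1] < (lo.IN + lo.LD + lo.TI)[-1]

    def test_invalid_grid_and_rates_rejected(self):
        r = ConditionRates(k_pr=0, k_in=0, k_ld=0, k_ti=0, k_dsb=1, tau=0.5)
        with pytest.raises(InputError):
            simulate_model(r, [0.0, 0.0, 1.0])
        with pytest.raises(InputError):
            ConditionRates(k_pr=-1, k_in=0, k_ld=0, k_ti=0, k_dsb=1, tau=0.5)
        with pytest.raises(InputError):
            ConditionRates(
                k_pr=math.nan, k_in=0, k_ld=0, k_ti=0, k_dsb=1, tau=0.5
            )


class TestDerivedKinetics:
    def test_resolution_half_life_identity(self):
        r = ConditionRates(
            k_pr=math.log(2) - 0.1, k_in=0.06, k_ld=0.04, k_ti=0.0,
            k_dsb=1.0, tau=0.1,
        )
        der = derive_kinetics(r)
        assert der.half_life_resolution == pytest.approx(1.0, rel=1e-9)

    def test_published_summary_statistics_reproduced(self, reconstructed_rates):
        """6.9 cleavages/indel and 11.1/large-deletion imply ~1.31 per
        precise repair, and K = 0.105 * 6.9 gives a ~0.96 h resolution
        half-life."""
        r = reconstructed_rates.condition("untreated")
        der = derive_kinetics(r)
        assert der.dsbs_per_product["in"] == pytest.approx(6.9, rel=1e-9)
        assert der.dsbs_per_product["ld"] == pytest.approx(11.1, rel=1e-9)
        assert der.dsbs_per_product["pr"] == pytest.approx(1.307, abs=0.01)
        assert der.half_life_resolution == pytest.approx(0.9567, abs=1e-3)

    def test_reciprocal_dsbs_identity(self, random_rate_sets):
        """Sum over repair classes of 1/(cleavages per product) is exactly 1."""
        for kw in random_rate_sets[:20]:
            der = derive_kinetics(ConditionRates(**kw))
            recip = sum(1.0 / v for v in der.dsbs_per_product.values())
            assert recip == pytest.approx(1.0, abs=1e-9)

    def test_hourly_likelihoods_sum_to_one(self, random_rate_sets):
        for kw in random_rate_sets[:20]:
            der = derive_kinetics(ConditionRates(**kw))
            assert sum(der.likelihood_per_hour.values()) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_symmetric_rates_split_evenly(self):
        r = ConditionRates(k_pr=0.2, k_in=0.2, k_ld=0.2, k_ti=0.0,
                           k_dsb=1.0, tau=0.1)
        der = derive_kinetics(r)
        vals = [der.dsbs_per_product[c] for c in ("pr", "in", "ld")]
        assert all(v == pytest.approx(3.0) for v in vals)
        lik = [der.likelihood_per_hour[c] for c in ("pr", "in", "ld")]
        assert lik[0] == pytest.approx(lik[1]) == pytest.approx(lik[2])

    def test_zero_rate_class_reported_absent(self):
        r = ConditionRates(k_pr=0.5, k_in=0.1, k_ld=0.0, k_ti=0.0,
                           k_dsb=1.0, tau=0.1)
        der = derive_kinetics(r)
        assert "ld" not in der.dsbs_per_product
        assert "ti" not in der.dsbs_per_product

    def test_vmax_of_products_trails_dsb_generation(self, reconstructed_rates):
        der = derive_kinetics(reconstructed_rates.condition("untreated"))
        t_dsb = der.vmax["dsb"][1]
        for c in ("pr", "in", "ld"):
            assert der.vmax[c][1] > t_dsb

    def test_crossing_times_in_recurrent_regime(self, reconstructed_rates):
        der = derive_kinetics(reconstructed_rates.condition("untreated"))
        assert 2.0 < der.t_dsb_cum_100 < 8.0
        assert der.t_dsb_cum_100 < der.t_pr_cum_100


class TestRecurrenceProfile:
    def test_no_precise_repair_means_no_second_cut(self):
        r = ConditionRates(k_pr=0.0, k_in=0.3, k_ld=0.1, k_ti=0.0,
                           k_dsb=0.8, tau=0.3)
        prof = recurrence_profile(r, np.linspace(0, 24, 25), c_max=5)
        assert np.allclose(prof.WT_cohorts[1:], 0.0, atol=1e-12)
        assert np.allclose(prof.DSB_cohorts[1:], 0.0, atol=1e-12)

    def test_cohort_sums_equal_aggregate_model(self, random_rate_sets):
        t = np.linspace(0, 24, 25)
        for kw in random_rate_sets[:8]:
            r = ConditionRates(**kw)
            prof = recurrence_profile(r, t, c_max=30)
            agg = simulate_model(r, t)
            assert np.max(np.abs(prof.WT_cohorts.sum(0) - agg.WT)) < 1e-6
            assert np.max(np.abs(prof.DSB_cohorts.sum(0) - agg.DSB)) < 1e-6
            assert np.max(np.abs(prof.total - 100.0)) < 1e-6

    def test_reconstructed_rates_recurrence_statements(self, reconstructed_rates):
        """Uncleaved pool below 1% by 12 h; at least 5 cleavage cohorts
        populated above 0.1% by 24 h."""
        r = reconstructed_rates.condition("untreated")
        t = np.linspace(0, 24, 49)
        prof = recurrence_profile(r, t, c_max=16, threshold=0.1)
        i12 = np.searchsorted(t, 12.0)
        assert prof.uncleaved[i12] < 1.0
        assert prof.min_cycles_reached >= 5

    def test_cohorts_nonnegative(self, reconstructed_rates):
        prof = recurrence_profile(
            reconstructed_rates.condition("untreated"),
            np.linspace(0, 24, 25), c_max=16,
        )
        assert np.all(prof.WT_cohorts >= -1e-12)
        assert np.all(prof.DSB_cohorts >= -1e-12)

    def test_small_cmax_warns(self, reconstructed_rates):
        with pytest.warns(RuntimeWarning, match="terminal cohort"):
            recurrence_profile(
                reconstructed_rates.condition("untreated"),
                np.linspace(0, 24, 25), c_max=1,
            )
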