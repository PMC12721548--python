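"""Partitioned-survival trace construction and reward accumulation."""

import numpy as np
import pytest
from scipy import integrate

from pscea import (
    CostSchedule,
    ModelSettings,
    UtilitySet,
    accumulate_costs,
    accumulate_life_years,
    accumulate_qalys,
    build_trace,
)


class TestTrace:
    def test_cycle_zero_everyone_progression_free(self, table2_models, settings):
        trace = build_trace(
            table2_models[("treatment", "pfs")],
            table2_models[("treatment", "os")],
            settings,
        )
        assert trace.occupancy_pfs[0] == 1.0
        assert trace.occupancy_pd[0] == 0.0
        assert trace.occupancy_death[0] == 0.0
        assert trace.discount_factor[0] == 1.0

    def test_death_occupancy_at_median_os(self, table2_models, settings):
        # 1 - S_os at the OS scale parameter is exactly one half, and the trace
        # carries that value wherever the grid lands on it.
        os_model = table2_models[("treatment", "os")]
        assert 1.0 - os_model.survival(13.97048) == pytest.approx(0.5, abs=1e-12)
        trace = build_trace(table2_models[("treatment", "pfs")], os_model, settings)
        expected = 1.0 - os_model.survival(trace.time_months)
        assert np.allclose(trace.occupancy_death, expected, atol=1e-15)

    @pytest.mark.parametrize("arm", ["treatment", "control"])
    def test_occupancy_conservation_all_cycles(self, table2_models, settings, arm):
        trace = build_trace(
            table2_models[(arm, "pfs")], table2_models[(arm, "os")], settings
        )
        assert len(trace) == 174
        total = trace.occupancy_pfs + trace.occupancy_pd + trace.occupancy_death
        assert np.max(np.abs(total - 1.0)) <= 1e-12

    @pytest.mark.parametrize("arm", ["treatment", "control"])
    def test_occupancy_monotonicity(self, table2_models, settings, arm):
        trace = build_trace(
            table2_models[(arm, "pfs")], table2_models[(arm, "os")], settings
        )
        alive = trace.occupancy_pfs + trace.occupancy_pd
        assert np.all(np.diff(trace.occupancy_pfs) <= 1e-15)
        assert np.all(np.diff(alive) <= 1e-15)
        assert np.all(np.diff(trace.occupancy_death) >= -1e-15)
        for arr in (trace.occupancy_pfs, trace.occupancy_pd, trace.occupancy_death):
            assert np.all((arr >= 0) & (arr <= 1))

    def test_crossing_curves_clip_pd_to_zero(self, table2_models, settings):
        # A PFS curve lying above OS is impossible; occupancy must clip, not go
        # negative.
        trace = build_trace(
            table2_models[("treatment", "os")],  # slower curve as "PFS"
            table2_models[("treatment", "pfs")],  # faster curve as "OS"
            settings,
        )
        assert trace.n_clipped > 0
        assert np.all(trace.occupancy_pd >= 0.0)
        total = trace.occupancy_pfs + trace.occupancy_pd + trace.occupancy_death
        assert np.max(np.abs(total - 1.0)) <= 1e-12

    def test_n_cycles_follows_horizon(self):
        st = ModelSettings(horizon_years=0.5)
        assert st.n_cycles == 8

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSettings(cycle_days=0)
        with pytest.raises(ValueError):
            ModelSettings(annual_discount=0.2)


class TestQALYs:
    def test_unit_utility_no_discount_matches_restricted_mean(self, table2_models):
        st = ModelSettings(annual_discount=0.0)
        os_model = table2_models[("control", "os")]
        trace = build_trace(table2_models[("control", "pfs")], os_model, st)
        ly = accumulate_qalys(trace, UtilitySet(1.0, 1.0), st)
        rm_years = os_model.restricted_mean(120.0) / 12.0
        one_cycle_years = st.cycle_months / 12.0
        assert abs(ly - rm_years) <= one_cycle_years
        assert ly == accumulate_life_years(trace, st)

    def test_zero_utilities_give_zero(self, table2_models, settings):
        trace = build_trace(
            table2_models[("treatment", "pfs")],
            table2_models[("treatment", "os")],
            settings,
        )
        assert accumulate_qalys(trace, UtilitySet(0.0, 0.0), settings) == 0.0

    def test_discounted_qalys_converge_to_continuous_integral(self, table2_models):
        """The cycle sum approaches the quadrature value as cycles shrink, and the
        coarse-grid error is bounded by one cycle's contribution."""
        pfs = table2_models[("treatment", "pfs")]
        os_ = table2_models[("treatment", "os")]
        u = UtilitySet(0.673, 0.473)
        rho = 0.05

        def integrand(t):
            sp, so = pfs.survival(t), os_.survival(t)
            p = min(sp, so)
            return (1 + rho) ** (-t / 12.0) * (u.u_pfs * p + u.u_pd * (so - p)) / 12.0

        exact, _ = integrate.quad(integrand, 0.0, 120.0, limit=400)
        errors = {}
        for cycle_days in (21.0, 1.0):
            st = ModelSettings(cycle_days=cycle_days, annual_discount=rho)
            trace = build_trace(pfs, os_, st)
            q = accumulate_qalys(trace, u, st)
            first_cycle = integrand(0.0) * st.cycle_months
            errors[cycle_days] = abs(q - exact)
            assert errors[cycle_days] <= first_cycle + 1e-12
        assert errors[1.0] < errors[21.0]

    def test_half_cycle_correction_lies_below_cycle_start(self, table2_models):
        st0 = ModelSettings(half_cycle_correction=False)
        st1 = ModelSettings(half_cycle_correction=True)
        trace = build_trace(
            table2_models[("treatment", "pfs")],
            table2_models[("treatment", "os")],
            st0,
        )
        u = UtilitySet(0.673, 0.473)
        assert accumulate_qalys(trace, u, st1) < accumulate_qalys(trace, u, st0)

    def test_discounting_reduces_qalys(self, table2_models):
        u = UtilitySet(0.673, 0.473)
        vals = {}
        for rho in (0.0, 0.05):
            st = ModelSettings(annual_discount=rho)
            trace = build_trace(
                table2_models[("control", "pfs")],
                table2_models[("control", "os")],
                st,
            )
            vals[rho] = accumulate_qalys(trace, u, st)
        assert vals[0.0] > vals[0.05]


class TestCosts:
    def test_zero_schedule_costs_nothing(self, table2_models, settings):
        trace = build_trace(
            table2_models[("control", "pfs")], table2_models[("control", "os")], settings
        )
        sched = CostSchedule(pfs_cost=0.0, pd_cost=0.0)
        assert accumulate_costs(trace, sched, settings) == 0.0

    def test_constant_pd_cost_is_linear_in_occupancy(self, table2_models):
        st = ModelSettings(annual_discount=0.0)
        trace = build_trace(
            table2_models[("control", "pfs")], table2_models[("control", "os")], st
        )
        sched = CostSchedule(pfs_cost=0.0, pd_cost=3115.0)
        expected = 3115.0 * float(np.sum(trace.occupancy_pd))
        assert accumulate_costs(trace, sched, st) == pytest.approx(expected, rel=1e-12)

    def test_one_off_only(self, table2_models, settings):
        trace = build_trace(
            table2_models[("control", "pfs")], table2_models[("control", "os")], settings
        )
        sched = CostSchedule(pfs_cost=0.0, pd_cost=0.0, one_off=100.0)
        assert accumulate_costs(trace, sched, settings) == 100.0

    def test_short_vector_rejected(self, table2_models, settings):
        trace = build_trace(
            table2_models[("control", "pfs")], table2_models[("control", "os")], settings
        )
        sched = CostSchedule(pfs_cost=np.ones(10), pd_cost=0.0)
        with pytest.raises(ValueError):
            accumulate_costs(trace, sched, settings)

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            CostSchedule(pfs_cost=-1.0, pd_cost=0.0)

    def test_discounting_reduces_costs(self, table2_models):
        vals = {}
        for rho in (0.0, 0.05):
            st = ModelSettings(annual_discount=rho)
            trace = build_trace(
                table2_models[("control", "pfs")], table2_models[("control", "os")], st
            )
            vals[rho] = accumulate_costs(
                trace, CostSchedule(pfs_cost=466.0, pd_cost=3581.0), st
            )
        assert vals[0.0] > vals[0.05]
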