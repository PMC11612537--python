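"""Closed-form life-history integrals against the quadrature oracle."""

from math import inf

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from tritherm import (
    Environment,
    ModelParameters,
    effective_rates,
    growth_trajectory,
    lifetime_reproduction,
    per_recruit_integrals,
    scenario_parameterization,
    stage_ages,
)

P = ModelParameters()


class TestGrowthTrajectory:
    def test_newborn_length_and_asymptote(self, baseline_rates):
        length, l_max = growth_trajectory(Environment(R_tilde=P.Rh), baseline_rates, P.Rh)
        assert length(0.0) == pytest.approx(7.0)
        assert l_max == pytest.approx(150.0)  # half-saturation: l_inf / 2

    def test_saturation_limit(self, baseline_rates):
        _, l_max = growth_trajectory(Environment(R_tilde=1e3), baseline_rates, P.Rh)
        assert l_max == pytest.approx(P.linf, rel=1e-7)

    def test_vulnerability_age_matches_numeric_inversion(self, baseline_rates):
        env = Environment(R_tilde=P.Rh)
        a_v, a_mat = stage_ages(env, baseline_rates, P.Rh)
        # independent oracle: invert the growth curve numerically
        length, _ = growth_trajectory(env, baseline_rates, P.Rh)
        a_v_oracle = brentq(lambda a: length(a) - P.lv, 0.0, 1e4, xtol=1e-12)
        assert a_v == pytest.approx(a_v_oracle, rel=1e-10)
        assert a_v == pytest.approx(25.1, abs=0.1)
        assert a_v <= a_mat

    def test_unreachable_stages_are_infinite(self, baseline_rates):
        # asymptote below the vulnerability threshold: vulnerable for life
        env = Environment(R_tilde=1e-6)  # l_max = 300/16.5 ≈ 18 mm < lv
        a_v, a_mat = stage_ages(env, baseline_rates, P.Rh)
        assert a_v == inf and a_mat == inf
        assert lifetime_reproduction(env, baseline_rates, P.Rh) == 0.0


def _random_environments():
    return st.tuples(
        st.floats(min_value=1e-6, max_value=5e-3),  # R_tilde
        st.floats(min_value=0.0, max_value=2.0),  # p
        st.sampled_from([1, 2, 5, 7, 10]),  # scenario id
        st.floats(min_value=6.0, max_value=24.0),  # temperature
    )


class TestClosedFormAgainstQuadrature:
    @given(_random_environments())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_all_integrals_agree_to_1e8(self, draw):
        r_tilde, p, sid, T = draw
        rates = effective_rates(T, P, scenario_parameterization(sid))
        env = Environment(R_tilde=r_tilde, p=p, T=T)
        closed = per_recruit_integrals(env, rates, P.Rh, P.omega, method="closed")
        quad = per_recruit_integrals(env, rates, P.Rh, P.omega, method="quadrature")
        for fld in ("R0", "theta_I", "theta_v", "theta_j", "theta_a"):
            c, q = getattr(closed, fld), getattr(quad, fld)
            assert c == pytest.approx(q, rel=1e-8, abs=1e-300 if c == 0 else None), fld

    def test_example_environment_agrees(self, baseline_rates):
        env = Environment(R_tilde=P.Rh, p=0.05)
        closed = per_recruit_integrals(env, baseline_rates, P.Rh, P.omega)
        quad = per_recruit_integrals(env, baseline_rates, P.Rh, P.omega, method="quadrature")
        assert closed.R0 == pytest.approx(quad.R0, rel=1e-8)


class TestCohortStatisticsProperties:
    def test_r0_monotone_in_resource_and_predation(self, baseline_rates):
        rs = np.linspace(1.2e-5, 1e-4, 5)
        ps = np.linspace(0.0, 0.5, 5)
        grid = np.array(
            [
                [
                    lifetime_reproduction(Environment(R_tilde=r, p=p), baseline_rates, P.Rh)
                    for p in ps
                ]
                for r in rs
            ]
        )
        assert np.all(np.diff(grid, axis=0) > 0)  # increasing in R
        assert np.all(np.diff(grid, axis=1) < 0)  # decreasing in p

    def test_r0_vanishes_below_maturation_resource(self, baseline_rates):
        # l_max = lmat exactly at sigma = lmat/linf
        sigma = P.lmat / P.linf
        r_crit = P.Rh * sigma / (1 - sigma)
        assert lifetime_reproduction(Environment(R_tilde=0.999 * r_crit), baseline_rates, P.Rh) == 0.0
        assert lifetime_reproduction(Environment(R_tilde=1.2 * r_crit), baseline_rates, P.Rh) > 0.0

    def test_zero_growth_outside_thermal_niche_means_no_reproduction(self, params):
        rates = effective_rates(25.0, params, scenario_parameterization(2))
        assert rates.G_T == 0.0
        for r in (1e-5, 1e-3, 1.0):
            assert lifetime_reproduction(Environment(R_tilde=r), rates, P.Rh) == 0.0

    def test_stage_additivity(self, baseline_rates):
        env = Environment(R_tilde=3e-5, p=0.2)
        stats = per_recruit_integrals(env, baseline_rates, P.Rh, P.omega)
        # one integral over the whole life vs the three stage bins
        total = stats.theta_v + stats.theta_j + stats.theta_a
        unsplit = per_recruit_integrals(
            env, baseline_rates, P.Rh, P.omega, method="quadrature"
        )
        assert total == pytest.approx(
            unsplit.theta_v + unsplit.theta_j + unsplit.theta_a, rel=1e-8
        )

    def test_extreme_predation_removes_later_stages(self, baseline_rates):
        env = Environment(R_tilde=5e-5, p=50.0)
        stats = per_recruit_integrals(env, baseline_rates, P.Rh, P.omega)
        mild = per_recruit_integrals(
            Environment(R_tilde=5e-5, p=0.0), baseline_rates, P.Rh, P.omega
        )
        assert stats.theta_j < 1e-6 * mild.theta_j
        assert stats.theta_a < 1e-6 * mild.theta_a

    def test_all_statistics_nonnegative(self, baseline_rates):
        for r, p in [(1e-5, 0.0), (5e-5, 1.0), (1e-3, 0.01)]:
            stats = per_recruit_integrals(
                Environment(R_tilde=r, p=p), baseline_rates, P.Rh, P.omega
            )
            for fld in ("R0", "theta_I", "theta_v", "theta_j", "theta_a"):
                assert getattr(stats, fld) >= 0.0


class TestDebugDump:
    def test_trajectory_dump_writes_length_and_survival(self, baseline_rates, tmp_path):
        from tritherm.life_history import dump_trajectory

        path = tmp_path / "traj.csv"
        dump_trajectory(
            Environment(R_tilde=P.Rh, p=0.1), baseline_rates, P.Rh, [0.0, 10.0, 50.0], path
        )
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "age_days,length_mm,survival"
        first = lines[1].split(",")
        assert float(first[1]) == pytest.approx(7.0)
        assert float(first[2]) == pytest.approx(1.0)
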