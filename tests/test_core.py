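"""Unit tests for the perception recursion core."""

import math

import pytest

from riskperc import (
    DegenerateParameterError,
    MemoryProfile,
    ScheduleError,
    association_sum,
    association_weight,
    constant_schedule,
    first_period_perception,
    kernel_F,
    memory_grid,
    simulate,
    steady_state_limit,
    step_perception,
)

from _oracle import oracle_association_weight, oracle_kernel, oracle_trajectory


class TestKernel:
    @pytest.mark.parametrize(
        "rho,k,n",
        [(0.5, 0.3, 10.0), (0.8, 0.2, 49.0), (0.3, 0.6, 2.5), (0.95, 0.05, 1.7)],
    )
    def test_matches_high_precision_oracle(self, rho, k, n):
        assert kernel_F(rho, k, n) == pytest.approx(float(oracle_kernel(rho, k, n)), rel=1e-12)

    def test_reference_value(self):
        # frozen from the 60-digit oracle
        assert kernel_F(0.5, 0.3, 10.0) == pytest.approx(32.180391906573560, rel=1e-12)

    @pytest.mark.parametrize("rho,k", [(0.5, 0.3), (0.6, 0.4), (0.9, 0.1)])
    def test_single_item_identity(self, rho, k):
        # with one item per period the kernel collapses to 1: the three-term
        # sum over the common denominator (p-k)(p-1)(k-1) has numerator
        # p^2(k-1) - k^2(p-1) + (p-k) = (p-k)(p-1)(k-1)
        assert kernel_F(rho, k, 1.0) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "rho,k",
        [(0.5, 0.5), (0.5, 0.5 + 1e-9), (1.0, 0.3), (0.5, 1.0), (0.0, 0.3), (0.5, -0.1), (1.2, 0.3)],
    )
    def test_degenerate_parameters_rejected(self, rho, k):
        with pytest.raises(DegenerateParameterError):
            kernel_F(rho, k, 10.0)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ScheduleError):
            kernel_F(0.5, 0.3, 0.0)


class TestAssociationWeight:
    def test_single_item_reduces_to_odds(self):
        assert association_weight(0.3, 1.0) == pytest.approx(3.0 / 7.0, rel=1e-15)
        assert association_weight(0.5, 1.0) == pytest.approx(1.0, rel=1e-15)

    def test_matches_oracle(self):
        assert association_weight(0.3, 10.0) == pytest.approx(
            float(oracle_association_weight(0.3, 10.0)), rel=1e-12
        )

    def test_strictly_increasing_in_count(self):
        values = [association_weight(0.3, n) for n in (1.0, 2.0, 5.0, 10.0, 50.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("k,n", [(1.0, 5.0), (0.0, 5.0), (0.3, 0.0), (0.3, -1.0)])
    def test_domain_errors(self, k, n):
        with pytest.raises((DegenerateParameterError, ScheduleError)):
            association_weight(k, n)


class TestFirstPeriod:
    def test_value_and_linearity(self, centre_profile):
        y1 = first_period_perception(centre_profile, 10.0, 2.0)
        assert y1 == pytest.approx(2.0 * float(oracle_kernel(0.5, 0.3, 10.0)), rel=1e-12)
        assert first_period_perception(centre_profile, 10.0, 0.0) == 0.0
        assert first_period_perception(centre_profile, 10.0, 7.0) == pytest.approx(3.5 * y1, rel=1e-12)

    def test_single_item_returns_stimulus(self, centre_profile):
        assert first_period_perception(centre_profile, 1.0, 4.2) == pytest.approx(4.2, rel=1e-12)


class TestAssociationSum:
    def test_single_period_is_one_weight(self, centre_profile):
        g = association_weight(0.3, 10.0)
        assert association_sum(centre_profile, [10.0], 1) == pytest.approx(g, rel=1e-15)

    def test_two_periods_constant_count(self, centre_profile):
        g = association_weight(0.3, 10.0)
        assert association_sum(centre_profile, [10.0, 10.0], 2) == pytest.approx(g * 1.3, rel=1e-14)

    def test_geometric_limit(self, centre_profile):
        # constant counts make the sum a geometric series -> g/(1-k)
        g = association_weight(0.3, 10.0)
        total = association_sum(centre_profile, [10.0] * 200, 200)
        assert total == pytest.approx(g / 0.7, rel=1e-12)

    def test_history_too_short(self, centre_profile):
        with pytest.raises(IndexError):
            association_sum(centre_profile, [10.0, 10.0], 3)


class TestStep:
    def test_matches_oracle_second_period(self, centre_profile, baseline_schedule):
        y1 = first_period_perception(centre_profile, 10.0, 2.0)
        y2 = step_perception(y1, centre_profile, baseline_schedule, 2)
        expected = float(oracle_trajectory(0.5, 0.3, [10.0] * 2, [2.0] * 2)[1])
        assert y2 == pytest.approx(expected, rel=1e-12)

    def test_zero_stimulus_is_pure_decay(self, centre_profile):
        from riskperc import InformationSchedule

        sched = InformationSchedule(N=(10.0, 10.0), S=(2.0, 0.0))
        assert step_perception(100.0, centre_profile, sched, 2) == pytest.approx(50.0, rel=1e-15)

    def test_first_period_rejected(self, centre_profile, baseline_schedule):
        with pytest.raises(ValueError):
            step_perception(0.0, centre_profile, baseline_schedule, 1)


class TestSimulateAndSteadyState:
    def test_constant_schedule_saturates(self, centre_profile, baseline_schedule):
        traj = simulate(centre_profile, baseline_schedule)
        star = steady_state_limit(centre_profile, 10.0, 2.0)
        assert all(a < b for a, b in zip(traj.y, traj.y[1:]))
        assert all(v < star for v in traj.y)
        assert abs(traj.y[-1] - star) / star < 1e-3

    @pytest.mark.parametrize("profile", memory_grid("table3"), ids=lambda p: p.label)
    def test_geometric_convergence_closed_form(self, profile):
        # the steady-state error obeys e_t = rho*e_{t-1} + beta*k^t with
        # beta = s*(rho-k)/(u-v)*g(k,n), solved independently of simulate
        rho, k = profile.rho, profile.k
        n, s, T = 10.0, 2.0, 20
        traj = simulate(profile, constant_schedule(n, s, T))
        star = steady_state_limit(profile, n, s)
        u, v = rho ** (1.0 / n), k ** (1.0 / n)
        beta = s * (rho - k) / (u - v) * association_weight(k, n)
        e = star - traj.y[0]
        expected_tail = rho ** (T - 1) * e + beta * sum(
            rho ** (T - j) * k**j for j in range(2, T + 1)
        )
        assert star - traj.y[-1] == pytest.approx(expected_tail, rel=1e-9)
        # geometric decay at rate max(rho, k)
        gap20 = star - traj.y[-1]
        traj40 = simulate(profile, constant_schedule(n, s, 40))
        assert (star - traj40.y[-1]) / gap20 < 1.1 * max(rho, k) ** 20

    def test_limit_agrees_with_long_run(self, centre_profile):
        traj = simulate(centre_profile, constant_schedule(10.0, 2.0, 80))
        star = steady_state_limit(centre_profile, 10.0, 2.0)
        assert traj.y[-1] == pytest.approx(star, rel=1e-9)

    def test_limit_linear_in_stimulus_and_zero(self, centre_profile):
        assert steady_state_limit(centre_profile, 10.0, 0.0) == 0.0
        assert steady_state_limit(centre_profile, 10.0, 4.0) == pytest.approx(
            2.0 * steady_state_limit(centre_profile, 10.0, 2.0), rel=1e-14
        )

    def test_limit_increases_with_association_rate(self):
        lo = steady_state_limit(MemoryProfile(0.5, 0.2), 10.0, 2.0)
        hi = steady_state_limit(MemoryProfile(0.5, 0.4), 10.0, 2.0)
        assert hi > lo

    def test_rho_below_k_also_valid(self):
        # the recursion is symmetric in which rate is larger; only equality
        # is degenerate
        traj = simulate(MemoryProfile(0.3, 0.6), constant_schedule(10.0, 2.0, 10))
        assert all(math.isfinite(v) for v in traj.y)
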