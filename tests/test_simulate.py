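"""Inverse-transform quantiles and the two path simulators."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

from qmcleap import (
    SimulationConfig,
    SystemState,
    builtin_model,
    cle_em_path,
    final_value,
    normal_quantile,
    poisson_quantile,
    pseudo_points,
    simulate_ensemble,
    species_observable,
    tau_leap_path,
)


def _poisson_quantile_bruteforce(u, lam):
    """Cumulative CDF summation from zero: the independent oracle."""
    q = 0
    term = math.exp(-lam)
    cdf = term
    while cdf < u:
        q += 1
        term *= lam / q
        cdf += term
    return q


class TestPoissonQuantile:
    def test_degenerate_mean_zero(self):
        assert poisson_quantile(0.0, 0.0) == 0
        assert poisson_quantile(0.999, 0.0) == 0

    def test_hand_checked_values(self):
        # CDF(0)=e^-1=0.3679 < 0.5 <= CDF(1)=0.7358
        assert poisson_quantile(0.5, 1.0) == 1
        # CDF(0)=e^-2=0.1353 >= 0.1
        assert poisson_quantile(0.1, 2.0) == 0

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 5.0, 50.0])
    def test_matches_bruteforce_cdf_summation(self, lam):
        for u in np.linspace(0.0, 0.999, 201):
            assert poisson_quantile(u, lam) == _poisson_quantile_bruteforce(u, lam)

    def test_large_mean_stays_near_mean(self):
        lam = 1e4
        for u in (0.01, 0.25, 0.5, 0.75, 0.99):
            assert abs(poisson_quantile(u, lam) - lam) < 4 * math.sqrt(lam)

    def test_stratified_histogram_matches_pmf(self):
        """Inverse-transforming a stratified uniform grid reproduces the pmf."""
        n = 10**5
        u = (np.arange(n) + 0.5) / n
        for lam in (0.5, 5.0, 50.0):
            draws = poisson_quantile(u, np.full(n, lam))
            hi = int(stats.poisson.ppf(1 - 1e-9, lam))
            observed = np.bincount(draws, minlength=hi + 1)[: hi + 1]
            expected = n * stats.poisson.pmf(np.arange(hi + 1), lam)
            keep = expected > 5
            chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            crit = stats.chi2.ppf(0.999, keep.sum() - 1)
            assert chi2 < crit

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            poisson_quantile(1.0, 2.0)
        with pytest.raises(ValueError):
            poisson_quantile(0.5, -1.0)


class TestNormalQuantile:
    def test_median_and_upper_tail(self):
        assert normal_quantile(0.5) == 0.0
        assert normal_quantile(0.975) == pytest.approx(1.959964, abs=1e-6)

    def test_roundtrip_through_cdf(self):
        grid = np.concatenate(
            [[1e-12, 1 - 1e-12], np.linspace(1e-6, 1 - 1e-6, 501)]
        )
        np.testing.assert_allclose(ndtr(normal_quantile(grid)), grid, atol=1e-9)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.1])
    def test_boundary_rejected(self, u):
        with pytest.raises(ValueError):
            normal_quantile(u)


class TestTauLeapPath:
    def test_quantile_zero_region_freezes_state(self):
        net, x0 = builtin_model("birth_death", {"epsilon": 0.1})
        cfg = SimulationConfig(tau=0.2, T=0.6)
        # all uniforms below e^{-max a_k tau} = e^{-2}: zero firings everywhere
        u = np.full(6, 0.1)
        traj = tau_leap_path(net, x0, cfg, u)
        assert (traj.states == 10).all()

    def test_single_step_hand_computation(self):
        # a_k*tau = 2 for both channels; Poisson(2) quantile at u=0.5 is 2,
        # so two births and two deaths cancel
        net, x0 = builtin_model("birth_death", {"epsilon": 0.1})
        cfg = SimulationConfig(tau=0.2, T=0.2)
        traj = tau_leap_path(net, x0, cfg, [0.5, 0.5])
        assert traj.states[-1, 0] == 10

    def test_closed_system_conserved_on_whole_grid(self):
        net, x0 = builtin_model("isomerisation", {"alpha": 0.1, "epsilon": 0.01})
        cfg = SimulationConfig(tau=0.2, T=1.6)
        u = pseudo_points(1, 2 * 8, seed=11).values[0]
        traj = tau_leap_path(net, x0, cfg, u)
        np.testing.assert_array_equal(
            traj.states.sum(axis=1), np.full(9, x0.copy_numbers.sum())
        )

    def test_pure_function_of_stream(self):
        net, x0 = builtin_model("schlogl", {})
        cfg = SimulationConfig(tau=0.4, T=4.0)
        u = pseudo_points(1, 40, seed=5).values[0]
        a = tau_leap_path(net, x0, cfg, u)
        b = tau_leap_path(net, x0, cfg, u)
        np.testing.assert_array_equal(a.states, b.states)

    def test_wrong_stream_length_rejected(self):
        net, x0 = builtin_model("birth_death", {})
        cfg = SimulationConfig(tau=0.2, T=1.6)
        with pytest.raises(ValueError, match="dimension"):
            tau_leap_path(net, x0, cfg, np.full(15, 0.5))

    def test_truncated_final_step(self):
        net, x0 = builtin_model("birth_death", {"epsilon": 0.1})
        cfg = SimulationConfig(tau=0.3, T=1.0)  # steps 0.3,0.3,0.3,0.1
        traj = tau_leap_path(net, x0, cfg, np.full(8, 0.5))
        np.testing.assert_allclose(traj.times, [0, 0.3, 0.6, 0.9, 1.0])
        assert traj.times[-1] == cfg.T


class TestCLEPath:
    def test_median_uniforms_reduce_to_euler_rre_step(self):
        """z=0 for every channel turns the scheme into a deterministic
        explicit-Euler step of the reaction rate equations."""
        net, x0 = builtin_model("schlogl", {})
        cfg = SimulationConfig(tau=0.4, T=0.4, method="cle_em")
        traj = cle_em_path(net, x0, cfg, np.full(4, 0.5))
        a = np.array([933.75, 257.3, 200.0, 875.0])
        expected = 250 + 0.4 * (a @ np.array([1, -1, 1, -1]))
        assert traj.states[-1, 0] == pytest.approx(expected)

    def test_equal_normals_cancel_in_birth_death(self):
        net, _ = builtin_model("birth_death", {"epsilon": 0.01})
        cfg = SimulationConfig(tau=0.2, T=0.2, method="cle_em")
        u = ndtr(0.7)  # same z for both channels
        traj = cle_em_path(net, SystemState(np.array([100])), cfg, [u, u])
        assert traj.states[-1, 0] == pytest.approx(100.0)

    def test_single_step_hand_computation(self):
        net, _ = builtin_model("birth_death", {"epsilon": 0.01})
        cfg = SimulationConfig(tau=0.2, T=0.2, method="cle_em")
        traj = cle_em_path(net, SystemState(np.array([100])), cfg, [0.5, ndtr(1.0)])
        assert traj.states[-1, 0] == pytest.approx(100 + math.sqrt(20), abs=1e-9)


class TestEnsembleMoments:
    @pytest.mark.parametrize("method", ["tau_leap", "cle_em"])
    def test_birth_death_mean_and_variance(self, method):
        """With equal birth/death rates the mean stays at X(0) and the
        variance grows as 2 c t X(0); both simulators are unbiased here."""
        net, x0 = builtin_model("birth_death", {"epsilon": 1e-3, "c": 1.0})
        cfg = SimulationConfig(tau=0.2, T=1.6, method=method)
        n = 10**4
        u = pseudo_points(n, 16, seed=42).values
        finals = simulate_ensemble(net, x0, cfg, u)[:, 0]
        target_var = 2 * 1.0 * 1.6 * 1000  # 3200
        se = finals.std(ddof=1) / math.sqrt(n)
        assert abs(finals.mean() - 1000) < 5 * se
        assert abs(finals.var(ddof=1) - target_var) < 0.1 * target_var


class TestObservables:
    def test_final_value_and_powers(self):
        net, x0 = builtin_model("isomerisation", {"alpha": 0.5, "epsilon": 0.5})
        cfg = SimulationConfig(tau=0.5, T=0.5)
        traj = tau_leap_path(net, x0, cfg, [0.01, 0.01])
        g1 = species_observable(net, "S1")
        g2 = species_observable(net, "S1", power=2)
        assert final_value(traj, g2) == final_value(traj, g1) ** 2

    def test_frozen_species_observable_is_constant(self):
        net, x0 = builtin_model("schlogl", {})
        cfg = SimulationConfig(tau=0.4, T=4.0)
        u = pseudo_points(1, 40, seed=2).values[0]
        traj = tau_leap_path(net, x0, cfg, u)
        g = species_observable(net, "S2")
        assert final_value(traj, g) == 10**5
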