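"""Clipping, noising, Rényi accounting and the calibration procedures.

The accountant's independent oracle is a direct numerical integration of
the sampled-Gaussian Rényi integral
    A_alpha = E_{z ~ N(0, s^2)} [((1-q) + q e^{(2z-1)/(2 s^2)})^alpha],
evaluated with a log-space shift for stability; RDP(alpha) =
log(A_alpha)/(alpha - 1).
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from fedleak import dp_mechanism as dp


def oracle_rdp(q: float, sigma: float, alpha: float) -> float:
    """Quadrature evaluation of the sampled-Gaussian RDP bound."""

    def log_f(z):
        lt = np.logaddexp(math.log1p(-q), math.log(q)
                          + (2 * z - 1) / (2 * sigma ** 2))
        return stats.norm.logpdf(z, 0, sigma) + alpha * lt

    # shift by the maximum of the log-integrand so exp() cannot overflow,
    # and integrate a finite window with a breakpoint at the peak (the
    # integrand decays quadratically on both sides)
    lo, hi = -12 * sigma, alpha + 12 * sigma
    zs = np.linspace(lo, hi, 8001)
    logs = log_f(zs)
    shift = float(np.max(logs))
    peak = float(zs[np.argmax(logs)])
    val, _ = integrate.quad(lambda z: np.exp(log_f(z) - shift), lo, hi,
                            points=[0.0, peak], limit=500)
    return (shift + math.log(val)) / (alpha - 1.0)


class TestAccountant:
    def test_alpha_grid_matches_stated_orders(self):
        grid = dp.default_alpha_grid()
        assert grid[0] == 1.1 and grid[98] == 10.9
        assert np.allclose(np.diff(grid[:99]), 0.1)
        assert list(grid[99:]) == list(np.arange(12.0, 64.0))

    def test_full_participation_equals_gaussian_closed_form(self):
        grid = dp.default_alpha_grid()
        for sigma in (0.7, 1.0, 2.5):
            assert np.allclose(dp.rdp_step(1.0, sigma, grid),
                               grid / (2 * sigma ** 2), rtol=0, atol=0)

    def test_specific_closed_form_value(self):
        assert dp.rdp_step(1.0, 1.0, [2.0])[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("q,sigma", [(0.01, 1.5), (0.2, 0.8),
                                         (0.5, 2.0)])
    def test_subsampled_values_match_quadrature_oracle(self, q, sigma):
        grid = dp.default_alpha_grid()
        mine = dp.rdp_step(q, sigma, grid)
        for k in range(0, len(grid), 5):
            ref = oracle_rdp(q, sigma, float(grid[k]))
            assert mine[k] == pytest.approx(ref, rel=1e-4)

    def test_zero_sampling_rate_costs_nothing(self):
        assert np.all(dp.rdp_step(0.0, 1.0, dp.default_alpha_grid()) == 0)

    def test_orders_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            dp.rdp_step(0.5, 1.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            dp.AccountantState(alphas=np.array([0.5, 2.0]))

    def test_rdp_accumulates_additively_and_monotonically(self):
        state = dp.AccountantState()
        one = dp.rdp_step(0.3, 1.2, state.alphas)
        prev = state.rdp.copy()
        for k in range(1, 4):
            state.step(0.3, 1.2)
            assert np.allclose(state.rdp, k * one)
            assert np.all(state.rdp >= prev)
            prev = state.rdp.copy()


class TestEpsilonConversion:
    def test_zero_steps_minimized_at_largest_order(self):
        state = dp.AccountantState()
        eps, alpha = dp.convert_to_eps(state, 1e-2)
        assert alpha == state.alphas[-1]
        assert eps == pytest.approx(math.log(100) / (alpha - 1))

    def test_single_full_batch_step_matches_manual_minimization(self):
        state = dp.AccountantState()
        state.step(1.0, 1.0)
        eps, _ = dp.convert_to_eps(state, 1e-2)
        grid = state.alphas
        assert eps == pytest.approx(
            np.min(grid / 2 + math.log(100) / (grid - 1)))

    def test_epsilon_nondecreasing_in_steps(self):
        state = dp.AccountantState()
        last = 0.0
        for _ in range(5):
            state.step(0.2, 1.0)
            eps, _ = dp.convert_to_eps(state, 1e-3)
            assert eps >= last
            last = eps

    def test_delta_validation(self):
        with pytest.raises(ValueError):
            dp.convert_to_eps(dp.AccountantState(), 1.5)


class TestDeltaRule:
    @pytest.mark.parametrize("n,expected", [
        (350, 0.9 / 350), (10, 1e-2), (90, 1e-2), (1000, 9e-4)])
    def test_values(self, n, expected):
        assert dp.delta_for_client(n) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dp.delta_for_client(0)


class TestClipping:
    def test_scales_large_gradients_to_the_bound(self, rng):
        g = {"w": np.array([[3.0, 4.0]])}          # norm 5, C = 2.5
        clipped = dp.clip_per_sample(g, 2.5)
        assert np.linalg.norm(clipped["w"]) == pytest.approx(2.5)
        assert np.allclose(clipped["w"] / np.linalg.norm(clipped["w"]),
                           g["w"] / 5.0)

    def test_leaves_small_gradients_unchanged(self):
        g = {"w": np.array([[0.3, 0.4]])}          # norm 0.5, C = 1
        assert np.allclose(dp.clip_per_sample(g, 1.0)["w"], g["w"])

    def test_random_batch_norms_bounded(self, rng):
        g = {"a": rng.normal(size=(10, 4, 4)), "b": rng.normal(size=(10, 7))}
        clipped = dp.clip_per_sample(g, 0.8)
        joint = np.concatenate([clipped["a"].reshape(10, -1),
                                clipped["b"]], axis=1)
        assert np.all(np.linalg.norm(joint, axis=1) <= 0.8 + 1e-9)

    def test_per_layer_mode_bounds_each_entry(self, rng):
        g = {"a": rng.normal(size=(6, 5)) * 10,
             "b": rng.normal(size=(6, 3)) * 10}
        clipped = dp.clip_per_sample(g, {"a": 1.0, "b": 0.5},
                                     mode="per_layer")
        assert np.all(np.linalg.norm(clipped["a"], axis=1) <= 1.0 + 1e-9)
        assert np.all(np.linalg.norm(clipped["b"], axis=1) <= 0.5 + 1e-9)

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            dp.clip_per_sample({"w": np.ones((1, 2))}, 0.0)


class TestNoisyAggregate:
    def test_zero_noise_is_exact_mean(self, rng):
        g = {"w": rng.normal(size=(4, 3))}
        out = dp.noisy_aggregate(g, 1.0, 0.0, rng)
        assert np.allclose(out["w"], g["w"].mean(axis=0))

    def test_noise_scale_matches_sigma_c_over_batch(self):
        rng = np.random.default_rng(0)
        sigma, C, batch, n = 0.5, 2.0, 4, 20000
        draws = np.array([dp.noisy_aggregate(
            {"w": np.zeros((batch, 1))}, C, sigma, rng)["w"][0]
            for _ in range(n)])
        assert draws.std() == pytest.approx(sigma * C / batch, rel=0.05)

    def test_different_seeds_differ(self):
        g = {"w": np.zeros((2, 3))}
        a = dp.noisy_aggregate(g, 1.0, 1.0, np.random.default_rng(1))
        b = dp.noisy_aggregate(g, 1.0, 1.0, np.random.default_rng(2))
        assert not np.allclose(a["w"], b["w"])


class TestNoiseCalibration:
    def test_returned_sigma_is_tight(self):
        target, delta, q, steps = 6.0, 1e-2, 0.1, 100
        sigma = dp.calibrate_noise(target, delta, q, steps)

        def spent(s):
            st = dp.AccountantState()
            st.rdp = steps * dp.rdp_step(q, s, st.alphas)
            st.steps = steps
            return dp.convert_to_eps(st, delta)[0]

        assert spent(sigma) <= target
        assert spent(sigma / 1.1) > target

    def test_monotone_in_target_epsilon(self):
        kw = dict(delta=1e-2, q=0.2, planned_steps=50)
        assert dp.calibrate_noise(1.0, **kw) > dp.calibrate_noise(10.0, **kw)

    def test_infeasible_budget_raises(self):
        with pytest.raises(ValueError):
            dp.calibrate_noise(0.01, 1e-5, 1.0, 1000,
                               sigma_range=(0.2, 5.0))


class TestClippingCalibration:
    def test_reproducible_and_positive(self, toy_model_bn, rng):
        from fedleak import synthetic_data as sd

        model, pset = toy_model_bn
        imgs = [sd.make_image(sd.PEDIATRIC, i % 2, 10, i % 2, 32,
                              np.random.default_rng(i)) for i in range(12)]
        X = np.stack([im.pixels for im in imgs])
        y = np.array([im.label for im in imgs], float)
        c1 = dp.calibrate_clipping(model, pset, X, y, epochs=2, seed=4)
        c2 = dp.calibrate_clipping(model, pset, X, y, epochs=2, seed=4)
        assert c1 == pytest.approx(c2, abs=1e-3)
        assert c1 > 0

    def test_per_layer_medians_bounded_by_global(self, toy_model_bn):
        from fedleak import synthetic_data as sd

        model, pset = toy_model_bn
        imgs = [sd.make_image(sd.ADULT, i % 2, 40, i % 2, 32,
                              np.random.default_rng(100 + i))
                for i in range(12)]
        X = np.stack([im.pixels for im in imgs])
        y = np.array([im.label for im in imgs], float)
        global_c = dp.calibrate_clipping(model, pset, X, y, epochs=1, seed=0)
        per_layer = dp.calibrate_clipping(model, pset, X, y, epochs=1,
                                          seed=0, mode="per_layer")
        bound = global_c * math.sqrt(len(per_layer))
        assert all(v <= bound + 1e-9 for v in per_layer.values())

    def test_empty_auxiliary_set_rejected(self, toy_model_bn):
        model, pset = toy_model_bn
        with pytest.raises(ValueError):
            dp.calibrate_clipping(model, pset, np.empty((0, 32, 32)),
                                  np.empty(0))


def test_aggregation_never_advances_the_accountant(toy_model_bn, rng):
    """Post-processing closure: averaging noised updates is free."""
    from fedleak.federated_core import federated_average

    _, pset = toy_model_bn
    spec = dp.PrivacySpec(10.0, 1e-2, 1.0, 1.0, 1.0, 5)
    acct = dp.AccountantState()
    hook = dp.make_dp_hook(spec, acct, rng)
    hook({"fc.bias": rng.normal(size=(2, 1))})
    before = (acct.steps, acct.rdp.copy())
    federated_average([(pset, 3), (pset.copy(), 5)])
    assert acct.steps == before[0]
    assert np.array_equal(acct.rdp, before[1])
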