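"""TAMSD estimator, exponent/crossover fitting, scatter, state splitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anomemb.dichotomy import DichotomousSeries
from anomemb.synthgen import FbmParams, gen_ctrw, gen_fbm
from anomemb.tamsd import (
    TamsdCurve,
    Trajectory,
    default_lags,
    detect_crossover,
    diffusion_coefficient,
    ensemble_tamsd,
    fit_exponent,
    local_slope,
    relative_sd,
    subtract_reference,
    tamsd,
    tamsd_by_state,
)


def brute_force_tamsd(pos: np.ndarray, m: int) -> float:
    total = 0.0
    n = len(pos)
    for i in range(n - m):
        d = pos[i + m] - pos[i]
        total += float(d @ d)
    return total / (n - m)


class TestEstimator:
    @given(st.integers(10, 200), st.integers(1, 3), st.integers(0, 10_000))
    def test_matches_brute_force_double_loop(self, n, dim, seed):
        rng = np.random.default_rng(seed)
        pos = rng.standard_normal((n, dim)).cumsum(axis=0)
        traj = Trajectory(times=np.arange(n, dtype=float), positions=pos)
        lags = [1, 2, n // 3, n - 1]
        curve = tamsd(traj, lags=lags)
        for lag, val in zip(curve.lags, curve.values):
            assert val == pytest.approx(brute_force_tamsd(pos, int(lag)),
                                        rel=1e-12)

    def test_ballistic_is_exact(self):
        t = np.arange(100, dtype=float)
        v = 0.7
        traj = Trajectory(times=t, positions=(v * t)[:, None])
        c = tamsd(traj, lags=[1, 5, 20])
        np.testing.assert_allclose(c.values, v**2 * c.lags**2, rtol=1e-12)

    def test_constant_position_is_zero(self):
        traj = Trajectory(times=np.arange(50, dtype=float),
                          positions=np.ones((50, 2)))
        assert np.all(tamsd(traj, lags=[1, 10]).values == 0)

    def test_brownian_matches_2dD_closed_form(self):
        """2D Brownian motion with D=1 gives TAMSD ~ 4*lag within 3 SE."""
        rng = np.random.default_rng(21)
        vals = []
        lag = 10
        for _ in range(200):
            pos = np.sqrt(2.0) * rng.standard_normal((2000, 2)).cumsum(axis=0)
            traj = Trajectory(times=np.arange(2000, dtype=float), positions=pos)
            vals.append(tamsd(traj, lags=[lag]).values[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 4 * lag) < 3 * se

    def test_rigid_motions_and_scaling(self):
        rng = np.random.default_rng(22)
        pos = rng.standard_normal((300, 2)).cumsum(axis=0)
        t = np.arange(300, dtype=float)
        base = tamsd(Trajectory(times=t, positions=pos), lags=[1, 7, 30])
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = tamsd(Trajectory(times=t, positions=pos @ R.T + [5.0, -3.0]),
                      lags=[1, 7, 30])
        np.testing.assert_allclose(moved.values, base.values, rtol=1e-10)
        scaled = tamsd(Trajectory(times=t, positions=2.5 * pos), lags=[1, 7, 30])
        np.testing.assert_allclose(scaled.values, 2.5**2 * base.values,
                                   rtol=1e-12)

    def test_lag_must_be_below_measurement_time(self):
        traj = Trajectory(times=np.arange(20, dtype=float),
                          positions=np.zeros((20, 1)))
        with pytest.raises(ValueError):
            tamsd(traj, lags=[25])

    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="resampl"):
            Trajectory(times=np.array([0.0, 1.0, 3.0, 4.0]),
                       positions=np.zeros((4, 1)))


class TestReferenceSubtraction:
    def test_identity_cancellation(self):
        t = np.arange(10, dtype=float)
        pos = np.random.default_rng(0).standard_normal((10, 2))
        out = subtract_reference(Trajectory(times=t, positions=pos,
                                            reference=pos.copy()))
        assert np.all(out.positions == 0) and out.reference is None

    def test_zero_reference_is_noop(self):
        t = np.arange(10, dtype=float)
        pos = np.random.default_rng(1).standard_normal((10, 2))
        out = subtract_reference(Trajectory(times=t, positions=pos,
                                            reference=np.zeros((10, 2))))
        np.testing.assert_array_equal(out.positions, pos)

    def test_missing_reference_rejected(self):
        traj = Trajectory(times=np.arange(5, dtype=float),
                          positions=np.zeros((5, 1)))
        with pytest.raises(ValueError):
            subtract_reference(traj)

    def test_drift_removal_restores_fbm_exponent(self):
        """fBM plus a linear drift (the leaflet COM) recovers the pure-fBM
        exponent after reference subtraction, within 0.03."""
        p = FbmParams(hurst=0.325, n_steps=20_000, dim=2, n_traj=10, seed=23)
        pure_curves, corr_curves = [], []
        for tr in gen_fbm(p):
            drift = 0.05 * tr.times[:, None] * np.array([1.0, 0.5])
            drifted = Trajectory(times=tr.times, positions=tr.positions + drift,
                                 reference=drift)
            pure_curves.append(tamsd(tr))
            corr_curves.append(tamsd(subtract_reference(drifted)))
        a_pure = fit_exponent(ensemble_tamsd(pure_curves), (1, 100)).alpha
        a_corr = fit_exponent(ensemble_tamsd(corr_curves), (1, 100)).alpha
        assert abs(a_pure - a_corr) < 0.03


class TestEnsembleAndFits:
    def test_single_curve_mean_is_itself(self):
        c = TamsdCurve(lags=np.array([1.0, 2.0]), values=np.array([1.0, 2.0]),
                       T=100.0, dim=2)
        np.testing.assert_array_equal(ensemble_tamsd([c]).values, c.values)

    def test_mean_of_c_and_3c(self):
        lags = np.array([1.0, 2.0, 4.0])
        c1 = TamsdCurve(lags=lags, values=np.array([1.0, 2.0, 4.0]), T=40.0,
                        dim=2)
        c3 = TamsdCurve(lags=lags, values=3 * c1.values, T=40.0, dim=2)
        np.testing.assert_allclose(ensemble_tamsd([c1, c3]).values,
                                   2 * c1.values)

    def test_mismatched_grids_rejected(self):
        a = TamsdCurve(lags=np.array([1.0, 2.0]), values=np.ones(2), T=10.0,
                       dim=2)
        b = TamsdCurve(lags=np.array([1.0, 3.0]), values=np.ones(2), T=10.0,
                       dim=2)
        with pytest.raises(ValueError):
            ensemble_tamsd([a, b])

    def test_exact_power_laws_recovered(self):
        lags = np.geomspace(1, 100, 20)
        c = TamsdCurve(lags=lags, values=4 * lags, T=1000.0, dim=2)
        f = fit_exponent(c, (1, 100))
        assert f.alpha == pytest.approx(1.0, abs=1e-10)
        assert f.D_a == pytest.approx(1.0, rel=1e-10)
        c2 = TamsdCurve(lags=lags, values=2 * lags**0.5, T=1000.0, dim=2)
        f2 = fit_exponent(c2, (1, 100))
        assert f2.alpha == pytest.approx(0.5, abs=1e-10)
        assert f2.D_a == pytest.approx(0.5, rel=1e-10)

    def test_ensemble_tightens_exponent_estimate(self, fbm_h0325_ensemble,
                                                 fbm_h0325_mean_tamsd):
        singles = [fit_exponent(tamsd(t), (1, 100)).alpha
                   for t in fbm_h0325_ensemble[:10]]
        mean_alpha = fit_exponent(fbm_h0325_mean_tamsd, (1, 100)).alpha
        assert abs(mean_alpha - 0.65) <= np.mean(np.abs(np.array(singles) - 0.65))

    @pytest.mark.parametrize("hurst", [0.25, 0.325, 0.5, 0.75])
    def test_alpha_equals_twice_hurst(self, hurst):
        p = FbmParams(hurst=hurst, n_steps=100_000, dim=2, n_traj=25,
                      seed=int(1000 * hurst))
        ens = ensemble_tamsd([tamsd(t) for t in gen_fbm(p)])
        fit = fit_exponent(ens, (1, 100))
        assert abs(fit.alpha - 2 * hurst) < 0.05


class TestLocalSlopeAndCrossover:
    def test_exact_power_law_slope_constant(self):
        lags = np.geomspace(1, 1000, 30)
        c = TamsdCurve(lags=lags, values=lags**0.7, T=1e4, dim=2)
        out = local_slope(c, window=5)
        np.testing.assert_allclose(out[:, 1], 0.7, atol=1e-10)

    def test_ballistic_slope_is_two(self):
        lags = np.geomspace(1, 1000, 30)
        c = TamsdCurve(lags=lags, values=lags**2, T=1e4, dim=2)
        assert np.allclose(local_slope(c, window=5)[:, 1], 2.0)

    def test_window_too_large_rejected(self):
        lags = np.geomspace(1, 10, 5)
        c = TamsdCurve(lags=lags, values=lags, T=100.0, dim=2)
        with pytest.raises(ValueError):
            local_slope(c, window=7)

    def test_constructed_crossover_recovered_exactly(self):
        lags = np.geomspace(1, 1000, 40)
        vals = np.where(lags < 10, 2 * lags**0.65,
                        2 * 10**0.65 * (lags / 10) ** 1.0)
        cx = detect_crossover(TamsdCurve(lags=lags, values=vals, T=1e4, dim=2))
        assert cx.crossover_lag == pytest.approx(10.0, rel=0.06)
        assert cx.alpha_short == pytest.approx(0.65, abs=0.02)
        assert cx.alpha_long == pytest.approx(1.0, abs=0.02)
        assert cx.significant

    def test_pure_power_law_flagged_not_significant(self):
        lags = np.geomspace(1, 1000, 40)
        cx = detect_crossover(TamsdCurve(lags=lags, values=3 * lags**0.7,
                                         T=1e4, dim=2))
        assert not cx.significant
        assert abs(cx.alpha_short - cx.alpha_long) < 0.02

    def test_tempered_ensemble_breakpoint_near_generator_crossover(
            self, tempered_mean_tamsd):
        cx = detect_crossover(tempered_mean_tamsd)
        assert 10.0 / 3 <= cx.crossover_lag <= 10.0 * 3
        assert cx.alpha_short < cx.alpha_long

    def test_tempered_local_slope_rises_through_crossover(
            self, tempered_mean_tamsd):
        out = local_slope(tempered_mean_tamsd, window=9)
        short = out[:3, 1].mean()  # smallest available lags (~dt scale)
        long_ = out[out[:, 0] >= 300, 1].mean()
        assert short < 0.85 and long_ > 0.92 and short < long_


class TestDiffusionCoefficient:
    def test_exact_linear_curves(self):
        lags = np.linspace(1, 50, 25)
        c2 = TamsdCurve(lags=lags, values=4 * lags, T=500.0, dim=2)
        assert diffusion_coefficient(c2, (1, 50)) == pytest.approx(1.0)
        c3 = TamsdCurve(lags=lags, values=6 * lags, T=500.0, dim=3)
        assert diffusion_coefficient(c3, (1, 50)) == pytest.approx(1.0)

    def test_brownian_generator_parameter_recovered(self):
        D = 0.25
        p = FbmParams(hurst=0.5, n_steps=10_000, dim=2, n_traj=100,
                      step_scale=np.sqrt(2 * D), seed=24)
        ens = ensemble_tamsd([tamsd(t) for t in gen_fbm(p)])
        got = diffusion_coefficient(ens, (10, 500))
        assert abs(got - D) < 0.02


class TestRelativeSd:
    def test_identical_curves_give_zero(self):
        c = TamsdCurve(lags=np.array([1.0, 2.0]), values=np.array([3.0, 4.0]),
                       T=20.0, dim=2)
        assert relative_sd([c, c, c], 2.0) == 0.0

    def test_two_point_example(self):
        lags = np.array([1.0, 2.0])
        a = TamsdCurve(lags=lags, values=np.array([1.0, 1.0]), T=20.0, dim=2)
        b = TamsdCurve(lags=lags, values=np.array([3.0, 3.0]), T=20.0, dim=2)
        assert relative_sd([a, b], 2.0) == pytest.approx(0.5)

    def test_fbm_scatter_below_ctrw_scatter(self):
        T = 1000
        fbm_curves = [tamsd(t, lags=[T // 10]) for t in
                      gen_fbm(FbmParams(hurst=0.5, n_steps=T, dim=2,
                                        n_traj=100, seed=25))]
        ctrw_curves = [tamsd(t, lags=[T // 10]) for t in
                       gen_ctrw(T, 0.5, 1.0, dim=2, n_traj=100, seed=26)]
        assert relative_sd(fbm_curves, T // 10) < relative_sd(ctrw_curves,
                                                              T // 10)

    def test_ergodic_scatter_shrinks_with_T_but_ctrw_does_not(self):
        """fBM relative scatter decreases with measurement time (ergodic);
        heavy-tailed CTRW scatter stays O(1) (ergodicity breaking)."""
        out = {}
        for T in (1024, 8192):
            fbm_curves = [tamsd(t, lags=[10]) for t in
                          gen_fbm(FbmParams(hurst=0.5, n_steps=T, dim=2,
                                            n_traj=100, seed=27))]
            ctrw_curves = [tamsd(t, lags=[10]) for t in
                           gen_ctrw(T, 0.5, 1.0, dim=2, n_traj=100, seed=28)]
            out[T] = (relative_sd(fbm_curves, 10), relative_sd(ctrw_curves, 10))
        assert out[8192][0] < 0.6 * out[1024][0]
        assert out[8192][1] > 0.3


class TestStateConditionedTamsd:
    def _brownian(self, n, D, rng):
        return np.sqrt(2 * D) * rng.standard_normal((n, 2)).cumsum(axis=0)

    def test_single_state_equals_plain_tamsd(self):
        rng = np.random.default_rng(29)
        pos = self._brownian(500, 1.0, rng)
        t = np.arange(500, dtype=float)
        traj = Trajectory(times=t, positions=pos)
        states = DichotomousSeries(times=t, states=np.ones(500, dtype=int))
        out = tamsd_by_state(traj, states, min_dwell=10.0, lags=[1, 5, 20])
        assert out[-1] is None
        ref = tamsd(traj, lags=[1, 5, 20])
        np.testing.assert_allclose(out[+1].values, ref.values, rtol=1e-12)

    def test_two_state_diffusivities_recovered(self):
        """Switching every 50 steps between D=0.5 and D=1.0: the per-state
        estimates are ordered and each within 15%."""
        rng = np.random.default_rng(30)
        n = 40_000
        period = 50
        state = np.where((np.arange(n) // period) % 2 == 0, 1, -1)
        D = np.where(state == 1, 0.5, 1.0)
        steps = np.sqrt(2 * D)[:, None] * rng.standard_normal((n, 2))
        pos = np.vstack([np.zeros((1, 2)), steps.cumsum(axis=0)[:-1]])
        t = np.arange(n, dtype=float)
        traj = Trajectory(times=t, positions=pos)
        states = DichotomousSeries(times=t, states=state)
        out = tamsd_by_state(traj, states, min_dwell=20.0, lags=[1, 2, 4, 8])
        D_high = diffusion_coefficient(out[+1], (1, 8))
        D_low = diffusion_coefficient(out[-1], (1, 8))
        assert D_high < D_low
        assert abs(D_high - 0.5) < 0.15 * 0.5
        assert abs(D_low - 1.0) < 0.15 * 1.0

    def test_min_dwell_longer_than_runs_gives_empty(self):
        t = np.arange(100, dtype=float)
        traj = Trajectory(times=t, positions=np.zeros((100, 2)))
        states = DichotomousSeries(
            times=t, states=np.where(np.arange(100) % 10 < 5, 1, -1))
        out = tamsd_by_state(traj, states, min_dwell=50.0, lags=[1, 2])
        assert out[+1] is None and out[-1] is None


def test_default_lags_grid_properties():
    lags = default_lags(T=10_000.0, dt=1.0)
    assert lags[0] == 1.0
    assert lags[-1] <= 1000.0
    assert np.all(np.diff(lags) > 0)
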