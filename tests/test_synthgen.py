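"""Generators: increment statistics, sojourn laws, renewal construction."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from anomemb.synthgen import (
    FbmParams,
    RenewalSeriesParams,
    SojournParams,
    fgn_autocovariance,
    gen_alternating_renewal,
    gen_contact_count,
    gen_ctrw,
    gen_fbm,
    gen_tempered_fbm,
    gen_toy_membrane_frames,
    sample_sojourns,
    sojourn_mean,
    tempered_msd,
)
from anomemb.tamsd import ensemble_tamsd, fit_exponent, tamsd
from anomemb.spectra import ensemble_psd
from anomemb.dichotomy import residence_times


class TestFbm:
    def test_increment_autocovariance_matches_closed_form(self):
        """Sample autocovariance of the increments equals the fGn form
        within 3 standard errors over 1000 paths (H=0.8)."""
        p = FbmParams(hurst=0.8, n_steps=512, dim=1, n_traj=1000, seed=1)
        incs = np.array([np.diff(t.positions[:, 0]) for t in gen_fbm(p)])
        theo = fgn_autocovariance(np.arange(6), 0.8)
        for k in range(6):
            a = incs[:, : incs.shape[1] - k]
            b = incs[:, k:]
            prods = (a * b).mean(axis=1)
            se = prods.std(ddof=1) / np.sqrt(len(prods))
            assert abs(prods.mean() - theo[k]) < 3 * se + 1e-12

    def test_h_half_is_brownian(self):
        p = FbmParams(hurst=0.5, n_steps=10_000, dim=2, n_traj=25, seed=2)
        ens = ensemble_tamsd([tamsd(t) for t in gen_fbm(p)])
        fit = fit_exponent(ens, (1, 100))
        assert abs(fit.alpha - 1.0) < 0.05

    def test_paths_start_at_origin_and_have_right_length(self):
        p = FbmParams(hurst=0.3, n_steps=64, dim=3, n_traj=2, seed=3)
        for t in gen_fbm(p):
            assert t.positions.shape == (65, 3)
            assert np.all(t.positions[0] == 0)

    def test_seed_reproducibility(self):
        p = FbmParams(hurst=0.33, n_steps=128, dim=2, n_traj=3, seed=7)
        a = gen_fbm(p)
        b = gen_fbm(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_hurst_rejected(self, hurst):
        with pytest.raises(ValueError):
            FbmParams(hurst=hurst, n_steps=100)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            FbmParams(hurst=0.5, n_steps=1)


class TestTemperedFbm:
    def test_infinite_crossover_reproduces_fbm_exactly(self):
        p = FbmParams(hurst=0.325, n_steps=256, dim=2, n_traj=2, seed=11)
        plain = gen_fbm(p)
        limit = gen_tempered_fbm(p, np.inf)
        for a, b in zip(plain, limit):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_long_lag_slope_is_diffusive(self, tempered_mean_tamsd):
        fit = fit_exponent(tempered_mean_tamsd, (100, 1000))
        assert abs(fit.alpha - 1.0) < 0.05

    def test_short_lag_slope_matches_tempered_theory(self):
        """Fitted short-lag slope agrees with the slope of the theoretical
        MSD obtained by summing the tempered autocovariance."""
        p = FbmParams(hurst=0.325, n_steps=16_384, dim=2, n_traj=100, seed=12)
        trajs = gen_tempered_fbm(p, 10.0)
        ens = ensemble_tamsd([tamsd(t, lags=np.arange(1, 6)) for t in trajs])
        fit = fit_exponent(ens, (1, 5))
        msd = tempered_msd(p, 10.0, 5)
        theo_slope = stats.linregress(np.log(np.arange(1, 6)),
                                      np.log(msd[1:6])).slope
        assert abs(fit.alpha - theo_slope) < 0.05

    def test_nonpositive_crossover_rejected(self):
        p = FbmParams(hurst=0.3, n_steps=64)
        with pytest.raises(ValueError):
            gen_tempered_fbm(p, 0.0)


class TestCtrw:
    def test_unit_waits_recover_lattice_walk(self):
        trajs = gen_ctrw(2000, 1.0, 1.0, dim=2, n_traj=25, seed=4)
        ens = ensemble_tamsd([tamsd(t) for t in trajs])
        fit = fit_exponent(ens, (1, 100))
        assert abs(fit.alpha - 1.0) < 0.05

    def test_zero_jump_scale_gives_zero_paths(self):
        for t in gen_ctrw(100, 0.5, 0.0, n_traj=2, seed=5):
            assert np.all(t.positions == 0)
            c = tamsd(t, lags=[1, 5, 10])
            assert np.all(c.values == 0)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            gen_ctrw(100, 1.5, 1.0)
        with pytest.raises(ValueError):
            gen_ctrw(100, 0.0, 1.0)


class TestSampleSojourns:
    def test_pure_pareto_matches_analytic_cdf(self):
        """KS distance below the 1% critical value against the Pareto CDF."""
        for gamma in (0.3, 0.57, 1.5):
            x = sample_sojourns(SojournParams(gamma=gamma, tau_c=np.inf),
                                10_000, seed=6)
            assert np.all(x >= 1.0)
            res = stats.kstest(x, lambda t, g=gamma: 1 - t ** (-g))
            crit = 1.628 / np.sqrt(len(x))  # 1% two-sided KS critical value
            assert res.statistic < crit

    @pytest.mark.parametrize("gamma,tau_c", [(0.3, 100.0), (0.57, 100.0),
                                             (1.5, 100.0)])
    def test_cutoff_law_matches_quadrature_cdf(self, gamma, tau_c):
        x = sample_sojourns(SojournParams(gamma=gamma, tau_c=tau_c), 10_000,
                            seed=7)
        z = quad(lambda t: t ** (-1 - gamma) * np.exp(-t / tau_c), 1, np.inf)[0]

        def cdf(t):
            t = np.atleast_1d(t)
            return np.array([
                quad(lambda u: u ** (-1 - gamma) * np.exp(-u / tau_c), 1, ti)[0] / z
                for ti in t
            ])

        sub = np.sort(x)[::20]  # quadrature CDF is slow; thin the sample
        res = stats.kstest(sub, cdf)
        crit = 1.628 / np.sqrt(len(sub))
        assert res.statistic < crit

    def test_sample_mean_matches_quadrature(self):
        p = SojournParams(gamma=0.57, tau_c=600.0, tau_min=1.0)
        x = sample_sojourns(p, 100_000, seed=8)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - sojourn_mean(p)) < 3 * se

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            sample_sojourns(SojournParams(gamma=0.5), 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SojournParams(gamma=0.0)
        with pytest.raises(ValueError):
            SojournParams(gamma=0.5, tau_c=-1.0)

    def test_low_acceptance_warns(self):
        with pytest.warns(RuntimeWarning):
            sample_sojourns(SojournParams(gamma=0.5, tau_c=0.1, tau_min=1.0),
                            10, seed=9)


class TestAlternatingRenewal:
    def test_degenerate_sojourns_give_square_wave(self):
        # gamma -> inf concentrates the Pareto at tau_min: fixed 10-dt sojourns
        soj = SojournParams(gamma=1e7, tau_c=np.inf, tau_min=10.0)
        s = gen_alternating_renewal(
            RenewalSeriesParams(high=soj, low=soj, total_time=400.0,
                                initial_state=+1, seed=10)
        )
        res = residence_times(s)
        interior = res.durations[~res.censored]
        assert np.all(interior == 10.0)  # strict square wave, period 20*dt
        assert np.all(res.states[1:] != res.states[:-1])

    def test_construction_sojourns_match_sampler_distribution(self):
        """Two-sample KS (5%) between construction sojourns and fresh
        sampler draws."""
        soj = SojournParams(gamma=0.8, tau_c=200.0)
        _, (dur, st, cens) = gen_alternating_renewal(
            RenewalSeriesParams(high=soj, low=soj, total_time=2e5, seed=11),
            return_sojourns=True,
        )
        fresh = sample_sojourns(soj, 5000, seed=12)
        res = stats.ks_2samp(dur[~cens], fresh)
        assert res.pvalue > 0.05

    def test_states_alternate(self):
        soj = SojournParams(gamma=0.8, tau_c=50.0)
        _, (dur, st, _) = gen_alternating_renewal(
            RenewalSeriesParams(high=soj, low=soj, total_time=5000.0, seed=13),
            return_sojourns=True,
        )
        assert np.all(st[1:] != st[:-1])
        assert np.all(dur > 0)

    def test_short_horizon_rejected(self):
        soj = SojournParams(gamma=0.5)
        with pytest.raises(ValueError):
            RenewalSeriesParams(high=soj, low=soj, total_time=0.5, dt=1.0)


class TestContactCount:
    def test_single_process_is_binary(self):
        soj = SojournParams(gamma=0.8, tau_c=100.0)
        cs = gen_contact_count(1, (soj, soj), 2000.0, seed=14)
        assert set(np.unique(cs.counts)) <= {0, 1}

    def test_counts_bounded_by_k(self):
        soj = SojournParams(gamma=0.8, tau_c=100.0)
        cs = gen_contact_count(4, (soj, soj), 2000.0, seed=15)
        assert cs.counts.min() >= 0 and cs.counts.max() <= 4

    def test_mean_matches_renewal_reward_ratio(self):
        """Mean of N(t) ~ K * E[ON] / (E[ON] + E[OFF]) (quadrature means),
        within 3 standard errors across 25 realizations."""
        on = SojournParams(gamma=0.55, tau_c=600.0)
        off = SojournParams(gamma=0.55, tau_c=300.0)
        target = 4 * sojourn_mean(on) / (sojourn_mean(on) + sojourn_mean(off))
        means = [gen_contact_count(4, (on, off), 1e5, seed=s).counts.mean()
                 for s in range(25)]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - target) < 3 * se

    def test_all_off_start_with_huge_off_sojourn_stays_zero(self):
        on = SojournParams(gamma=0.8, tau_c=50.0)
        off = SojournParams(gamma=5.0, tau_c=np.inf, tau_min=1e7)
        cs = gen_contact_count(3, (on, off), 1000.0, seed=16,
                               initial_state=-1)
        assert np.all(cs.counts == 0)

    def test_superposition_psd_is_k_times_single(self):
        """Independent superposition: ensemble PSD of K processes equals K
        times the single-process ensemble PSD (stochastic tolerance)."""
        soj = SojournParams(gamma=0.8, tau_c=100.0)
        k_series = [gen_contact_count(4, (soj, soj), 2**14, seed=s).counts
                    for s in range(30)]
        one_series = [gen_contact_count(1, (soj, soj), 2**14, seed=1000 + s).counts
                      for s in range(30)]
        pk = ensemble_psd([c.astype(float) for c in k_series])
        p1 = ensemble_psd([c.astype(float) for c in one_series])
        band = (pk.frequencies > 1e-3) & (pk.frequencies < 1e-1)
        ratio = pk.values[band].sum() / p1.values[band].sum()
        assert 3.3 < ratio < 4.7


class TestToyMembrane:
    def test_zero_bound_fraction_means_zero_contacts(self):
        from anomemb.contacts import count_contacts

        tm = gen_toy_membrane_frames(8, 5, {"PIP3": 5}, bound_fraction=0.0,
                                     seed=17)
        for fr in tm.frames:
            assert count_contacts(fr, "PIP3", 0.7) == 0

    def test_scripted_contacts_counted_exactly(self):
        from anomemb.contacts import count_contacts

        tm = gen_toy_membrane_frames(20, 8, {"PIP3": 6}, bound_fraction=0.5,
                                     seed=18)
        fr = tm.frames[-1]
        assert count_contacts(fr, "PIP3", 0.7) == tm.expected_contacts["PIP3"]

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            gen_toy_membrane_frames(4, 1, {"PIP3": 50}, bound_fraction=1.0,
                                    seed=19)
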