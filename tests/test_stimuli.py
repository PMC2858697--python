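"""Stimulus generators: sources, bars, spike encodings, correlated trains."""

import itertools

import numpy as np
import pytest
from scipy import stats

from spikeica.stimuli import (BarsConfig, CorrelationSpec, bar_templates,
                              bars_sample, bars_to_rates, correlated_trains,
                              mix_rotate, onoff_encode, poisson_trains,
                              preprocess_image_patches, sample_laplace_pair,
                              solve_dichotomous_gaussian,
                              synthetic_grating_image)


class TestLaplaceSources:
    def test_moments(self, rng):
        s = sample_laplace_pair(rng, size=1_000_000)
        var = s.var(axis=0)
        assert np.all((var > 0.99) & (var < 1.01))
        kurt = stats.kurtosis(s, axis=0, fisher=True)
        np.testing.assert_allclose(kurt, 3.0, atol=0.1)
        r = np.corrcoef(s.T)[0, 1]
        assert abs(r) < 0.005


class TestMixing:
    def test_identity_and_quarter_turn(self):
        s = np.array([1.0, 2.0])
        np.testing.assert_allclose(mix_rotate(s, 0.0), s)
        np.testing.assert_allclose(mix_rotate(s, np.pi / 2), [-2.0, 1.0],
                                   atol=1e-12)

    def test_norm_preserved(self, rng):
        s = sample_laplace_pair(rng, size=100)
        x = mix_rotate(s, 0.7)
        np.testing.assert_allclose(np.linalg.norm(x, axis=1),
                                   np.linalg.norm(s, axis=1))


class TestOnOff:
    def test_rectification(self):
        np.testing.assert_allclose(onoff_encode(np.array([1.5, -0.3])),
                                   [1.5, 0.0, 0.0, 0.3])
        assert np.all(onoff_encode(np.zeros(2)) == 0)

    def test_reconstruction_and_exclusivity(self, rng):
        x = rng.standard_normal((200, 2))
        e = onoff_encode(x)
        np.testing.assert_allclose(e[:, 0::2] - e[:, 1::2], x)
        assert np.all(e[:, 0::2] * e[:, 1::2] == 0)


class TestPoissonTrains:
    def test_zero_rate_silent(self, rng):
        t = poisson_trains(np.zeros(3), 1000.0, 1.0, 2, rng)
        assert not t.any()
        assert t.shape == (1000, 6)

    def test_count_statistics(self, rng):
        t = poisson_trains(np.array([20.0]), 1_000_000.0, 1.0, 1, rng)
        count = int(t.sum())
        assert abs(count - 20000) < 3 * np.sqrt(20000)

    def test_synapses_of_one_channel_independent(self, rng):
        t = poisson_trains(np.array([20.0]), 1_000_000.0, 1.0, 2, rng).astype(float)
        r = np.corrcoef(t.T)[0, 1]
        assert abs(r) < 0.01

    def test_rate_above_one_per_bin_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_trains(np.array([2000.0]), 100.0, 1.0, 1, rng)


class TestBars:
    def test_templates_cover_grid_without_overlap_per_orientation(self):
        cfg = BarsConfig(grid=5, bar_width=1)
        t = bar_templates(cfg)
        assert t.shape == (10, 5, 5)
        assert np.all(t[:5].sum(axis=0) == 1)   # horizontal bars tile the grid
        assert np.all(t[5:].sum(axis=0) == 1)
        cfg2 = BarsConfig(grid=10, bar_width=2)
        assert bar_templates(cfg2).shape == (10, 10, 10)

    def test_empty_when_p_zero(self, rng):
        grid, ids = bars_sample(BarsConfig(mode="independent_p", p=0.0), rng)
        assert not grid.any() and ids == []

    def test_exactly_k_draws_k_distinct(self, rng):
        cfg = BarsConfig(mode="exactly_k", k=4)
        t = bar_templates(cfg)
        for _ in range(20):
            grid, ids = bars_sample(cfg, rng)
            assert len(ids) == 4 and len(set(ids)) == 4
            want = np.zeros_like(grid)
            for i in ids:
                want |= t[i]
            np.testing.assert_array_equal(grid, want)

    def test_center_pixel_probability_by_enumeration(self, rng):
        """3x3 grid, p=0.5: the center pixel is on iff its row or column bar
        is on; enumerating all 2^6 subsets gives P = 0.75."""
        cfg = BarsConfig(grid=3, bar_width=1, mode="independent_p", p=0.5)
        t = bar_templates(cfg)
        p_on = 0.0
        for subset in itertools.product([0, 1], repeat=6):
            grid = np.zeros((3, 3), bool)
            for i, b in enumerate(subset):
                if b:
                    grid |= t[i]
            p_on += grid[1, 1] * 0.5**6
        assert p_on == pytest.approx(0.75)
        draws = np.mean([bars_sample(cfg, rng)[0][1, 1] for _ in range(20000)])
        assert abs(draws - 0.75) < 0.01

    def test_rate_encoding_single_bar_hits_nu_max(self):
        cfg = BarsConfig(grid=5, bar_width=1)
        t = bar_templates(cfg)
        rates = bars_to_rates(t[2], cfg).reshape(5, 5)
        np.testing.assert_allclose(rates[t[2]], cfg.nu_max)
        np.testing.assert_allclose(rates[~t[2]], cfg.nu_bg)

    def test_rate_encoding_empty_grid_is_background(self):
        cfg = BarsConfig(grid=5, bar_width=1)
        rates = bars_to_rates(np.zeros((5, 5), bool), cfg)
        np.testing.assert_allclose(rates, cfg.nu_bg)

    def test_rate_encoding_two_disjoint_bars(self):
        cfg = BarsConfig(grid=5, bar_width=1)
        t = bar_templates(cfg)
        grid = t[0] | t[1]  # two parallel bars, no overlap
        rates = bars_to_rates(grid, cfg).reshape(5, 5)
        want = cfg.nu_bg + (cfg.nu_max - cfg.nu_bg) / np.sqrt(2.0)
        np.testing.assert_allclose(rates[grid], want)


class TestDichotomousGaussian:
    def test_independent_case(self):
        gamma, lam = solve_dichotomous_gaussian(20.0, 0.0, 1.0)
        assert lam == 0.0
        assert stats.norm.sf(gamma) == pytest.approx(0.02)

    def test_comonotone_limit(self):
        _, lam = solve_dichotomous_gaussian(10.0, 0.999, 1.0)
        assert lam > 0.999

    def test_solver_against_scipy_bivariate_cdf(self):
        """Dual route: the Plackett-integral orthant probability used by the
        solver agrees with scipy's bivariate normal CDF."""
        from spikeica.stimuli import _orthant_prob
        mvn = stats.multivariate_normal
        for lam in (0.2, 0.6, 0.9):
            for gamma in (0.5, 1.5, 2.3):
                ours = _orthant_prob(gamma, lam)
                ref = mvn(mean=[0, 0], cov=[[1, lam], [lam, 1]]).cdf(
                    [-gamma, -gamma])
                assert ours == pytest.approx(ref, abs=1e-9)

    def test_reproduces_target_correlation(self, rng):
        gamma, lam = solve_dichotomous_gaussian(10.0, 0.5, 1.0)  # p = 0.01
        n = 1_000_000
        common = rng.standard_normal(n)
        eps = rng.standard_normal((n, 2))
        z = np.sqrt(lam) * common[:, None] + np.sqrt(1 - lam) * eps
        x = z > gamma
        r = np.corrcoef(x.T.astype(float))[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_unattainable_correlation_rejected(self):
        with pytest.raises(ValueError):
            solve_dichotomous_gaussian(2000.0, 0.5, 1.0)  # p > 1


class TestCorrelatedTrains:
    @pytest.mark.parametrize("c", [0.0, 0.2, 0.5])
    def test_rates_and_correlations(self, c, rng):
        """Module acceptance gate: first and second moments match the spec."""
        spec = CorrelationSpec(nu=20.0, c=c, dt=1.0,
                               member_sets=[[0, 1, 2], [3, 4]])
        x = correlated_trains(spec, 100_000.0, rng, n_channels=7).astype(float)
        p_hat = x.mean(axis=0)
        se = np.sqrt(0.02 * 0.98 / x.shape[0])
        assert np.all(np.abs(p_hat - 0.02) < 4 * se)
        r = np.corrcoef(x.T)
        within = [r[0, 1], r[0, 2], r[1, 2], r[3, 4]]
        across = [r[0, 3], r[2, 4], r[0, 5], r[5, 6]]
        np.testing.assert_allclose(within, c, atol=0.02)
        np.testing.assert_allclose(across, 0.0, atol=0.01)

    def test_overlapping_member_sets_rejected(self):
        with pytest.raises(ValueError):
            CorrelationSpec(member_sets=[[0, 1], [1, 2]])

    def test_c_zero_matches_poisson_counts(self, rng):
        spec = CorrelationSpec(nu=20.0, c=0.0, dt=1.0, member_sets=[[0, 1]])
        x = correlated_trains(spec, 200_000.0, rng, n_channels=2)
        counts = x[:, 0].reshape(-1, 1000).sum(axis=1)  # per-second counts
        # distributional check against Poisson(20) via chi-square on binned counts
        edges = np.array([-0.5, 14.5, 17.5, 19.5, 21.5, 24.5, np.inf])
        obs, _ = np.histogram(counts, bins=edges)
        probs = np.diff(stats.poisson.cdf(edges, mu=20.0 * 0.9995))
        chi2, p = stats.chisquare(obs, probs / probs.sum() * obs.sum())
        assert p > 0.01


class TestImagePreprocessing:
    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess_image_patches(np.ones((64, 64)), rng=rng, n_patches=20)

    def test_onoff_maps_disjoint(self, rng):
        img = synthetic_grating_image(size=128)
        on, off = preprocess_image_patches(img, rng=rng, n_patches=30)
        assert np.all(((on - 2.0) * (off - 2.0)) == 0)  # nu_bg floor

    def test_dog_removes_dc(self):
        from scipy import ndimage
        img = 100.0 + synthetic_grating_image(size=128, noise=0.0)
        filtered = (ndimage.gaussian_filter(img, 1.0)
                    - ndimage.gaussian_filter(img, 3.0))
        assert abs(filtered.mean()) < 0.01 * abs(img.mean())
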