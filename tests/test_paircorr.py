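"""Pair correlation estimator (FFT vs brute force), composite fit, verdicts."""

import numpy as np
import pytest

import qsmlm
from qsmlm.paircorr import (RadialCorrelation, _gauss_conv_kernel,
                            classify_clustered, stochastic_term)
from helpers import make_table, pair_correlation_bruteforce


def _image_from_points(x, y, side, pixel_size=1.6):
    t = make_table(np.arange(len(x)), x, y, field_width=side, field_height=side)
    return qsmlm.binarize(t, pixel_size)


class TestAutocorrelate:
    @pytest.mark.parametrize("pattern", ["csr", "clustered"])
    def test_fft_matches_bruteforce_oracle(self, pattern):
        """The load-bearing check: FFT estimate == direct pair counting."""
        rng = np.random.default_rng(5)
        side = 2000.0
        if pattern == "csr":
            n = 1500
            x, y = rng.uniform(0, side, (2, n))
        else:
            centers = rng.uniform(0, side, (2, 60))
            x = np.repeat(centers[0], 20) + rng.normal(0, 25, 1200)
            y = np.repeat(centers[1], 20) + rng.normal(0, 25, 1200)
            keep = (x >= 0) & (x < side) & (y >= 0) & (y < side)
            x, y = x[keep], y[keep]
        img = _image_from_points(x, y, side)
        corr = qsmlm.autocorrelate(img, max_r=400.0)
        r_o, g_o, counts_o = pair_correlation_bruteforce(img, max_r=400.0)
        assert np.allclose(corr.r, r_o)
        assert np.allclose(corr.counts, counts_o, atol=0.51)
        occupied = counts_o > 0
        assert np.allclose(corr.g[occupied], g_o[occupied], rtol=0.05)

    def test_csr_is_flat_at_one(self):
        rng = np.random.default_rng(6)
        side = np.sqrt(20.0) * 1000
        x, y = rng.uniform(0, side, (2, 5000))
        corr = qsmlm.autocorrelate(_image_from_points(x, y, side))
        sel = corr.r > 10
        # binomial-style standard error per bin from the pair counts
        se = 1.0 / np.sqrt(np.maximum(corr.counts[sel], 1.0))
        assert np.all(np.abs(corr.g[sel] - 1.0) < 3 * np.maximum(se, 0.02) + 0.05)
        assert abs(corr.g[corr.r > 250].mean() - 1.0) < 0.02

    def test_duplicated_points_collapse_in_binary_image(self):
        rng = np.random.default_rng(7)
        side = 2000.0
        x, y = rng.uniform(0, side, (2, 800))
        img_single = _image_from_points(x, y, side)
        img_double = _image_from_points(np.r_[x, x], np.r_[y, y], side)
        g1 = qsmlm.autocorrelate(img_single, max_r=300.0)
        g2 = qsmlm.autocorrelate(img_double, max_r=300.0)
        assert np.allclose(g1.g, g2.g, rtol=1e-6)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        side = 2000.0
        centers = rng.uniform(200, side - 200, (2, 40))
        x = np.repeat(centers[0], 15) + rng.normal(0, 20, 600)
        y = np.repeat(centers[1], 15) + rng.normal(0, 20, 600)
        img = _image_from_points(x, y, side)
        img_shift = _image_from_points(
            (x + 160.0) % side, (y + 240.0) % side, side)  # 100/150 pixel torus shift
        img_rot = qsmlm.locio.BinaryImage(np.rot90(img.pixels).copy(),
                                          img.pixel_size, img.loss_fraction)
        g0 = qsmlm.autocorrelate(img, max_r=300.0)
        g_rot = qsmlm.autocorrelate(img_rot, max_r=300.0)
        assert np.allclose(g0.g, g_rot.g, rtol=1e-6)  # exact grid rotation
        g_shift = qsmlm.autocorrelate(img_shift, max_r=300.0)
        occ = (g0.counts > 20) & (g_shift.counts > 20)
        # torus shift re-wraps a few pairs across the edge: statistical agreement
        assert np.corrcoef(g0.g[occ], g_shift.g[occ])[0, 1] > 0.95

    def test_few_localizations_warns(self):
        img = _image_from_points(np.arange(10) * 100.0, np.arange(10) * 100.0, 2000.0)
        with pytest.warns(UserWarning, match="unreliable"):
            qsmlm.autocorrelate(img, max_r=300.0)


class TestFitProteinCorrelation:
    def test_recovers_own_model_noiselessly(self):
        """Noiseless synthetic curve with A=5, xi=20 is recovered to <=1%."""
        r = np.arange(2.5, 500, 5.0)
        sigma_bar, rho_loc, alpha = 12.0, 3.6e-4, 3.0
        rho_mol = rho_loc / alpha
        var = 2 * sigma_bar ** 2
        s, kernel = _gauss_conv_kernel(r, var, r.max() + 5 * sigma_bar)
        g = 1.0 + stochastic_term(r, sigma_bar, rho_mol) + kernel @ (5.0 * np.exp(-s / 20.0))
        corr = RadialCorrelation(r=r, g=g, counts=np.full_like(r, 1e4),
                                 rho_loc=rho_loc, n_localizations=7200)
        fit = qsmlm.fit_protein_correlation(corr, sigma_bar, alpha)
        assert fit.A == pytest.approx(5.0, rel=0.01)
        assert fit.xi == pytest.approx(20.0, rel=0.01)
        assert fit.clustered is True

    def test_n_per_cluster_identity_and_integral_oracle(self):
        """n = 1 + 2 pi A xi^2 rho_mol, cross-checked by numerical integration."""
        r = np.arange(2.5, 500, 5.0)
        sigma_bar, rho_loc = 12.0, 3.57e-4
        alpha = 3.0
        rho_mol = 1.19e-4
        var = 2 * sigma_bar ** 2
        s, kernel = _gauss_conv_kernel(r, var, r.max() + 5 * sigma_bar)
        g = (1.0 + stochastic_term(r, sigma_bar, rho_mol)
             + kernel @ (7.0 * np.exp(-s / 21.0)))
        corr = RadialCorrelation(r=r, g=g, counts=np.full_like(r, 1e4),
                                 rho_loc=alpha * rho_mol, n_localizations=7200)
        fit = qsmlm.fit_protein_correlation(corr, sigma_bar, alpha)
        assert fit.n_per_cluster == pytest.approx(
            1 + 2 * np.pi * 7.0 * 21.0 ** 2 * rho_mol, rel=1e-6)
        assert fit.n_per_cluster == pytest.approx(3.31, abs=0.02)
        # independent oracle: rho_mol * integral of (g_protein - 1) over the plane,
        # by numerical quadrature of the fitted exponential
        rq = np.linspace(0, 2000, 20001)
        integral = np.trapezoid(fit.A * np.exp(-rq / fit.xi) * 2 * np.pi * rq, rq)
        assert fit.n_per_cluster == pytest.approx(1 + rho_mol * integral, rel=1e-3)

    def test_csr_with_blinking_is_random(self, random_analysis):
        assert random_analysis.fit.clustered is False
        assert classify_clustered(random_analysis.fit) == "random"

    def test_clustered_preset_is_detected(self, bt474_analysis):
        assert bt474_analysis.fit.clustered is True
        assert bt474_analysis.fit.A > 0
        assert 5 <= bt474_analysis.fit.xi <= 200

    def test_recovered_parameters_monotone_in_truth(self):
        """xi and n/cluster rank-track the generative radius and occupancy."""
        from dataclasses import replace
        from scipy.stats import spearmanr
        xis, ns = [], []
        radii = [18.0, 24.0, 31.0]
        occs = [1.7, 3.0, 4.3]
        for rad in radii:
            fits = []
            for s in range(2):
                p = replace(qsmlm.preset("bt474"), radius_mean=rad, radius_sd=0.5,
                            radius_range=(rad - 1, rad + 1))
                t, _ = qsmlm.simulate_roi(p, seed=300 + s)
                fits.append(qsmlm.analyze_roi(t).fit.xi)
            xis.append(np.mean(fits))
        for occ in occs:
            fits = []
            for s in range(2):
                p = replace(qsmlm.preset("bt474"), occupancy_mean=occ, occupancy_sd=0.3,
                            occupancy_range=(max(occ - 0.5, 1.0), occ + 0.5))
                t, _ = qsmlm.simulate_roi(p, seed=400 + s)
                fits.append(qsmlm.analyze_roi(t).fit.n_per_cluster)
            ns.append(np.mean(fits))
        assert spearmanr(radii, xis).statistic > 0
        assert spearmanr(occs, ns).statistic > 0

    def test_needs_enough_bins(self):
        corr = RadialCorrelation(r=np.arange(5.0), g=np.ones(5), counts=np.ones(5),
                                 rho_loc=1e-4, n_localizations=500)
        with pytest.raises(ValueError):
            qsmlm.fit_protein_correlation(corr, 12.0, 3.0)
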