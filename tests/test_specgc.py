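"""Estimator behaviour: AR fit consistency, spectral closed forms, Geweke
GC properties, band averaging and invariances."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from gcnet import specgc
from gcnet.synthcohort import (
    BandTarget,
    TimeSeriesSet,
    VarModelSpec,
    analytic_band_adjacency,
    analytic_spectral_gc,
    make_var_model,
    simulate_var,
)


class TestFitVar:
    def test_recovers_known_var2_coefficients(self):
        coeff = np.array([[[0.4, 0.0], [0.3, 0.3]],
                          [[-0.2, 0.0], [0.1, -0.15]]])
        m = VarModelSpec(coeff=coeff, noise_cov=np.diag([1.0, 0.8]), fs=500.0)
        ts = simulate_var(m, 60_000, seed=21)
        fit = specgc.fit_var(ts.data[0], ts.data[1], 2, fs=500.0)
        assert np.max(np.abs(fit.coeff - coeff)) < 0.02
        assert np.max(np.abs(fit.noise_cov - m.noise_cov)) < 0.03

    def test_independent_white_noise_fits_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60_000)
        y = rng.standard_normal(60_000)
        fit = specgc.fit_var(x, y, 5, fs=500.0)
        assert np.max(np.abs(fit.coeff)) < 0.03

    def test_residual_covariance_is_psd_and_symmetric(self, fitted_pair):
        sigma = fitted_pair.noise_cov
        assert np.allclose(sigma, sigma.T)
        assert np.min(np.linalg.eigvalsh(sigma)) >= -1e-10

    def test_constant_series_raises_degenerate_error(self):
        with pytest.raises(specgc.DegenerateInputError):
            specgc.fit_var(np.ones(1000), np.random.default_rng(0).standard_normal(1000), 3)


class TestSpectralFactors:
    def test_white_noise_spectrum_is_identity(self):
        m = specgc.BivariateVarModel(order=1, coeff=np.zeros((1, 2, 2)),
                                     noise_cov=np.eye(2), fs=500.0)
        f = specgc.spectral_factors(m, np.linspace(0, 250, 32))
        assert np.allclose(f.spectrum, np.eye(2)[None], atol=1e-12)
        assert np.allclose(f.transfer, np.eye(2)[None], atol=1e-12)

    def test_ar1_spectrum_closed_form_at_zero(self):
        # S_00(f) = 1/|1 - 0.5 e^{-i 2 pi f / fs}|^2 -> 4.0 at f = 0
        coeff = np.zeros((1, 2, 2))
        coeff[0, 0, 0] = 0.5
        m = specgc.BivariateVarModel(order=1, coeff=coeff, noise_cov=np.eye(2),
                                     fs=500.0)
        f = specgc.spectral_factors(m, np.array([0.0, 100.0]))
        assert f.spectrum[0, 0, 0].real == pytest.approx(4.0)
        expected = 1 / abs(1 - 0.5 * np.exp(-1j * 2 * np.pi * 100 / 500)) ** 2
        assert f.spectrum[1, 0, 0].real == pytest.approx(expected)

    def test_spectrum_diagonal_real_positive(self, fitted_pair):
        f = specgc.spectral_factors(fitted_pair, np.linspace(0, 125, 200))
        diag = np.diagonal(f.spectrum, axis1=1, axis2=2)
        assert np.allclose(diag.imag, 0, atol=1e-10)
        assert np.all(diag.real > 0)


class TestSpectralGC:
    def test_gc_non_negative_everywhere(self, fitted_pair):
        grid = specgc.make_freq_grid(250.0, 0.1)
        gi, gj = specgc.spectral_gc_pair(fitted_pair, grid)
        assert np.all(gi.gc >= 0) and np.all(gj.gc >= 0)

    def test_absent_reverse_causality_estimates_near_zero(self, fitted_pair):
        grid = specgc.make_freq_grid(250.0, 0.1)
        _, rev = specgc.spectral_gc_pair(fitted_pair, grid)
        assert rev.gc.max() < 0.01

    def test_estimate_tracks_analytic_oracle(self, coupled_pair_model,
                                             fitted_pair):
        grid = specgc.make_freq_grid(250.0, 0.1)
        oracle = analytic_spectral_gc(coupled_pair_model, grid)
        est, _ = specgc.spectral_gc_pair(fitted_pair, grid)
        peak = oracle[0, 1].max()
        assert np.max(np.abs(est.gc - oracle[0, 1])) < 0.10 * peak

    def test_geweke_integral_identity_on_fitted_model(self, fitted_pair):
        lam = np.arange(0, np.pi + 1e-12, 0.01)
        grid = lam * fitted_pair.fs / (2 * np.pi)
        gi, _ = specgc.spectral_gc_pair(fitted_pair, grid)
        integral = np.trapezoid(gi.gc, lam) / np.pi
        td = fitted_pair.time_domain_gc()[0]
        assert fitted_pair.instantaneous_gc() < 0.01
        assert integral == pytest.approx(td, rel=0.02)

    def test_band_gc_stable_between_order_30_and_40(self, coupled_pair_series):
        ts = coupled_pair_series
        grid = specgc.make_freq_grid(ts.fs, 0.1)
        vals = {}
        for p in (30, 40):
            fit = specgc.fit_var(ts.data[0], ts.data[1], p, fs=ts.fs)
            gi, _ = specgc.spectral_gc_pair(fit, grid)
            sel = (grid >= 8) & (grid <= 12)
            vals[p] = gi.gc[sel].mean()
        assert abs(vals[30] - vals[40]) / vals[30] < 0.15

    def test_gc_invariant_to_positive_scaling(self, coupled_pair_series):
        ts = coupled_pair_series
        grid = np.linspace(0, 125, 300)
        fit1 = specgc.fit_var(ts.data[0], ts.data[1], 12, fs=ts.fs)
        fit2 = specgc.fit_var(7.3 * ts.data[0], 7.3 * ts.data[1], 12, fs=ts.fs)
        g1, _ = specgc.spectral_gc_pair(fit1, grid)
        g2, _ = specgc.spectral_gc_pair(fit2, grid)
        assert np.max(np.abs(g1.gc - g2.gc)) < 1e-8


class TestConnectivityMatrices:
    def test_paper_grid_has_2501_samples(self):
        assert specgc.make_freq_grid(500.0, 0.1).size == 2501

    def test_tensor_shape_and_zero_diagonal_68_rois(self):
        rng = np.random.default_rng(3)
        ts = TimeSeriesSet("s", 500.0, rng.standard_normal((68, 400)),
                           [f"roi{i}" for i in range(68)])
        conn = specgc.connectivity_matrices(ts, p=5, freq_resolution=1.0)
        assert conn.tensor.shape == (68, 68, 251)
        assert np.all(np.diagonal(conn.tensor, axis1=0, axis2=1) == 0)
        assert not conn.failed_pairs

    def test_chain_topology_ordering(self):
        # truth 0 -> 1 -> 2: forward links dominate the absent 2 -> 0 link
        coeff = np.zeros((2, 3, 3))
        coeff[0][np.diag_indices(3)] = 0.4
        coeff[0, 1, 0] = 0.4
        coeff[0, 2, 1] = 0.4
        m = VarModelSpec(coeff=coeff, noise_cov=np.eye(3), fs=250.0)
        ts = simulate_var(m, 20_000, seed=2)
        conn = specgc.connectivity_matrices(ts, p=10, freq_resolution=0.5)
        summed = conn.tensor.sum(axis=2)
        assert summed[0, 1] > 5 * summed[2, 0]
        assert summed[1, 2] > 5 * summed[2, 0]

    def test_rank_agreement_with_oracle_on_cohort_model(self):
        """Among edges with any true (direct or indirect) influence, the
        estimated band adjacency rank-matches the analytic oracle; edges with
        no true influence stay near the estimator noise floor."""
        from gcnet.synthcohort import (_cohort_band_targets,
                                       default_partition_indices,
                                       demo_cohort_config)

        cfg = demo_cohort_config(seed=3)
        f_idx, p_idx, x_idx = default_partition_indices(10)
        targets, _sinks = _cohort_band_targets(cfg, f_idx, p_idx, x_idx, "low")
        m = make_var_model(10, targets, seed=cfg.seed, fs=250.0)
        oracle = analytic_band_adjacency(m, specgc.DEFAULT_BANDS,
                                         freq_resolution=0.1)
        ts = simulate_var(m, 60_000, seed=11).standardized()
        conn = specgc.connectivity_matrices(ts, p=30, freq_resolution=0.1)
        bc = specgc.band_average(conn)
        off = ~np.eye(10, dtype=bool)
        est = np.concatenate([bc.adjacency[b][off] for b in specgc.DEFAULT_BANDS])
        orc = np.concatenate([oracle[b][off] for b in specgc.DEFAULT_BANDS])
        linked = orc > 1e-6
        assert spearmanr(est[linked], orc[linked]).statistic > 0.9
        # no-influence edges stay well below the weakest direct coupling
        assert est[~linked].max() < 0.1 * oracle["theta"].max()


class TestBandAverage:
    def _conn(self, tensor, grid):
        return specgc.SpectralConnectivity("s", tensor, grid, ["a", "b"])

    def test_constant_spectrum_averages_to_constant(self):
        grid = specgc.make_freq_grid(500.0, 0.1)
        tensor = np.full((2, 2, grid.size), 0.7)
        tensor[np.arange(2), np.arange(2)] = 0
        bc = specgc.band_average(self._conn(tensor, grid))
        for A in bc.adjacency.values():
            assert A[0, 1] == pytest.approx(0.7)

    def test_theta_band_covers_41_grid_points(self):
        grid = specgc.make_freq_grid(500.0, 0.1)
        sel = (grid >= 4 - 1e-9) & (grid <= 8 + 1e-9)
        assert sel.sum() == 41

    def test_default_bands_are_the_four_canonical_ones(self):
        grid = specgc.make_freq_grid(500.0, 0.1)
        bc = specgc.band_average(self._conn(np.zeros((2, 2, grid.size)), grid))
        assert list(bc.adjacency) == ["theta", "alpha", "beta", "gamma"]
        assert bc.bands["beta"] == (14.0, 30.0)

    def test_empty_band_is_an_error(self):
        grid = np.array([0.0, 50.0, 100.0])
        with pytest.raises(ValueError, match="no grid point"):
            specgc.band_average(self._conn(np.zeros((2, 2, 3)), grid),
                                {"narrow": (10.0, 12.0)})
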