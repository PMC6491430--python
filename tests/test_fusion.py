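"""Fusion oracles: CRLB limits, the inverse-variance merge, weight curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from daisysmlm import EmitterTruth, OpticalModel, render_stack
from daisysmlm.axial import add_axial_estimates, z_from_astig, z_from_saf
from daisysmlm.calibrate import AstigLUT
from daisysmlm.detect import fit_psf
from daisysmlm.fusion import (crlb_astig_z, crlb_lateral, crlb_saf_z,
                              fuse_localizations, gaussian_psf_crlb, merge_scalar,
                              weight_curves)


class TestCRLBLateral:
    def test_shot_noise_limit(self):
        """background -> 0, small pixels: sigma -> width / sqrt(N)."""
        val = crlb_lateral(2750.0, 110.0, background=0.0, pixel=10.0)
        assert val == pytest.approx(110.0 / np.sqrt(2750.0), rel=0.01)

    def test_scaling_with_photons(self):
        s1 = crlb_lateral(2000.0, 110.0, background=0.0, pixel=10.0)
        s2 = crlb_lateral(4000.0, 110.0, background=0.0, pixel=10.0)
        assert s2 == pytest.approx(s1 / np.sqrt(2.0), rel=0.01)

    def test_matches_independent_fisher_integration(self):
        """Default conditions vs an independently coded Fisher summation."""
        n, w, b, a = 2750.0, 110.0, 100.0, 100.0
        val = crlb_lateral(n, w, background=b, pixel=a)

        # independent oracle: Fisher information for x0 with all six
        # parameters free (x0, y0, sx, sy, N, b), using numerical
        # derivatives of the pixel-integrated model
        from scipy.special import erf

        k = 7
        cents = np.arange(-k, k + 1) * a

        def mu(theta):
            x0, y0, sx, sy, nn, bb = theta
            ex = 0.5 * (erf((cents + a / 2 - x0) / (np.sqrt(2) * sx))
                        - erf((cents - a / 2 - x0) / (np.sqrt(2) * sx)))
            ey = 0.5 * (erf((cents + a / 2 - y0) / (np.sqrt(2) * sy))
                        - erf((cents - a / 2 - y0) / (np.sqrt(2) * sy)))
            return nn * np.outer(ey, ex) + bb

        theta0 = np.array([0.0, 0.0, w, w, n, b])
        eps = np.array([1e-3, 1e-3, 1e-3, 1e-3, 1e-1, 1e-4])
        grads = []
        for p in range(6):
            dp = np.zeros(6)
            dp[p] = eps[p]
            grads.append((mu(theta0 + dp) - mu(theta0 - dp)) / (2 * eps[p]))
        g = np.array([gr.ravel() for gr in grads])
        fisher = (g / mu(theta0).ravel()) @ g.T
        oracle = np.sqrt(np.linalg.inv(fisher)[0, 0])
        assert val == pytest.approx(oracle, rel=0.02)


class TestCRLBAstig:
    def test_zero_slope_diverges(self, optics):
        lut = AstigLUT(np.array([0.0, 10.0, 20.0]), np.array([0.0, 1e-12, 2e-12]))
        val = crlb_astig_z(2750.0, 150.0, 150.0, lut, 5.0, background=0.0)
        assert val > 1e6

    def test_photon_scaling(self, optics):
        lut = AstigLUT.from_optics(optics)
        wx, wy = optics.uaf_widths(300.0)
        s1 = crlb_astig_z(2750.0, wx, wy, lut, 300.0, background=0.0)
        s4 = crlb_astig_z(4 * 2750.0, wx, wy, lut, 300.0, background=0.0)
        assert s4 == pytest.approx(s1 / 2.0, rel=0.02)

    def test_matches_monte_carlo_sd(self, optics, rng):
        """CRLB at z=300 within 15% of the Monte-Carlo SD of z_from_astig."""
        lut = AstigLUT.from_optics(optics)
        z0 = 300.0
        wx, wy = optics.uaf_widths(z0)
        c = gaussian_psf_crlb(2750.0, wx, wy, background=100.0, pixel=100.0)
        n_mc = 2000
        wx_s = wx + rng.normal(0, c["sigma_wx"], n_mc)
        wy_s = wy + rng.normal(0, c["sigma_wy"], n_mc)
        z_mc, _ = z_from_astig(wx_s, wy_s, lut)
        pred = crlb_astig_z(2750.0, wx, wy, lut, z0, background=100.0)
        assert np.nanstd(z_mc) == pytest.approx(pred, rel=0.15)


class TestCRLBSaf:
    def test_slope_scaling(self):
        from daisysmlm.simulate import SAFCurve

        c1 = SAFCurve(0.85, 130.0)
        c2 = SAFCurve(1.70, 130.0)  # doubled ratio -> doubled slope at z=0
        s1 = crlb_saf_z(2750.0, 5100.0, c1, 0.0, var_n_uaf=2750.0, var_n_epi=5100.0)
        s2 = crlb_saf_z(2750.0, 5100.0, c2, 0.0, var_n_uaf=2750.0, var_n_epi=5100.0)
        assert s2 == pytest.approx(s1 / 2.0, rel=1e-6)

    def test_deep_z_diverges(self, optics):
        s = crlb_saf_z(2750.0, 2760.0, optics.saf_curve, 2000.0,
                       var_n_uaf=2750.0, var_n_epi=2760.0)
        assert s > 1e3

    def test_matches_monte_carlo_sd(self, optics, rng):
        """Coverslip conditions: propagation law vs Monte-Carlo z_from_saf SD."""
        curve = optics.saf_curve
        n_u, n_e = 2750.0, 2750.0 * (1 + curve.rho(0.0))
        var_u, var_e = n_u + 1500.0, n_e + 1500.0  # fitted-count variances
        n_mc = 4000
        nu = n_u + rng.normal(0, np.sqrt(var_u), n_mc)
        ne = n_e + rng.normal(0, np.sqrt(var_e), n_mc)
        z_mc, _, _, _ = z_from_saf(ne, nu, curve)
        pred = crlb_saf_z(n_u, n_e, curve, 0.0, var_n_uaf=var_u, var_n_epi=var_e)
        assert np.nanstd(z_mc) == pytest.approx(pred, rel=0.15)


class TestMergeScalar:
    def test_symmetric_average(self):
        v, s = merge_scalar(10.0, 2.0, 20.0, 2.0)
        assert v == pytest.approx(15.0)
        assert s == pytest.approx(2.0 / np.sqrt(2.0))

    def test_worked_example(self):
        """v1=100 +- 15, v2=130 +- 30 -> 106.0 +- 13.42."""
        v, s = merge_scalar(100.0, 15.0, 130.0, 30.0)
        assert v == pytest.approx(106.0, abs=1e-9)
        assert s == pytest.approx(13.4164, abs=1e-3)

    def test_single_source_limit(self):
        v, s = merge_scalar(42.0, 3.0, 99.0, np.inf)
        assert (v, s) == (42.0, 3.0)
        v, s = merge_scalar(42.0, 3.0, np.nan, 5.0)
        assert (v, s) == (42.0, 3.0)

    def test_both_absent(self):
        v, s = merge_scalar(np.nan, np.inf, np.nan, np.inf)
        assert np.isnan(v) and np.isinf(s)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(v1=st.floats(-1e3, 1e3), v2=st.floats(-1e3, 1e3),
           s1=st.floats(0.1, 1e2), s2=st.floats(0.1, 1e2))
    def test_equals_two_normal_posterior(self, v1, v2, s1, s2):
        """Fused value maximizes the product of the two normal densities, and
        the fused value always lies between the inputs."""
        v, s = merge_scalar(v1, s1, v2, s2)
        nll = lambda x: ((x - v1) / s1) ** 2 + ((x - v2) / s2) ** 2
        res = minimize_scalar(nll, bounds=(min(v1, v2) - 1, max(v1, v2) + 1),
                              method="bounded")
        assert v == pytest.approx(res.x, abs=1e-3)
        assert min(v1, v2) - 1e-9 <= v <= max(v1, v2) + 1e-9
        assert s <= min(s1, s2) + 1e-12


class TestFuseLocalizations:
    def _record(self, optics, bundle, z, with_epi=True):
        n_u, n_e = optics.expected_counts(5500.0, z)
        wx, wy = optics.uaf_widths(z)
        w_e = optics.epi_width(z)
        row = dict(frame=0, x_uaf_nm=5000.0, y_uaf_nm=5000.0, wx_uaf_nm=wx,
                   wy_uaf_nm=wy, n_uaf=n_u, n_uaf_sum=n_u, bg_uaf=100.0,
                   x_epi_nm=5005.0 if with_epi else np.nan,
                   y_epi_nm=5005.0 if with_epi else np.nan,
                   wx_epi_nm=w_e if with_epi else np.nan,
                   wy_epi_nm=w_e if with_epi else np.nan,
                   n_epi=n_e if with_epi else np.nan,
                   n_epi_sum=n_e if with_epi else np.nan,
                   bg_epi=100.0 if with_epi else np.nan, pair_distance_nm=np.nan)
        df = add_axial_estimates(pd.DataFrame([row]), bundle)
        return fuse_localizations(df, bundle.lut, bundle.saf_curve)

    def test_uaf_only_record_passthrough(self, optics, bundle):
        out = self._record(optics, bundle, 600.0, with_epi=False)
        assert out.x_nm.iloc[0] == pytest.approx(5000.0)
        assert not out.saf_used.iloc[0]
        assert out.sigma_x_nm.iloc[0] == pytest.approx(out.sigma_x_uaf_nm.iloc[0])

    def test_saf_dominates_at_coverslip(self, optics, bundle):
        out = self._record(optics, bundle, 0.0)
        assert out.weight_saf.iloc[0] > out.weight_astig.iloc[0]

    def test_saf_weight_negligible_at_800(self, optics, bundle):
        out = self._record(optics, bundle, 800.0)
        assert out.weight_saf.iloc[0] < 0.01

    def test_fused_sigma_below_sources(self, optics, bundle):
        out = self._record(optics, bundle, 100.0)
        assert out.sigma_z_nm.iloc[0] <= out.sigma_z_saf_nm.iloc[0]
        assert out.sigma_z_nm.iloc[0] <= out.sigma_z_astig_nm.iloc[0]
        assert out.sigma_x_nm.iloc[0] <= min(out.sigma_x_uaf_nm.iloc[0],
                                             out.sigma_x_epi_nm.iloc[0])

    def test_fused_z_sd_beats_single_sources(self, optics, bundle, rng):
        """Monte Carlo at a fixed height: SD of fused z <= SD of each source."""
        z0 = 120.0
        n = 1500
        n_u, n_e = optics.expected_counts(5500.0, z0)
        wx, wy = optics.uaf_widths(z0)
        w_e = optics.epi_width(z0)
        c_u = gaussian_psf_crlb(n_u, wx, wy, background=100.0, pixel=100.0)
        c_e = gaussian_psf_crlb(n_e, w_e, w_e, background=100.0, pixel=100.0)
        df = pd.DataFrame({
            "frame": np.arange(n), "x_uaf_nm": 5000.0, "y_uaf_nm": 5000.0,
            "wx_uaf_nm": wx + rng.normal(0, c_u["sigma_wx"], n),
            "wy_uaf_nm": wy + rng.normal(0, c_u["sigma_wy"], n),
            "n_uaf": n_u + rng.normal(0, c_u["sigma_n"], n),
            "n_uaf_sum": n_u, "bg_uaf": 100.0,
            "x_epi_nm": 5000.0, "y_epi_nm": 5000.0,
            "wx_epi_nm": w_e, "wy_epi_nm": w_e,
            "n_epi": n_e + rng.normal(0, c_e["sigma_n"], n),
            "n_epi_sum": n_e, "bg_epi": 100.0, "pair_distance_nm": 0.0})
        est = add_axial_estimates(df, bundle)
        fused = fuse_localizations(est, bundle.lut, bundle.saf_curve)
        sd_fused = np.nanstd(fused.z_nm)
        sd_saf = np.nanstd(fused.z_saf_nm)
        sd_ast = np.nanstd(fused.z_astig_nm)
        n_eff = np.isfinite(fused.z_nm).sum()
        band = 3 * sd_fused / np.sqrt(2 * n_eff)
        assert sd_fused <= sd_saf + band
        assert sd_fused <= sd_ast + band


class TestWeightCurves:
    def test_weights_normalized_and_monotone(self, optics):
        wc = weight_curves(optics)
        np.testing.assert_allclose(wc.weight_saf + wc.weight_astig, 1.0, atol=1e-12)
        np.testing.assert_allclose(wc.weight_x_uaf + wc.weight_x_epi, 1.0, atol=1e-12)
        # SAF weight decays with depth (strictly while the EPI view is live)
        assert np.all(np.diff(wc.weight_saf) <= 0)
        live = wc[wc.z_nm <= 400.0]
        assert np.all(np.diff(live.weight_saf) < 0)

    def test_daisy_crlb_below_sources_pointwise(self, optics):
        wc = weight_curves(optics)
        assert np.all(wc.sigma_z_daisy_nm
                      <= np.minimum(wc.sigma_z_saf_nm, wc.sigma_z_astig_nm) + 1e-9)

    def test_uaf_lateral_dominates_beyond_600(self, optics):
        wc = weight_curves(optics)
        deep = wc[wc.z_nm > 600.0]
        assert np.all(deep.weight_y_uaf > deep.weight_y_epi)
        assert np.all(deep.weight_x_uaf > deep.weight_x_epi)
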