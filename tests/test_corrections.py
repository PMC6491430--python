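"""Correction-stage oracles: tilt plane, axial/lateral drift, field affine."""

import numpy as np
import pandas as pd
import pytest

from daisysmlm import (BiasSpec, OpticalModel, generate_emitters,
                       simulate_localizations)
from daisysmlm import corrections as C
from daisysmlm.axial import add_axial_estimates
from daisysmlm.detect import quality_filter
from daisysmlm.geometry import AffineMap2D


def _estimated_table(optics, bundle, emitters, bias=None, n_frames=500, seed=0):
    df = simulate_localizations(emitters, optics, bias=bias, n_frames=n_frames,
                                seed=seed)
    return add_axial_estimates(quality_filter(df), bundle)


class TestTilt:
    def test_exact_plane_noiseless(self):
        rngx = np.random.default_rng(1)
        x = rngx.uniform(0, 30000, 500)
        y = rngx.uniform(0, 30000, 500)
        df = pd.DataFrame({"frame": 0, "x_uaf_nm": x, "y_uaf_nm": y,
                           "z_saf_nm": 0.0, "z_astig_nm": -0.002 * x})
        plane = C.estimate_tilt(df)
        assert plane.a == pytest.approx(0.002, abs=1e-9)
        assert plane.b == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_tenth_nm_per_um(self, rng):
        x = rng.uniform(0, 30000, 2000)
        y = rng.uniform(0, 30000, 2000)
        disc = 0.0015 * x - 0.0008 * y + rng.normal(0, 15, 2000)
        df = pd.DataFrame({"frame": 0, "x_uaf_nm": x, "y_uaf_nm": y,
                           "z_saf_nm": 100.0, "z_astig_nm": 100.0 - disc})
        plane = C.estimate_tilt(df)
        assert plane.a == pytest.approx(0.0015, abs=1e-4)
        assert plane.b == pytest.approx(-0.0008, abs=1e-4)

    def test_null_case_within_se(self, rng):
        x = rng.uniform(0, 30000, 1500)
        y = rng.uniform(0, 30000, 1500)
        df = pd.DataFrame({"frame": 0, "x_uaf_nm": x, "y_uaf_nm": y,
                           "z_saf_nm": 0.0,
                           "z_astig_nm": rng.normal(0, 20, 1500)})
        plane = C.estimate_tilt(df)
        assert abs(plane.a) < 3 * plane.se_a
        assert abs(plane.b) < 3 * plane.se_b

    def test_apply_zero_plane_is_identity(self):
        df = pd.DataFrame({"frame": [0], "x_uaf_nm": [1.0], "y_uaf_nm": [2.0],
                           "z_saf_nm": [0.0], "z_astig_nm": [5.0]})
        out = C.apply_tilt(df, C.TiltPlane(0.0, 0.0, 0.0))
        assert out.z_astig_nm.iloc[0] == 5.0

    def test_correction_closure(self, optics, bundle):
        """Re-estimating the tilt on corrected data gives ~zero slopes."""
        em = generate_emitters("coverslip_plane", 60, ((0, 30000), (0, 30000), (0, 0)),
                               seed=21)
        est = _estimated_table(optics, bundle, em,
                               bias=BiasSpec(tilt_plane=(0.002, -0.001)), seed=22)
        plane = C.estimate_tilt(est)
        corrected = C.apply_tilt(est, plane)
        plane2 = C.estimate_tilt(corrected)
        assert abs(plane2.a) < 1e-4 and abs(plane2.b) < 1e-4

    def test_insufficient_spread_raises(self):
        df = pd.DataFrame({"frame": 0, "x_uaf_nm": np.full(200, 100.0),
                           "y_uaf_nm": np.full(200, 100.0),
                           "z_saf_nm": np.zeros(200), "z_astig_nm": np.zeros(200)})
        with pytest.raises(ValueError, match="spread"):
            C.estimate_tilt(df)


class TestAxialDrift:
    def _scene(self):
        return generate_emitters("coverslip_plane", 30,
                                 ((0, 25000), (0, 25000), (0, 0)), seed=31)

    def test_null_drift_small_knots(self, optics, bundle):
        est = _estimated_table(optics, bundle, self._scene(), n_frames=2000, seed=32)
        trace = C.estimate_axial_drift(est)
        assert np.all(np.abs(trace.dz) < 3.0)

    def test_step_drift_exact_on_clean_z(self, optics, bundle):
        """A 45 nm (3 voxel) step between subsets is recovered exactly."""
        em = self._scene()
        df = simulate_localizations(em, optics, n_frames=2000, seed=33)
        est = add_axial_estimates(quality_filter(df), bundle)
        # noise-free references at a voxel center (a delta distribution has
        # no sub-voxel information off-center)
        est["z_saf_nm"] = 107.5
        est["z_astig_nm"] = np.where(est.frame < 1000, 107.5, 152.5)
        trace = C.estimate_axial_drift(est)
        assert trace.dz[0] == pytest.approx(0.0, abs=0.5)
        assert trace.dz[1] == pytest.approx(-45.0, abs=0.5)

    def test_smooth_drift_rms_below_6nm(self, optics, bundle):
        """Sinusoidal 100 nm drift: knots accurate to < 6 nm RMS."""
        drift = lambda f: 100.0 * np.sin(2 * np.pi * np.asarray(f) / 20000.0)
        est = _estimated_table(optics, bundle, self._scene(),
                               bias=BiasSpec(axial_drift=drift),
                               n_frames=5000, seed=34)
        plane = C.estimate_tilt(est)
        est = C.apply_tilt(est, plane)
        trace = C.estimate_axial_drift(est)
        err = (plane.c + trace.dz) - (-drift(trace.knot_times))
        assert np.sqrt(np.mean(err ** 2)) < 6.0

    def test_apply_constant_and_zero(self):
        df = pd.DataFrame({"frame": [0, 500], "z_astig_nm": [10.0, 20.0],
                           "z_saf_nm": [0.0, 0.0]})
        zero = C.DriftTrace(np.array([250.0]), dz=np.array([0.0]))
        assert C.apply_axial_drift(df, zero).z_astig_nm.tolist() == [10.0, 20.0]
        shift = C.DriftTrace(np.array([250.0]), dz=np.array([-70.0]))
        assert C.apply_axial_drift(df, shift).z_astig_nm.tolist() == [-60.0, -50.0]

    def test_sparse_subset_skipped_with_warning(self, optics, bundle):
        est = _estimated_table(optics, bundle, self._scene(), n_frames=1000, seed=35)
        sparse = est.iloc[:5].copy()
        sparse["frame"] = 1500  # a second subset with almost no localizations
        with pytest.warns(UserWarning, match="knot skipped"):
            trace = C.estimate_axial_drift(pd.concat([est, sparse],
                                                     ignore_index=True))
        assert len(trace.dz) == 1


class TestOrderIndependence:
    def test_tilt_then_drift_vs_drift_then_tilt(self, optics, bundle):
        """Additive z biases: the two correction orders agree to < 1 nm."""
        em = generate_emitters("coverslip_plane", 60, ((0, 25000), (0, 25000), (0, 0)),
                               seed=41)
        bias = BiasSpec(tilt_plane=(0.0005, 0.0),
                        axial_drift=lambda f: 10.0 * np.asarray(f) / 3000.0)
        est = _estimated_table(optics, bundle, em, bias=bias, n_frames=3000, seed=42)

        tilted = C.apply_tilt(est, C.estimate_tilt(est))
        a = C.apply_axial_drift(tilted, C.estimate_axial_drift(tilted))
        drifted = C.apply_axial_drift(est, C.estimate_axial_drift(est))
        b = C.apply_tilt(drifted, C.estimate_tilt(drifted))
        diff = (a.z_astig_nm - b.z_astig_nm).abs().mean()
        assert diff < 1.0


class TestLateralDrift:
    def _structured_table(self, rng, drift_per_frame=(0.0, 0.0), n_frames=3000):
        # a filament-like scene: emitters along two lines
        t = rng.uniform(0, 1, 4000)
        x0 = np.where(t < 0.5, 4000 + 8000 * t * 2, rng.uniform(2000, 10000, 4000))
        y0 = np.where(t < 0.5, 3000.0, 5000 + (x0 - 2000) * 0.3)
        frames = rng.integers(0, n_frames, 4000)
        x = x0 + drift_per_frame[0] * frames + rng.normal(0, 10, 4000)
        y = y0 + drift_per_frame[1] * frames + rng.normal(0, 10, 4000)
        return pd.DataFrame({"frame": frames, "x_uaf_nm": x, "y_uaf_nm": y})

    def test_null_drift(self, rng):
        trace = C.estimate_lateral_drift(self._structured_table(rng), window=1000)
        assert np.all(np.abs(trace.dx) < 10.0)
        assert np.all(np.abs(trace.dy) < 10.0)

    def test_linear_drift_recovery_within_5pct(self, rng):
        df = self._structured_table(rng, drift_per_frame=(0.05, -0.03), n_frames=4000)
        trace = C.estimate_lateral_drift(df, window=1000)
        slope = np.polyfit(trace.knot_times, -trace.dx, 1)[0]
        assert slope == pytest.approx(0.05, rel=0.08)

    def test_featureless_scene_raises(self, rng):
        df = pd.DataFrame({"frame": rng.integers(0, 2000, 300),
                           "x_uaf_nm": rng.uniform(0, 30000, 300),
                           "y_uaf_nm": rng.uniform(0, 30000, 300)})
        with pytest.raises(ValueError, match="fiducial"):
            C.estimate_lateral_drift(df, window=1000)


class TestFieldAffine:
    def _pairs(self, rng, amap, n=5000, jitter=20.0, extent=25000.0):
        xy = rng.uniform(0, extent, (n, 2))
        ux, uy = amap.apply(xy[:, 0], xy[:, 1])
        uaf = np.column_stack([ux, uy]) + rng.normal(0, jitter, (n, 2))
        epi = xy + rng.normal(0, jitter, (n, 2))
        return uaf, epi

    def test_identity_data(self, rng):
        uaf, epi = self._pairs(rng, AffineMap2D.identity(), jitter=0.0)
        est = C.estimate_field_affine(uaf, epi)
        assert est.anisotropy == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(est.linear, np.eye(2), atol=1e-9)

    def test_recovers_injected_magnification_difference(self, rng):
        """3.5% x/y magnification + 0.2 deg rotation recovered accurately."""
        amap = AffineMap2D.from_params(scale_x=1.035, rotation_deg=0.2,
                                       tx=200.0, ty=0.0)
        uaf, epi = self._pairs(rng, amap)
        est = C.estimate_field_affine(uaf, epi)
        assert 100 * est.anisotropy == pytest.approx(3.5, abs=0.1)
        assert est.rotation_deg == pytest.approx(-0.2, abs=0.02)

    def test_subsample_stability(self, rng):
        amap = AffineMap2D.from_params(scale_x=1.035, rotation_deg=0.2)
        uaf, epi = self._pairs(rng, amap)
        full = C.estimate_field_affine(uaf, epi)
        idx = rng.choice(len(uaf), len(uaf) // 2, replace=False)
        half = C.estimate_field_affine(uaf[idx], epi[idx])
        assert abs(full.anisotropy - half.anisotropy) < 5e-4

    def test_apply_and_inverse_roundtrip(self):
        amap = AffineMap2D.from_params(scale_x=1.035, rotation_deg=0.2, tx=200.0)
        corners = np.array([[0.0, 0.0], [25000.0, 0.0], [0.0, 25000.0],
                            [25000.0, 25000.0]])
        x, y = amap.apply(corners[:, 0], corners[:, 1])
        xb, yb = amap.inverse().apply(x, y)
        np.testing.assert_allclose(np.column_stack([xb, yb]), corners, atol=0.01)

    def test_systematic_residual_below_6nm_after_correction(self, rng):
        amap = AffineMap2D.from_params(scale_x=1.035, rotation_deg=0.2, tx=200.0)
        uaf, epi = self._pairs(rng, amap)
        est = C.estimate_field_affine(uaf, epi)
        cx, cy = est.apply(uaf[:, 0], uaf[:, 1])
        res = C.residual_deformation(np.column_stack([cx, cy]), epi)
        assert res["systematic_residual_nm"] < 6.0

    def test_collinear_raises(self, rng):
        x = rng.uniform(0, 10000, 600)
        pts = np.column_stack([x, 2 * x + 5])
        with pytest.raises(ValueError, match="collinear"):
            C.estimate_field_affine(pts, pts)


class TestChromaticInsensitivity:
    def test_70nm_chromatic_offset_removed(self, optics, bundle):
        """Two channels with 70 nm astigmatic focal offset end up < 5 nm apart."""
        from daisysmlm.fusion import fuse_localizations

        em = generate_emitters("random3d", 30, ((0, 25000), (0, 25000), (0, 250)),
                               seed=51)

        def run(bias, seed):
            est = _estimated_table(optics, bundle, em, bias=bias, n_frames=800,
                                   seed=seed)
            plane = C.estimate_tilt(est)
            est = C.apply_tilt(est, plane)
            est = C.apply_axial_drift(est, C.estimate_axial_drift(est))
            return fuse_localizations(est, bundle.lut, bundle.saf_curve)

        f1 = run(None, 52)
        f2 = run(BiasSpec(chromatic_offset={"ch0": 70.0}), 53)
        m1 = f1.groupby("id")["z_nm"].mean()
        m2 = f2.groupby("id")["z_nm"].mean()
        assert abs(float((m1 - m2).mean())) < 5.0
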