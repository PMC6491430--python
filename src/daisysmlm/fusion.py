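"""Cramer-Rao lower bounds and inverse-variance fusion of the redundant
position estimates.

The CRLBs are computed by numerical Fisher information of the exact imaging
model: a pixel-integrated elliptical Gaussian with ``N`` photons on a uniform
background ``b`` photons/pixel under Poisson noise, jointly estimating
(x0, y0, sx, sy, N, b). The fusion itself is the normal-distribution
combination law: each coordinate is the inverse-variance weighted mean of its
two sources, and the fused variance is the harmonic combination -- absent
sources carry infinite variance (zero weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .axial import SAF_WINDOW
from .calibrate import AstigLUT
from .simulate import OpticalModel, SAFCurve

__all__ = [
    "gaussian_psf_crlb", "crlb_lateral", "crlb_astig_z", "crlb_saf_z",
    "merge_scalar", "PrecisionModel", "fuse_localizations", "weight_curves",
]


# ---------------------------------------------------------- Fisher information

def _phi(t):
    return np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)


def gaussian_psf_crlb(n, wx, wy, background: float = 0.0, pixel: float = 100.0,
                      roi_half_px: int = 7, chunk: int = 2048) -> dict:
    """Per-record CRLBs of the pixel-integrated elliptical-Gaussian fit.

    Vectorized over records (arrays broadcast together). Returns a dict with
    ``sigma_x, sigma_y, sigma_wx, sigma_wy, sigma_n, var_n, cov_wxwy`` --
    square roots of the diagonal (and one off-diagonal) of the inverse Fisher
    matrix, evaluated with the emitter at a pixel center. The pixel grid is
    ``roi_half_px`` half-width (matching the fitter's ROI), enlarged when
    needed so at least +-3.5 widths are covered. The joint parameters are
    (x0, y0, sx, sy, N, b), matching the fitter; with ``background == 0``
    the offset is dropped (its information diverges).
    """
    n, wx, wy = np.broadcast_arrays(np.asarray(n, float), np.asarray(wx, float),
                                    np.asarray(wy, float))
    shape = n.shape
    n, wx, wy = n.ravel(), wx.ravel(), wy.ravel()
    out = {k: np.full(n.size, np.nan) for k in
           ("sigma_x", "sigma_y", "sigma_wx", "sigma_wy", "sigma_n", "cov_wxwy")}
    ok = np.isfinite(n) & np.isfinite(wx) & np.isfinite(wy) & (n > 0)
    idx_all = np.nonzero(ok)[0]
    # sort by ROI size so each chunk uses a tight pixel grid
    idx_all = idx_all[np.argsort(np.maximum(wx[idx_all], wy[idx_all]))]
    use_bg = background > 0
    npar = 6 if use_bg else 5

    for s in range(0, idx_all.size, chunk):
        idx = idx_all[s:s + chunk]
        wxc, wyc, nc = wx[idx, None], wy[idx, None], n[idx, None]
        k = max(roi_half_px,
                int(np.ceil(3.5 * max(wxc.max(), wyc.max()) / pixel)))
        centers = np.arange(-k, k + 1) * pixel  # emitter at a pixel center
        hi = (centers + pixel / 2)
        lo = (centers - pixel / 2)

        def edges(w):
            return lo / w, hi / w

        ax_lo, ax_hi = edges(wxc)
        ay_lo, ay_hi = edges(wyc)
        ex = 0.5 * (erf(ax_hi / np.sqrt(2)) - erf(ax_lo / np.sqrt(2)))
        ey = 0.5 * (erf(ay_hi / np.sqrt(2)) - erf(ay_lo / np.sqrt(2)))
        dex_dx = (_phi(ax_lo) - _phi(ax_hi)) / wxc
        dey_dy = (_phi(ay_lo) - _phi(ay_hi)) / wyc
        dex_dw = (ax_lo * _phi(ax_lo) - ax_hi * _phi(ax_hi)) / wxc
        dey_dw = (ay_lo * _phi(ay_lo) - ay_hi * _phi(ay_hi)) / wyc

        m, npx = idx.size, centers.size
        mu = nc[..., None] * ey[:, :, None] * ex[:, None, :] + background
        grads = np.empty((m, npar, npx, npx))
        grads[:, 0] = nc[..., None] * ey[:, :, None] * dex_dx[:, None, :]   # x0
        grads[:, 1] = nc[..., None] * dey_dy[:, :, None] * ex[:, None, :]   # y0
        grads[:, 2] = nc[..., None] * ey[:, :, None] * dex_dw[:, None, :]   # sx
        grads[:, 3] = nc[..., None] * dey_dw[:, :, None] * ex[:, None, :]   # sy
        grads[:, 4] = ey[:, :, None] * ex[:, None, :]                        # N
        if use_bg:
            grads[:, 5] = 1.0                                                # b

        g = grads.reshape(m, npar, -1)
        fisher = np.einsum("mpk,mqk->mpq", g / mu.reshape(m, 1, -1), g)
        try:
            cov = np.linalg.inv(fisher)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(fisher)
        diag = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
        out["sigma_x"][idx] = diag[:, 0]
        out["sigma_y"][idx] = diag[:, 1]
        out["sigma_wx"][idx] = diag[:, 2]
        out["sigma_wy"][idx] = diag[:, 3]
        out["sigma_n"][idx] = diag[:, 4]
        out["cov_wxwy"][idx] = cov[:, 2, 3]

    out = {k: v.reshape(shape) for k, v in out.items()}
    out["var_n"] = out["sigma_n"] ** 2
    return out


def crlb_lateral(n, width, background: float = 0.0, pixel: float = 100.0,
                 width_y=None):
    """Lateral CRLB (nm) along x for an (elliptical) Gaussian PSF.

    Reduces to ``width/sqrt(N)`` as background -> 0 and pixel -> 0.
    """
    wy = width if width_y is None else width_y
    return gaussian_psf_crlb(n, width, wy, background, pixel)["sigma_x"]


def crlb_astig_z(n_uaf, w_x, w_y, lut: AstigLUT, z,
                 background: float = 0.0, pixel: float = 100.0):
    """Astigmatic axial CRLB: width-fit bounds through the local LUT slope.

    Diverges (+inf) where the width-difference curve is flat.
    """
    c = gaussian_psf_crlb(n_uaf, w_x, w_y, background, pixel)
    var_dw = c["sigma_wx"] ** 2 + c["sigma_wy"] ** 2 - 2.0 * c["cov_wxwy"]
    slope = np.abs(lut.slope_at(z))
    with np.errstate(divide="ignore"):
        return np.where(slope > 0, np.sqrt(var_dw) / slope, np.inf)


def crlb_saf_z(n_uaf, n_epi, curve: SAFCurve, z, var_n_uaf=None, var_n_epi=None,
               background: float = 0.0, counting_area_px: int = 400):
    """SAF axial CRLB: the ratio variance over the squared local curve slope.

    Count variances default to Poisson plus the background variance of a
    summation count over ``counting_area_px`` pixels; pass explicit variances
    (e.g. from the Gaussian-fit Fisher information) to model a fitted count.
    """
    n_uaf = np.asarray(n_uaf, float)
    n_epi = np.asarray(n_epi, float)
    if var_n_uaf is None:
        var_n_uaf = n_uaf + 2.0 * counting_area_px * background
    if var_n_epi is None:
        var_n_epi = n_epi + 2.0 * counting_area_px * background
    var_rho = (np.asarray(var_n_epi, float) / n_uaf ** 2
               + n_epi ** 2 * np.asarray(var_n_uaf, float) / n_uaf ** 4)
    slope = np.abs(curve.slope(z))
    with np.errstate(divide="ignore"):
        return np.where(slope > 0, np.sqrt(var_rho) / slope, np.inf)


# ----------------------------------------------------------------------- merge

def merge_scalar(v1, sigma1, v2, sigma2):
    """Inverse-variance combination of two independent normal measurements.

    ``v = (v1/s1^2 + v2/s2^2) / (1/s1^2 + 1/s2^2)``,
    ``sigma = (1/s1^2 + 1/s2^2)^(-1/2)``. An absent estimate is represented
    by NaN value or non-finite sigma and carries zero weight; if both are
    absent the result is (NaN, inf).
    """
    v1, s1, v2, s2 = np.broadcast_arrays(*[np.asarray(a, float)
                                           for a in (v1, sigma1, v2, sigma2)])
    w1 = np.where(np.isfinite(v1) & np.isfinite(s1) & (s1 > 0), 1.0 / s1 ** 2, 0.0)
    w2 = np.where(np.isfinite(v2) & np.isfinite(s2) & (s2 > 0), 1.0 / s2 ** 2, 0.0)
    wsum = w1 + w2
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (np.where(w1 > 0, v1, 0.0) * w1 + np.where(w2 > 0, v2, 0.0) * w2) / wsum
        sigma = 1.0 / np.sqrt(wsum)
    v = np.where(wsum > 0, v, np.nan)
    sigma = np.where(wsum > 0, sigma, np.inf)
    if v.ndim == 0:
        return float(v), float(sigma)
    return v, sigma


# ------------------------------------------------------------- precision model

@dataclass
class PrecisionModel:
    """Model-based per-localization precisions for the fusion weights.

    Evaluates the Fisher-information CRLBs at each record's fitted photons and
    widths, and the SAF/astigmatic axial bounds at the record's current z
    estimates (one fixed-point re-evaluation happens inside
    ``fuse_localizations``).
    """

    pixel_size: float = 100.0
    background: float = 100.0

    def evaluate(self, df: pd.DataFrame, lut: AstigLUT, curve: SAFCurve,
                 z_eval=None) -> pd.DataFrame:
        out = self.evaluate_fisher(df)
        self.update_axial_sigmas(out, lut, curve, z_eval=z_eval)
        return out

    def evaluate_fisher(self, df: pd.DataFrame) -> pd.DataFrame:
        """Photon/width/position bounds (z-independent part), appended as columns."""
        out = df.copy()
        u = gaussian_psf_crlb(out["n_uaf"], out["wx_uaf_nm"], out["wy_uaf_nm"],
                              self.background, self.pixel_size)
        e = gaussian_psf_crlb(out["n_epi"], out["wx_epi_nm"], out["wy_epi_nm"],
                              self.background, self.pixel_size)
        out["sigma_x_uaf_nm"] = u["sigma_x"]
        out["sigma_y_uaf_nm"] = u["sigma_y"]
        out["sigma_x_epi_nm"] = e["sigma_x"]
        out["sigma_y_epi_nm"] = e["sigma_y"]
        out["_var_dw"] = u["sigma_wx"] ** 2 + u["sigma_wy"] ** 2 - 2.0 * u["cov_wxwy"]
        out["_var_n_uaf"] = u["var_n"]
        out["_var_n_epi"] = e["var_n"]
        return out

    def update_axial_sigmas(self, out: pd.DataFrame, lut: AstigLUT, curve: SAFCurve,
                            z_eval=None) -> None:
        """(Re-)evaluate the slope-dependent axial sigmas in place at z_eval."""
        if z_eval is None:
            z_eval = out["z_astig_nm"].where(out["z_astig_nm"].notna(),
                                             out.get("z_saf_nm"))
        z_eval = np.asarray(z_eval, float)
        z_ast = np.where(np.isfinite(z_eval), z_eval, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["sigma_z_astig_nm"] = (np.sqrt(out["_var_dw"])
                                       / np.abs(lut.slope_at(z_ast)))
        z_saf = np.asarray(out.get("z_saf_nm", np.nan), float)
        z_for_slope = np.where(np.isfinite(z_eval), z_eval, z_saf)
        out["sigma_z_saf_nm"] = crlb_saf_z(
            out["n_uaf"].to_numpy(float), out["n_epi"].to_numpy(float), curve,
            z_for_slope, var_n_uaf=out["_var_n_uaf"].to_numpy(),
            var_n_epi=out["_var_n_epi"].to_numpy())
        out.loc[~np.isfinite(z_saf), "sigma_z_saf_nm"] = np.nan


def fuse_localizations(df: pd.DataFrame, lut: AstigLUT, curve: SAFCurve,
                       pixel_size: float = 100.0, background: float = 100.0,
                       fixed_point: bool = True, use_saf: bool = True,
                       ) -> pd.DataFrame:
    """Merge the redundant coordinates into final fused positions.

    x: UAF vs EPI; y: UAF vs EPI; z: SAF vs astigmatic -- each by the
    inverse-variance combination law with model-based (CRLB) weights. With
    ``fixed_point`` the axial weights are re-evaluated once at the first-pass
    fused z. ``use_saf=False`` zeroes the SAF weight (astigmatism-only mode,
    for comparison studies).

    Adds x_nm, y_nm, z_nm, sigma_x_nm, sigma_y_nm, sigma_z_nm, the axial
    weight columns and provenance flags (epi_used, saf_used).
    """
    pm = PrecisionModel(pixel_size=pixel_size, background=background)
    out = pm.evaluate_fisher(df)
    pm.update_axial_sigmas(out, lut, curve)
    if not use_saf:
        out["sigma_z_saf_nm"] = np.nan

    if fixed_point:
        z, _ = merge_scalar(out["z_saf_nm"], out["sigma_z_saf_nm"],
                            out["z_astig_nm"], out["sigma_z_astig_nm"])
        pm.update_axial_sigmas(out, lut, curve, z_eval=z)
        if not use_saf:
            out["sigma_z_saf_nm"] = np.nan

    x, sx = merge_scalar(out["x_uaf_nm"], out["sigma_x_uaf_nm"],
                         out["x_epi_nm"], out["sigma_x_epi_nm"])
    y, sy = merge_scalar(out["y_uaf_nm"], out["sigma_y_uaf_nm"],
                         out["y_epi_nm"], out["sigma_y_epi_nm"])
    z, sz = merge_scalar(out["z_saf_nm"], out["sigma_z_saf_nm"],
                         out["z_astig_nm"], out["sigma_z_astig_nm"])
    out["x_nm"], out["sigma_x_nm"] = x, sx
    out["y_nm"], out["sigma_y_nm"] = y, sy
    out["z_nm"], out["sigma_z_nm"] = z, sz

    w_saf = np.where(np.isfinite(out["sigma_z_saf_nm"]) & np.isfinite(out["z_saf_nm"]),
                     1.0 / out["sigma_z_saf_nm"] ** 2, 0.0)
    w_ast = np.where(np.isfinite(out["sigma_z_astig_nm"]) & np.isfinite(out["z_astig_nm"]),
                     1.0 / out["sigma_z_astig_nm"] ** 2, 0.0)
    tot = np.where(w_saf + w_ast > 0, w_saf + w_ast, np.nan)
    out["weight_saf"] = w_saf / tot
    out["weight_astig"] = w_ast / tot
    out["epi_used"] = np.isfinite(out["x_epi_nm"])
    out["saf_used"] = w_saf > 0
    out = out.drop(columns=[c for c in out.columns if c.startswith("_")])
    return out[np.isfinite(out["z_nm"]) | np.isfinite(out["x_nm"])].reset_index(drop=True)


def weight_curves(optics: OpticalModel, photons_total: float = 5500.0,
                  background: float = 100.0, z_grid=None,
                  epi_width_cutoff: float = 180.0) -> pd.DataFrame:
    """Relative fusion weights and CRLBs versus depth for nominal conditions.

    For each z: expected photons and widths in both views, lateral CRLBs,
    SAF and astigmatic axial CRLBs, the fused (DAISY) bounds, and normalized
    inverse-variance weights (axial SAF/astig, lateral UAF/EPI per axis).
    Beyond ``epi_width_cutoff`` the EPI PSF is too defocused to survive the
    detection width filter, so the EPI-derived bounds (EPI lateral, SAF
    axial) are set to infinity there -- only the astigmatic view remains.
    """
    if z_grid is None:
        z_grid = np.arange(0.0, 901.0, 25.0)
    z = np.asarray(z_grid, float)
    n_uaf, n_epi = optics.expected_counts(photons_total, z)
    wx_u, wy_u = optics.uaf_widths(z)
    w_e = optics.epi_width(z)
    lut = AstigLUT.from_optics(optics)

    u = gaussian_psf_crlb(n_uaf, wx_u, wy_u, background, optics.pixel_size)
    e = gaussian_psf_crlb(n_epi, w_e, w_e, background, optics.pixel_size)
    var_dw = u["sigma_wx"] ** 2 + u["sigma_wy"] ** 2 - 2.0 * u["cov_wxwy"]
    with np.errstate(divide="ignore"):
        s_ast = np.sqrt(var_dw) / np.abs(lut.slope_at(z))
    s_saf = crlb_saf_z(n_uaf, n_epi, optics.saf_curve, z,
                       var_n_uaf=u["var_n"], var_n_epi=e["var_n"])
    undetectable = w_e > epi_width_cutoff
    for arr in (e["sigma_x"], e["sigma_y"], s_saf):
        arr[undetectable] = np.inf

    def norm_weights(s1, s2):
        w1, w2 = 1.0 / s1 ** 2, 1.0 / s2 ** 2
        return w1 / (w1 + w2), w2 / (w1 + w2)

    w_saf, w_ast = norm_weights(s_saf, s_ast)
    wux, wex = norm_weights(u["sigma_x"], e["sigma_x"])
    wuy, wey = norm_weights(u["sigma_y"], e["sigma_y"])
    return pd.DataFrame({
        "z_nm": z, "sigma_x_uaf_nm": u["sigma_x"], "sigma_y_uaf_nm": u["sigma_y"],
        "sigma_x_epi_nm": e["sigma_x"], "sigma_y_epi_nm": e["sigma_y"],
        "sigma_z_saf_nm": s_saf, "sigma_z_astig_nm": s_ast,
        "sigma_z_daisy_nm": 1.0 / np.sqrt(1.0 / s_saf ** 2 + 1.0 / s_ast ** 2),
        "sigma_x_daisy_nm": 1.0 / np.sqrt(1.0 / u["sigma_x"] ** 2 + 1.0 / e["sigma_x"] ** 2),
        "sigma_y_daisy_nm": 1.0 / np.sqrt(1.0 / u["sigma_y"] ** 2 + 1.0 / e["sigma_y"] ** 2),
        "weight_saf": w_saf, "weight_astig": w_ast,
        "weight_x_uaf": wux, "weight_x_epi": wex,
        "weight_y_uaf": wuy, "weight_y_epi": wey,
    })
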