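"""Axial position estimation: the two independent z readouts per molecule.

``z_from_saf`` inverts the SAF/UAF photon-ratio curve (absolute height above
the coverslip); ``z_from_astig`` inverts the astigmatic width-difference LUT
(height relative to the focal reference until corrected). Both return a
per-localization uncertainty obtained by propagating the count / width
variances through the local slope of the respective calibration curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import AstigLUT, CalibrationBundle
from .simulate import SAFCurve

__all__ = ["z_from_saf", "z_from_astig", "add_axial_estimates", "SAF_WINDOW"]

# height window in which the SAF readout is considered precise and reliable
SAF_WINDOW = (-50.0, 300.0)


def z_from_saf(n_epi, n_uaf, curve: SAFCurve, var_n_epi=None, var_n_uaf=None,
               background: float = 0.0, counting_area_px: int = 400):
    """Absolute height from the EPI/UAF photon ratio.

    rho_obs = n_epi/n_uaf - 1 is inverted through the curve; results are
    clipped to the curve's valid range (flagged), and non-positive ratios are
    flagged absent (NaN). The uncertainty propagates the variances of both
    counts through the local curve slope; unless explicit count variances are
    given, Poisson variance plus the background variance of a plain summation
    over ``counting_area_px`` pixels (2x background, the estimate being
    background-subtracted) is assumed.

    The logarithmic inversion is convex, so symmetric ratio noise biases the
    raw height upward by ~ sigma_z^2 / (2 * decay_depth) (delta method);
    this Jensen term is subtracted, which matters for the deeper part of the
    reliable window where the relative ratio noise grows.

    Returns (z_saf, sigma_z_saf, in_window, out_of_range).
    """
    n_epi = np.asarray(n_epi, dtype=float)
    n_uaf = np.asarray(n_uaf, dtype=float)
    if np.any(n_uaf[np.isfinite(n_uaf)] <= 0):
        raise ValueError("n_uaf must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_obs = n_epi / n_uaf - 1.0
    z_raw = curve.invert(rho_obs)

    if var_n_epi is None:
        var_n_epi = n_epi + 2.0 * counting_area_px * background
    if var_n_uaf is None:
        var_n_uaf = n_uaf + 2.0 * counting_area_px * background
    var_rho = (np.asarray(var_n_epi, float) / n_uaf ** 2
               + n_epi ** 2 * np.asarray(var_n_uaf, float) / n_uaf ** 4)
    lo, hi = curve.valid_range
    slope = np.abs(curve.slope(np.clip(np.where(np.isfinite(z_raw), z_raw, hi),
                                       lo, hi)))
    with np.errstate(divide="ignore"):
        sigma = np.sqrt(var_rho) / slope

    # apply the debias only where the delta method is trustworthy (small
    # relative ratio noise); a huge sigma would otherwise drag estimates that
    # are effectively out of range back into the reliable window
    jensen = np.where(sigma < curve.decay_depth,
                      sigma ** 2 / (2.0 * curve.decay_depth), 0.0)
    z = z_raw - jensen
    out = ~np.isfinite(z) | (z < lo) | (z > hi)
    z = np.clip(z, lo, hi)
    # a non-positive ratio means the molecule is above the sensitive range
    z = np.where(rho_obs > 0, z, np.nan)
    in_window = (np.isfinite(z) & (z >= SAF_WINDOW[0]) & (z <= SAF_WINDOW[1])
                 & (z_raw <= SAF_WINDOW[1] + curve.decay_depth / 2.0))
    return z, sigma, in_window, out


def z_from_astig(w_x, w_y, lut: AstigLUT, sigma_w_x=None, sigma_w_y=None,
                 tolerance: float = 5.0):
    """Focus-referenced height from the astigmatic width difference.

    The observed w_x - w_y is inverted through the monotone LUT (linear
    interpolation, exact for a piecewise-linear table; width differences
    outside the table range by more than ``tolerance`` nm give NaN). The
    uncertainty divides the width-difference noise by the local LUT slope.

    Returns (z_astig, sigma_z_astig).
    """
    w_x = np.asarray(w_x, dtype=float)
    w_y = np.asarray(w_y, dtype=float)
    z = lut.invert(w_x - w_y, tolerance=tolerance)
    if sigma_w_x is None:
        sigma = np.full_like(z, np.nan)
    else:
        var_dw = np.asarray(sigma_w_x, float) ** 2 + np.asarray(sigma_w_y, float) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = np.sqrt(var_dw) / np.abs(lut.slope_at(np.where(np.isfinite(z), z, 0.0)))
        sigma = np.where(np.isfinite(z), sigma, np.nan)
    return z, sigma


def add_axial_estimates(df: pd.DataFrame, bundle: CalibrationBundle,
                        background: float = 100.0, pixel_size: float = 100.0,
                        sigma_w_x=None, sigma_w_y=None,
                        var_n_epi=None, var_n_uaf=None) -> pd.DataFrame:
    """Append z_saf / z_astig columns (and sigmas) to a localization table.

    Photon counts in the table come from the Gaussian fit, so unless explicit
    variances are given the count noise is modelled as Poisson plus the
    matched-filter background term ``b * 4 pi wx wy / a^2`` (not the much
    larger variance of a plain summation count).
    """
    out = df.copy()
    a2 = pixel_size ** 2
    if var_n_uaf is None:
        var_n_uaf = (out["n_uaf"] + background * 4.0 * np.pi
                     * out["wx_uaf_nm"] * out["wy_uaf_nm"] / a2).to_numpy()
    if var_n_epi is None:
        var_n_epi = (out["n_epi"] + background * 4.0 * np.pi
                     * out["wx_epi_nm"] * out["wy_epi_nm"] / a2).to_numpy()
    z_s, s_s, win, oor = z_from_saf(out["n_epi"], out["n_uaf"], bundle.saf_curve,
                                    var_n_epi=var_n_epi, var_n_uaf=var_n_uaf,
                                    background=background)
    out["z_saf_nm"] = z_s
    out["sigma_z_saf_nm"] = np.where(np.isfinite(z_s), s_s, np.nan)
    out["saf_in_window"] = win
    out["saf_out_of_range"] = oor
    z_a, s_a = z_from_astig(out["wx_uaf_nm"], out["wy_uaf_nm"], bundle.lut,
                            sigma_w_x=sigma_w_x, sigma_w_y=sigma_w_y)
    out["z_astig_nm"] = z_a
    out["sigma_z_astig_nm"] = s_a
    return out
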