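"""SAF-referenced correction of the astigmatic detection biases.

The absolute axial reference carried by the SAF readout (height above the
coverslip, insensitive to focus position) is used to remove, from the
focus-referenced astigmatic positions: the sample tilt (a static plane), the
axial drift (a slow temporal trace estimated by cross-correlating the SAF and
astigmatic 3D histograms in frame subsets), and lateral drift (temporal
cross-correlation of 2D histograms). The lateral field deformation induced by
the cylindrical lens (anisotropic magnification) is estimated from matched
UAF/EPI localization pairs as an affine map.

All estimators are pure functions of localization tables; re-running an
estimator on corrected data returns a near-null estimate (closure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .axial import SAF_WINDOW
from .geometry import AffineMap2D

__all__ = [
    "TiltPlane", "DriftTrace", "estimate_tilt", "apply_tilt",
    "estimate_axial_drift", "apply_axial_drift", "estimate_lateral_drift",
    "apply_lateral_drift", "estimate_field_affine", "apply_field_affine",
    "residual_deformation",
]


# ------------------------------------------------------------------------ tilt

@dataclass
class TiltPlane:
    """Static plane z = a*x + b*y + c describing the sample tilt (nm per nm)."""

    a: float
    b: float
    c: float
    se_a: float = np.nan
    se_b: float = np.nan

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and np.isfinite(self.c)):
            raise ValueError("tilt coefficients must be finite")
        if abs(self.a) >= 0.01 or abs(self.b) >= 0.01:
            raise ValueError("implausible tilt (> 10 nm/um); check the inputs")

    def predict(self, x, y):
        return self.a * np.asarray(x, float) + self.b * np.asarray(y, float) + self.c


def _in_window(df: pd.DataFrame, drift_margin: float = 150.0) -> pd.Series:
    """Anchor subset for the SAF-referenced corrections.

    The reliable-SAF height window is selected through the astigmatic
    readout rather than z_saf itself: conditioning on the noisy z_saf would
    bias its conditional mean near the window edge (lucky fluctuations of
    deeper molecules leak in), corrupting the tilt fit and the correlation
    anchor. z_astig is 3-5x less noisy here and its noise is independent of
    the SAF noise, so selecting on it leaves the z_saf distribution of the
    kept molecules unbiased. The lower margin tolerates uncorrected drift /
    chromatic offsets of the (so far focus-referenced) astigmatic heights.
    """
    za = df["z_astig_nm"]
    return (za.notna() & df["z_saf_nm"].notna()
            & (za >= SAF_WINDOW[0] - drift_margin) & (za <= SAF_WINDOW[1]))


def estimate_tilt(df: pd.DataFrame, min_n: int = 100,
                  min_span_nm: float = 5000.0) -> TiltPlane:
    """Fit the tilt plane to the per-molecule z_saf - z_astig discrepancy.

    Restricted to molecules with a reliable SAF readout (z_saf within the
    coverslip window); robustified by one round of 3*MAD outlier rejection.
    """
    sub = df[_in_window(df)]
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} in-window localizations (need {min_n})")
    x = sub["x_uaf_nm"].to_numpy(float)
    y = sub["y_uaf_nm"].to_numpy(float)
    if np.ptp(x) < min_span_nm and np.ptp(y) < min_span_nm:
        raise ValueError("insufficient lateral spread to constrain a tilt plane")
    d = (sub["z_saf_nm"] - sub["z_astig_nm"]).to_numpy(float)

    def plane_fit(x, y, d):
        a_mat = np.column_stack([x, y, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(a_mat, d, rcond=None)
        return coef, a_mat

    coef, a_mat = plane_fit(x, y, d)
    resid = d - a_mat @ coef
    mad = np.median(np.abs(resid - np.median(resid)))
    keep = np.abs(resid - np.median(resid)) <= 3.0 * 1.4826 * max(mad, 1e-9)
    coef, a_mat = plane_fit(x[keep], y[keep], d[keep])
    resid = d[keep] - a_mat @ coef
    dof = max(keep.sum() - 3, 1)
    cov = (np.linalg.inv(a_mat.T @ a_mat) * (resid @ resid) / dof)
    return TiltPlane(float(coef[0]), float(coef[1]), float(coef[2]),
                     se_a=float(np.sqrt(cov[0, 0])), se_b=float(np.sqrt(cov[1, 1])))


def apply_tilt(df: pd.DataFrame, plane: TiltPlane) -> pd.DataFrame:
    """Correct z_astig by the fitted plane; the absolute z_saf is untouched."""
    out = df.copy()
    out["z_astig_nm"] = out["z_astig_nm"] + plane.predict(out["x_uaf_nm"],
                                                          out["y_uaf_nm"])
    return out


# ----------------------------------------------------------------------- drift

@dataclass
class DriftTrace:
    """Piecewise-linear drift correction: knots at subset midpoints, linear
    interpolation between them, constant extrapolation beyond."""

    knot_times: np.ndarray
    dz: np.ndarray | None = None
    dx: np.ndarray | None = None
    dy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float)
        if np.any(np.diff(self.knot_times) <= 0):
            raise ValueError("knot_times must be strictly increasing")
        for name in ("dz", "dx", "dy"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def _interp(self, frames, values):
        if values is None:
            return np.zeros(np.shape(frames))
        return np.interp(np.asarray(frames, float), self.knot_times, values)

    def dz_at(self, frames):
        return self._interp(frames, self.dz)

    def dx_at(self, frames):
        return self._interp(frames, self.dx)

    def dy_at(self, frames):
        return self._interp(frames, self.dy)

    def to_frame(self) -> pd.DataFrame:
        d = {"frame": self.knot_times}
        for name in ("dz", "dx", "dy"):
            v = getattr(self, name)
            if v is not None:
                d[name + "_nm"] = v
        return pd.DataFrame(d)


def _zshift_by_xcorr(hist_ref: np.ndarray, hist_mov: np.ndarray,
                     voxel_z: float, max_shift_vox: int) -> float:
    """Axial-only cross-correlation of two 3D histograms with sub-voxel
    (3-point parabolic) refinement. Returns the shift (nm) to ADD to the
    moving histogram's z so it best overlaps the reference."""
    nz = hist_ref.shape[2]
    shifts = np.arange(-max_shift_vox, max_shift_vox + 1)
    corr = np.empty(shifts.size)
    for k, s in enumerate(shifts):
        if s >= 0:
            a = hist_ref[:, :, s:]
            b = hist_mov[:, :, : nz - s]
        else:
            a = hist_ref[:, :, :s]
            b = hist_mov[:, :, -s:]
        corr[k] = float(np.sum(a * b))
    k = int(np.argmax(corr))
    refine = 0.0
    if 0 < k < corr.size - 1:
        c_m, c_0, c_p = corr[k - 1], corr[k], corr[k + 1]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            refine = 0.5 * (c_m - c_p) / denom
    return (shifts[k] + refine) * voxel_z


def estimate_axial_drift(df: pd.DataFrame, subset: int = 1000,
                         voxel: tuple[float, float, float] = (100.0, 100.0, 15.0),
                         min_occupancy: int = 200,
                         max_shift_nm: float = 300.0) -> DriftTrace:
    """Axial drift of the astigmatic detection, referenced to the SAF readout.

    The data is divided in ``subset``-frame subsets; for each, 3D histograms
    of the in-window localizations are built twice -- once with z = z_saf and
    once with z = z_astig -- and cross-correlated allowing only axial
    displacements. The per-subset corrections are pooled into a
    piecewise-linear trace with knots at subset midpoints. Subsets below
    ``min_occupancy`` in-window localizations are skipped with a warning.
    """
    sub = df[_in_window(df)]
    if sub.empty:
        raise ValueError("no in-window localizations for axial drift estimation")
    frames = df["frame"].to_numpy()
    n_sub = int(frames.max() // subset) + 1
    vx, vy, vz = voxel
    pad = max_shift_nm
    zlo, zhi = SAF_WINDOW[0] - pad, SAF_WINDOW[1] + pad
    xe = np.arange(sub["x_uaf_nm"].min() - vx, sub["x_uaf_nm"].max() + 2 * vx, vx)
    ye = np.arange(sub["y_uaf_nm"].min() - vy, sub["y_uaf_nm"].max() + 2 * vy, vy)
    ze = np.arange(zlo, zhi + vz, vz)
    max_shift_vox = int(np.ceil(max_shift_nm / vz))

    knots, dz = [], []
    for k in range(n_sub):
        s = sub[(sub["frame"] >= k * subset) & (sub["frame"] < (k + 1) * subset)]
        if len(s) < min_occupancy:
            warnings.warn(f"axial-drift subset {k}: only {len(s)} in-window "
                          "localizations; knot skipped")
            continue
        pts = s[["x_uaf_nm", "y_uaf_nm"]].to_numpy(float)
        z_saf = s["z_saf_nm"].to_numpy(float)
        z_ast = s["z_astig_nm"].to_numpy(float)
        h_saf, _ = np.histogramdd(np.column_stack([pts, z_saf]), bins=(xe, ye, ze))
        h_ast, _ = np.histogramdd(np.column_stack([pts, z_ast]), bins=(xe, ye, ze))
        coarse = _zshift_by_xcorr(h_saf, h_ast, vz, max_shift_vox)
        # sub-voxel refinement: re-histogram the astigmatic heights at
        # fractional shifts (exact, no interpolation aliasing) and place the
        # peak with a least-squares parabola over the whole scan window,
        # which averages out count-level jaggedness of the score curve
        deltas = coarse + np.linspace(-1.5 * vz, 1.5 * vz, 25)
        scores = np.empty(deltas.size)
        for i, d in enumerate(deltas):
            h_d, _ = np.histogramdd(np.column_stack([pts, z_ast + d]),
                                    bins=(xe, ye, ze))
            scores[i] = float(np.sum(h_saf * h_d))
        shift = float(deltas[np.argmax(scores)])
        coeff = np.polyfit(deltas - coarse, scores, 2)
        if coeff[0] < 0:
            vertex = coarse - coeff[1] / (2.0 * coeff[0])
            if deltas[0] <= vertex <= deltas[-1]:
                shift = float(vertex)
        knots.append(k * subset + subset / 2)
        dz.append(shift)
    if not knots:
        raise ValueError("every subset was below the occupancy threshold")
    trace = DriftTrace(np.asarray(knots), dz=np.asarray(dz))
    # the correlation sets the drift *shape* by aligning histogram peaks, but
    # the SAF height distribution is skewed, so its peak sits slightly below
    # its (unbiased) mean; re-anchor the constant level on the robust mean
    # residual so the corrected heights are mean-referenced to the coverslip
    resid = (sub["z_saf_nm"] - sub["z_astig_nm"]
             - trace.dz_at(sub["frame"])).to_numpy(float)
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    keep = np.abs(resid - med) <= 3.0 * 1.4826 * max(mad, 1e-9)
    trace.dz = trace.dz + float(np.mean(resid[keep]))
    return trace


def apply_axial_drift(df: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Correct z_astig by the drift trace; the absolute z_saf is untouched."""
    out = df.copy()
    out["z_astig_nm"] = out["z_astig_nm"] + trace.dz_at(out["frame"])
    return out


def estimate_lateral_drift(df: pd.DataFrame, window: int = 1000,
                           bin_nm: float = 50.0, coords=("x_uaf_nm", "y_uaf_nm"),
                           min_snr: float = 3.0) -> DriftTrace:
    """Lateral drift by temporal cross-correlation of 2D reconstruction
    histograms against the first window. Needs a structured scene (or bright
    fiducials); a featureless correlation (peak SNR below ``min_snr``) raises.
    """
    x = df[coords[0]].to_numpy(float)
    y = df[coords[1]].to_numpy(float)
    frames = df["frame"].to_numpy()
    xe = np.arange(np.nanmin(x) - bin_nm, np.nanmax(x) + 2 * bin_nm, bin_nm)
    ye = np.arange(np.nanmin(y) - bin_nm, np.nanmax(y) + 2 * bin_nm, bin_nm)
    n_win = int(frames.max() // window) + 1

    def hist(mask):
        h, _, _ = np.histogram2d(x[mask], y[mask], bins=(xe, ye))
        return h

    h0 = hist(frames < window)
    knots, dxs, dys = [], [], []
    for k in range(n_win):
        mask = (frames >= k * window) & (frames < (k + 1) * window)
        if mask.sum() < 10:
            continue
        hk = hist(mask)
        corr = signal.fftconvolve(h0, hk[::-1, ::-1], mode="full")
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        # featureless scenes give a correlation peak that is both weak in
        # absolute pair mass and indistinguishable from the random-overlap
        # background; either symptom aborts the estimate
        offpeak = corr.copy()
        r0, c0 = peak
        offpeak[max(r0 - 3, 0):r0 + 4, max(c0 - 3, 0):c0 + 4] = 0.0
        baseline = max(float(np.quantile(offpeak, 0.999)), 1e-12)
        weak_peak = corr[peak] < max(10.0, 0.01 * min(h0.sum(), hk.sum()))
        if weak_peak or corr[peak] / baseline < 1.0 + min_snr / 10.0:
            raise ValueError("featureless scene: lateral drift cross-correlation "
                             "peak too weak; consider adding fiducial markers")

        def refine(axis):
            i = peak[axis]
            sl = [peak[0], peak[1]]
            vals = []
            for d in (-1, 0, 1):
                sl[axis] = i + d
                if 0 <= sl[axis] < corr.shape[axis]:
                    vals.append(corr[tuple(sl)])
                else:
                    vals.append(corr[peak])
            c_m, c_0, c_p = vals
            denom = c_m - 2 * c_0 + c_p
            return 0.5 * (c_m - c_p) / denom if denom < 0 else 0.0

        # correction to ADD to window k so it aligns with window 0
        dxs.append(((peak[0] + refine(0)) - (h0.shape[0] - 1)) * bin_nm)
        dys.append(((peak[1] + refine(1)) - (h0.shape[1] - 1)) * bin_nm)
        knots.append(k * window + window / 2)
    return DriftTrace(np.asarray(knots, float), dx=np.asarray(dxs), dy=np.asarray(dys))


def apply_lateral_drift(df: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Shift all lateral coordinate columns by the drift trace."""
    out = df.copy()
    ddx = trace.dx_at(out["frame"])
    ddy = trace.dy_at(out["frame"])
    for c in ("x_uaf_nm", "x_epi_nm", "x_nm"):
        if c in out.columns:
            out[c] = out[c] + ddx
    for c in ("y_uaf_nm", "y_epi_nm", "y_nm"):
        if c in out.columns:
            out[c] = out[c] + ddy
    return out


# ---------------------------------------------------------- field deformation

def estimate_field_affine(uaf_xy: np.ndarray, epi_xy: np.ndarray,
                          min_n: int = 500) -> AffineMap2D:
    """Optimal affine map (UAF -> EPI frame) from matched localization pairs.

    Least squares on the matched pairs; the magnification anisotropy of the
    astigmatic view is then available from the singular values of the linear
    part, the rotation from its polar decomposition. Degenerate (collinear)
    geometry raises.
    """
    uaf = np.asarray(uaf_xy, float)
    epi = np.asarray(epi_xy, float)
    ok = np.all(np.isfinite(uaf), axis=1) & np.all(np.isfinite(epi), axis=1)
    uaf, epi = uaf[ok], epi[ok]
    if len(uaf) < min_n:
        raise ValueError(f"need at least {min_n} matched pairs, got {len(uaf)}")
    a_mat = np.column_stack([uaf, np.ones(len(uaf))])
    sv = np.linalg.svd(a_mat - a_mat.mean(0), compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise ValueError("degenerate (collinear) pair geometry")
    coef, *_ = np.linalg.lstsq(a_mat, epi, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    return AffineMap2D(linear, translation)


def apply_field_affine(df: pd.DataFrame, amap: AffineMap2D) -> pd.DataFrame:
    """Map the UAF lateral positions into the undistorted EPI frame."""
    out = df.copy()
    xn, yn = amap.apply(out["x_uaf_nm"].to_numpy(float),
                        out["y_uaf_nm"].to_numpy(float))
    out["x_uaf_nm"], out["y_uaf_nm"] = xn, yn
    if "x_epi_nm" in out.columns:
        out["pair_distance_nm"] = np.hypot(out["x_uaf_nm"] - out["x_epi_nm"],
                                           out["y_uaf_nm"] - out["y_epi_nm"])
    return out


def residual_deformation(uaf_xy: np.ndarray, epi_xy: np.ndarray,
                         n_bins: int = 5) -> dict:
    """Residual registration error between two matched point sets.

    Returns the raw mean pair distance (dominated by localization noise) and
    the systematic residual: the count-weighted mean magnitude of the per-cell
    mean displacement vector on an ``n_bins x n_bins`` grid -- the quantity
    that measures the remaining field deformation.
    """
    uaf = np.asarray(uaf_xy, float)
    epi = np.asarray(epi_xy, float)
    ok = np.all(np.isfinite(uaf), axis=1) & np.all(np.isfinite(epi), axis=1)
    uaf, epi = uaf[ok], epi[ok]
    dvec = epi - uaf
    raw = float(np.mean(np.hypot(dvec[:, 0], dvec[:, 1])))
    xe = np.linspace(uaf[:, 0].min(), uaf[:, 0].max() + 1e-9, n_bins + 1)
    ye = np.linspace(uaf[:, 1].min(), uaf[:, 1].max() + 1e-9, n_bins + 1)
    ix = np.clip(np.digitize(uaf[:, 0], xe) - 1, 0, n_bins - 1)
    iy = np.clip(np.digitize(uaf[:, 1], ye) - 1, 0, n_bins - 1)
    mags, weights = [], []
    for bx in range(n_bins):
        for by in range(n_bins):
            sel = (ix == bx) & (iy == by)
            if sel.sum() < 5:
                continue
            mean_vec = dvec[sel].mean(axis=0)
            mags.append(np.hypot(*mean_vec))
            weights.append(sel.sum())
    systematic = float(np.average(mags, weights=weights)) if mags else np.nan
    return {"mean_pair_distance_nm": raw, "systematic_residual_nm": systematic,
            "n_pairs": int(len(uaf))}
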