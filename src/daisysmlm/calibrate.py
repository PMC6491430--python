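"""Calibration of the axial detection: astigmatic width lookup table built on
fluorophore-decorated microspheres of known geometry, empirical refit of the
SAF ratio curve, and the serialized calibration bundle.

The width-vs-z lookup table (LUT) is built in the nominal acquisition
conditions on a sample whose geometry fixes each molecule's height: a sphere
of known radius touching the coverslip, so that the expected height at
lateral distance r from the contact point is ``z = R - sqrt(R^2 - r^2)``.
This avoids the focal-shift bias of objective-scanning bead calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.isotonic import IsotonicRegression

from .geometry import AffineMap2D
from .simulate import OpticalModel, SAFCurve

__all__ = [
    "sphere_expected_z", "fit_sphere_geometry", "build_lut", "fit_saf_curve",
    "AstigLUT", "CalibrationBundle",
]


# -------------------------------------------------------------- sphere geometry

def sphere_expected_z(x, y, center: tuple[float, float], radius: float):
    """Expected height on a lower spherical cap touching the coverslip.

    For a sphere of ``radius`` whose contact point projects to ``center``,
    a surface point at lateral distance r < radius from the center sits at
    ``z = radius - sqrt(radius**2 - r**2)``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    r = np.hypot(np.asarray(x, dtype=float) - center[0],
                 np.asarray(y, dtype=float) - center[1])
    if np.any(r >= radius):
        raise ValueError("lateral distance beyond the sphere radius (outside the cap)")
    return radius - np.sqrt(radius ** 2 - r ** 2)


def fit_sphere_geometry(x, y, z_cap: float = 1200.0) -> tuple[float, float, float]:
    """Estimate (center_x, center_y, radius) of a decorated sphere from the
    lateral footprint of its localizations.

    The detectable cap (heights up to ``z_cap``, the capture ceiling of the
    astigmatic detection) projects to a disc whose center is estimated by the
    centroid (unbiased by symmetry). For a uniformly decorated sphere the
    heights on the cap are uniformly distributed, giving the closed-form
    radial moment ``E[r^2] = R*z_cap - z_cap^2/3``; inverting it yields the
    sphere radius. Moments of the bulk are insensitive to localization-noise
    tails at the footprint edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 localizations to fit sphere geometry")
    cx, cy = float(np.mean(x)), float(np.mean(y))
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    radius = (float(np.mean(r2)) + z_cap ** 2 / 3.0) / z_cap
    return cx, cy, radius


# ------------------------------------------------------------------------- LUT

@dataclass
class AstigLUT:
    """Astigmatic width-difference lookup table on a fixed z grid.

    ``delta_w`` (= w_x - w_y) must be strictly monotone over the valid range
    so that the map is invertible; storage is on a regular grid with linear
    interpolation between knots.
    """

    z_grid: np.ndarray
    delta_w: np.ndarray
    w_x: np.ndarray | None = None
    w_y: np.ndarray | None = None
    valid_range: tuple[float, float] = (-100.0, 1200.0)
    channel_tag: str = "ch0"

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.delta_w = np.asarray(self.delta_w, dtype=float)
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        d = np.diff(self.delta_w)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("delta_w must be strictly monotone (calibration failed)")
        self._sign = 1.0 if d[0] > 0 else -1.0

    def delta_w_at(self, z):
        return np.interp(np.asarray(z, dtype=float), self.z_grid, self.delta_w)

    def slope_at(self, z):
        """Local d(delta_w)/dz of the piecewise-linear table."""
        z = np.asarray(z, dtype=float)
        slopes = np.diff(self.delta_w) / np.diff(self.z_grid)
        idx = np.clip(np.searchsorted(self.z_grid, z, side="right") - 1,
                      0, slopes.size - 1)
        return slopes[idx]

    def invert(self, delta_w_obs, tolerance: float = 0.0):
        """z at which the table equals the observed width difference.

        Values outside the table range by more than ``tolerance`` map to NaN;
        within tolerance they clip to the range edge.
        """
        d = self._sign * np.asarray(delta_w_obs, dtype=float)
        tab = self._sign * self.delta_w
        lo, hi = tab[0], tab[-1]
        z = np.interp(np.clip(d, lo, hi), tab, self.z_grid)
        out = (d < lo - tolerance) | (d > hi + tolerance)
        return np.where(out, np.nan, z)

    def to_dict(self) -> dict:
        return {"z_grid": self.z_grid.tolist(), "delta_w": self.delta_w.tolist(),
                "w_x": None if self.w_x is None else np.asarray(self.w_x).tolist(),
                "w_y": None if self.w_y is None else np.asarray(self.w_y).tolist(),
                "valid_range": list(self.valid_range), "channel_tag": self.channel_tag}

    @classmethod
    def from_dict(cls, d: dict) -> "AstigLUT":
        return cls(np.asarray(d["z_grid"]), np.asarray(d["delta_w"]),
                   None if d.get("w_x") is None else np.asarray(d["w_x"]),
                   None if d.get("w_y") is None else np.asarray(d["w_y"]),
                   tuple(d["valid_range"]), d.get("channel_tag", "ch0"))

    @classmethod
    def from_optics(cls, optics: OpticalModel, z_range: tuple[float, float] = (-100.0, 1200.0),
                    step: float = 10.0, channel_tag: str = "ch0") -> "AstigLUT":
        """Synthesize the LUT directly from the simulator's width law."""
        z = np.arange(z_range[0], z_range[1] + step / 2, step)
        wx, wy = optics.uaf_widths(z)
        return cls(z, wx - wy, wx, wy, z_range, channel_tag)


def build_lut(locs: pd.DataFrame, sphere_geometry: tuple[float, float, float] | None = None,
              z_bin: float = 25.0, min_count: int = 50, grid_step: float = 10.0,
              z_cap: float = 1200.0, channel_tag: str = "ch0") -> AstigLUT:
    """Build the width-difference LUT from localizations on a decorated sphere.

    ``locs`` needs columns x_uaf_nm, y_uaf_nm, wx_uaf_nm, wy_uaf_nm. The
    sphere center/radius are estimated from the lateral footprint unless given
    explicitly. Per ``z_bin`` the robust center (median) of w_x - w_y is taken
    against the geometric expected z; bins with fewer than ``min_count``
    localizations are dropped; monotonicity is enforced by isotonic regression
    before resampling onto the regular ``grid_step`` grid.
    """
    x = locs["x_uaf_nm"].to_numpy(dtype=float)
    y = locs["y_uaf_nm"].to_numpy(dtype=float)
    dw = (locs["wx_uaf_nm"] - locs["wy_uaf_nm"]).to_numpy(dtype=float)
    wx = locs["wx_uaf_nm"].to_numpy(dtype=float)
    wy = locs["wy_uaf_nm"].to_numpy(dtype=float)

    cx, cy, radius = (fit_sphere_geometry(x, y, z_cap=z_cap)
                      if sphere_geometry is None else sphere_geometry)
    r = np.hypot(x - cx, y - cy)
    ok = r < radius
    z_exp = np.full(x.shape, np.nan)
    z_exp[ok] = radius - np.sqrt(radius ** 2 - r[ok] ** 2)
    ok &= np.isfinite(dw)

    edges = np.arange(0.0, z_cap + z_bin, z_bin)
    idx = np.digitize(z_exp[ok], edges) - 1
    centers, mdw, mwx, mwy = [], [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.sum() < min_count:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        mdw.append(np.median(dw[ok][sel]))
        mwx.append(np.median(wx[ok][sel]))
        mwy.append(np.median(wy[ok][sel]))
    if len(centers) < 4:
        raise ValueError("too few populated z bins to build a LUT")
    centers = np.asarray(centers)
    mdw = np.asarray(mdw)

    increasing = mdw[-1] > mdw[0]
    iso = IsotonicRegression(increasing=increasing)
    smooth = iso.fit_transform(centers, mdw)
    # isotonic regression yields flats at ties; break them with a tiny slope so
    # the stored table stays strictly invertible
    eps = 1e-6 * (1 if increasing else -1)
    smooth = smooth + eps * np.arange(smooth.size)
    d = np.diff(smooth)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("LUT not monotone after smoothing (calibration failed)")

    grid = np.arange(centers[0], centers[-1] + grid_step / 2, grid_step)
    return AstigLUT(grid, np.interp(grid, centers, smooth),
                    np.interp(grid, centers, mwx), np.interp(grid, centers, mwy),
                    (float(centers[0]), float(centers[-1])), channel_tag)


def build_lut_by_scanning(z_nominal, w_x, w_y, unsafe: bool = False,
                          grid_step: float = 10.0, channel_tag: str = "ch0") -> AstigLUT:
    """LUT from an objective-scanning bead series (deliberately gated).

    Scanning the objective through a bead on the coverslip is biased by the
    focal shift and by aberration-induced PSF-shape changes, which is why the
    known-geometry sphere calibration is the primary path. This route exists
    only for comparison studies and must be enabled explicitly.
    """
    if not unsafe:
        raise ValueError("scanning calibration is biased by the focal shift; "
                         "pass unsafe=True only for comparison studies")
    z = np.asarray(z_nominal, dtype=float)
    order = np.argsort(z)
    z, wx, wy = z[order], np.asarray(w_x, float)[order], np.asarray(w_y, float)[order]
    grid = np.arange(z[0], z[-1] + grid_step / 2, grid_step)
    return AstigLUT(grid, np.interp(grid, z, wx - wy), np.interp(grid, z, wx),
                    np.interp(grid, z, wy), (float(z[0]), float(z[-1])), channel_tag)


# ------------------------------------------------------------------- SAF refit

def fit_saf_curve(z, n_epi, n_uaf, min_span: float = 300.0,
                  max_residual_frac: float = 0.2) -> SAFCurve:
    """Least-squares refit of (rho0, decay_depth) from known-height data.

    Fits ``rho(z) = rho0 * exp(-z/decay_depth)`` to the observed
    ``n_epi/n_uaf - 1``. Raises if the z span is below ``min_span``. If the
    residual SD exceeds ``max_residual_frac * rho0`` the curve is returned
    with ``valid_range`` unset (None markers) as a quality flag.
    """
    z = np.asarray(z, dtype=float)
    rho_obs = np.asarray(n_epi, dtype=float) / np.asarray(n_uaf, dtype=float) - 1.0
    ok = np.isfinite(z) & np.isfinite(rho_obs)
    z, rho_obs = z[ok], rho_obs[ok]
    if z.size < 10:
        raise ValueError("too few localizations to fit the SAF curve")
    if np.ptp(z) < min_span:
        raise ValueError(f"known-z span {np.ptp(z):.0f} nm < required {min_span:.0f} nm")
    popt, _ = curve_fit(lambda zz, r0, d: r0 * np.exp(-zz / d), z, rho_obs,
                        p0=(0.8, 150.0), bounds=([1e-3, 10.0], [10.0, 2000.0]))
    rho0, depth = map(float, popt)
    resid_sd = float(np.std(rho_obs - rho0 * np.exp(-z / depth)))
    curve = SAFCurve(rho0, depth)
    if resid_sd > max_residual_frac * rho0:
        curve.valid_range = (np.nan, np.nan)
    return curve


# ---------------------------------------------------------------------- bundle

@dataclass
class CalibrationBundle:
    """Everything the pipeline needs: LUT(s), SAF curve(s), intensity factors,
    and the EPI->UAF registration map. Serialized as a single JSON file."""

    lut: AstigLUT
    saf_curve: SAFCurve
    intensity_cal: dict = field(default_factory=lambda: {"uaf": 1.0, "epi": 1.0})
    registration: AffineMap2D = field(default_factory=AffineMap2D.identity)
    version: str = "1"

    @classmethod
    def from_optics(cls, optics: OpticalModel,
                    z_range: tuple[float, float] = (-100.0, 1200.0)) -> "CalibrationBundle":
        return cls(lut=AstigLUT.from_optics(optics, z_range=z_range),
                   saf_curve=optics.saf_curve,
                   intensity_cal={k: 1.0 / v for k, v in optics.intensity_cal.items()})

    def save(self, path) -> None:
        payload = {"version": self.version, "units": "nm",
                   "lut": self.lut.to_dict(), "saf_curve": self.saf_curve.to_dict(),
                   "intensity_cal": dict(self.intensity_cal),
                   "registration": self.registration.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "CalibrationBundle":
        d = json.loads(Path(path).read_text())
        return cls(lut=AstigLUT.from_dict(d["lut"]),
                   saf_curve=SAFCurve.from_dict(d["saf_curve"]),
                   intensity_cal=d["intensity_cal"],
                   registration=AffineMap2D.from_dict(d["registration"]),
                   version=d.get("version", "1"))
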