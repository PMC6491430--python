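"""Synthetic dual-view acquisition generator.

This module renders ground-truth emitter scenes through a simple optical model
of the dual-view instrument: an astigmatic UAF channel (cylindrical lens, SAF
photons blocked) and an unaberrated EPI channel carrying both the UAF and the
depth-decaying SAF photon yield. It provides the oracle for every downstream
stage: detection, width/photon fitting, calibration, bias correction, fusion
and stitching.

Conventions
-----------
* z = 0 at the coverslip, positive into the sample, all coordinates in nm.
* Pixel (0, 0) of a half-field has its center at (pixel/2, pixel/2) nm;
  indices are 0-based with half-open pixel intervals.
* The SAF/UAF photon ratio follows a parameterized mono-exponential
  ``rho(z) = rho0 * exp(-z / decay_depth)``; the defocus width law is
  hyperbolic (Gaussian-beam-like), ``w(z) = w0 * sqrt(1 + ((z - f)/d)^2)``.
* Acquisition biases (axial/lateral drift, sample tilt, chromatic focal
  offsets, anisotropic magnification of the UAF view) default to zero and act
  on the *apparent* defocus coordinate only -- the SAF yield always sees the
  true height above the coverslip, which is precisely the physical asymmetry
  the correction stage exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import AffineMap2D

__all__ = [
    "SAFCurve",
    "OpticalModel",
    "BiasSpec",
    "EmitterTruth",
    "DualViewFrameStack",
    "generate_emitters",
    "assign_blinking",
    "render_stack",
    "simulate_localizations",
]


# --------------------------------------------------------------------------- types

@dataclass
class SAFCurve:
    """Mono-exponential model of the SAF/UAF intensity ratio versus height.

    rho0 : ratio at the coverslip (dimensionless, > 0)
    decay_depth : 1/e depth of the near-field coupling, nm
    valid_range : z interval on which the inverse is considered reliable, nm
    """

    rho0: float = 0.85
    decay_depth: float = 130.0
    valid_range: tuple[float, float] = (-50.0, 500.0)

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValueError("rho0 must be > 0")
        if self.decay_depth <= 0:
            raise ValueError("decay_depth must be > 0")

    def rho(self, z):
        return self.rho0 * np.exp(-np.asarray(z, dtype=float) / self.decay_depth)

    def slope(self, z):
        """d rho / d z (always negative)."""
        return -self.rho(z) / self.decay_depth

    def invert(self, rho_obs):
        """Height for an observed ratio; NaN where the ratio is non-positive."""
        rho_obs = np.asarray(rho_obs, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = -self.decay_depth * np.log(rho_obs / self.rho0)
        return np.where(rho_obs > 0, z, np.nan)

    def to_dict(self) -> dict:
        return {"rho0": self.rho0, "decay_depth": self.decay_depth,
                "valid_range": list(self.valid_range)}

    @classmethod
    def from_dict(cls, d: dict) -> "SAFCurve":
        return cls(d["rho0"], d["decay_depth"], tuple(d["valid_range"]))


@dataclass
class OpticalModel:
    """Optics of the dual-view detection.

    The UAF path carries the cylindrical-lens astigmatism: two focal lines at
    ``uaf_focal_x`` and ``uaf_focal_y`` (defaults 800 and 0 nm). The EPI path
    is unaberrated, focused at ``epi_focus``, and collects the additional SAF
    photons. ``split_factor`` is the fraction of the (UAF-type) fluorescence
    sent to the UAF path by the beam splitter.
    """

    pixel_size: float = 100.0
    psf_width0: float = 110.0
    depth_of_field: float = 400.0
    uaf_focal_x: float = 800.0
    uaf_focal_y: float = 0.0
    epi_focus: float = 0.0
    saf_curve: SAFCurve = field(default_factory=SAFCurve)
    split_factor: float = 0.5
    intensity_cal: dict = field(default_factory=lambda: {"uaf": 1.0, "epi": 1.0})

    def __post_init__(self) -> None:
        if self.uaf_focal_x == self.uaf_focal_y:
            raise ValueError("astigmatism requires uaf_focal_x != uaf_focal_y")
        if not 0 < self.split_factor < 1:
            raise ValueError("split_factor must be in (0, 1)")

    def width(self, z, focal: float):
        z = np.asarray(z, dtype=float)
        return self.psf_width0 * np.sqrt(1.0 + ((z - focal) / self.depth_of_field) ** 2)

    def uaf_widths(self, z):
        return self.width(z, self.uaf_focal_x), self.width(z, self.uaf_focal_y)

    def epi_width(self, z):
        return self.width(z, self.epi_focus)

    def delta_w(self, z):
        wx, wy = self.uaf_widths(z)
        return wx - wy

    def expected_counts(self, photons_total, z_true):
        """Mean detected photons (n_uaf, n_epi) for a given fluorescence budget.

        ``photons_total`` is the expected UAF-type fluorescence per on-frame
        before the beam splitter; the EPI path additionally receives the SAF
        photons, ``rho(z)`` times the UAF-type yield.
        """
        photons_total = np.asarray(photons_total, dtype=float)
        n_uaf = self.split_factor * photons_total * self.intensity_cal["uaf"]
        n_epi = ((1.0 - self.split_factor) * photons_total
                 * (1.0 + self.saf_curve.rho(z_true)) * self.intensity_cal["epi"])
        return n_uaf, n_epi

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size, "psf_width0": self.psf_width0,
            "depth_of_field": self.depth_of_field,
            "uaf_focal_x": self.uaf_focal_x, "uaf_focal_y": self.uaf_focal_y,
            "epi_focus": self.epi_focus, "saf_curve": self.saf_curve.to_dict(),
            "split_factor": self.split_factor, "intensity_cal": dict(self.intensity_cal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalModel":
        d = dict(d)
        d["saf_curve"] = SAFCurve.from_dict(d["saf_curve"])
        return cls(**d)


@dataclass
class BiasSpec:
    """Injectable acquisition biases; everything defaults to the identity.

    axial_drift : frame -> nm added to the apparent defocus of all channels
    lateral_drift : frame -> (nm, nm) added to positions in both views
    tilt_plane : (a, b) nm-per-nm slopes; adds a*x + b*y to the apparent defocus
    chromatic_offset : channel_tag -> nm added to the astigmatic defocus
    affine_distortion : applied to the UAF-view lateral coordinates
    """

    axial_drift: Callable[[np.ndarray], np.ndarray] | None = None
    lateral_drift: Callable[[np.ndarray], tuple] | None = None
    tilt_plane: tuple[float, float] = (0.0, 0.0)
    chromatic_offset: dict = field(default_factory=dict)
    affine_distortion: AffineMap2D | None = None
    seed: int | None = None

    def drift_z(self, frames):
        if self.axial_drift is None:
            return np.zeros(np.shape(frames))
        return np.asarray(self.axial_drift(np.asarray(frames)), dtype=float)

    def drift_xy(self, frames):
        if self.lateral_drift is None:
            z = np.zeros(np.shape(frames))
            return z, z.copy()
        dx, dy = self.lateral_drift(np.asarray(frames))
        return np.asarray(dx, dtype=float), np.asarray(dy, dtype=float)

    def apparent_defocus(self, x, y, z, frames, channel_tag="ch0"):
        """Apparent height relative to the focal reference (drives PSF widths)."""
        a, b = self.tilt_plane
        return (np.asarray(z, dtype=float) + a * np.asarray(x) + b * np.asarray(y)
                + self.drift_z(frames) + self.chromatic_offset.get(channel_tag, 0.0))


@dataclass
class EmitterTruth:
    """Ground-truth emitter: absolute position, photon budget, blinking."""

    id: int
    x: float
    y: float
    z: float
    photons_total: float
    on_frames: np.ndarray | None = None  # None = always on; else bool mask per frame
    channel_tag: str = "ch0"

    def __post_init__(self) -> None:
        if self.photons_total <= 0:
            raise ValueError("photons_total must be > 0")
        if not -50.0 <= self.z <= 2500.0:
            raise ValueError(f"z={self.z} outside the simulator capture window [-50, 2500] nm")

    def is_on(self, frame: int) -> bool:
        return True if self.on_frames is None else bool(self.on_frames[frame])


@dataclass
class DualViewFrameStack:
    """A rendered multi-frame acquisition: two equal half-fields per frame.

    ``layout`` is 'horizontal' ([UAF | EPI], left/right) or 'vertical'
    ([UAF over EPI], top/bottom). Pixel values are photon counts.
    """

    frames: np.ndarray
    layout: str = "horizontal"
    frame_period: float = 0.05
    background_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.layout not in ("horizontal", "vertical"):
            raise ValueError("layout must be 'horizontal' or 'vertical'")
        if np.any(np.asarray(self.frames) < 0):
            raise ValueError("pixel values must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def half_shape(self) -> tuple[int, int]:
        n, h, w = self.frames.shape
        return (h, w // 2) if self.layout == "horizontal" else (h // 2, w)

    def uaf_view(self) -> np.ndarray:
        if self.layout == "horizontal":
            return self.frames[:, :, : self.frames.shape[2] // 2]
        return self.frames[:, : self.frames.shape[1] // 2, :]

    def epi_view(self) -> np.ndarray:
        if self.layout == "horizontal":
            return self.frames[:, :, self.frames.shape[2] // 2:]
        return self.frames[:, self.frames.shape[1] // 2:, :]

    def to_tiff(self, path) -> None:
        import tifffile

        data = np.clip(np.rint(self.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, data, photometric="minisblack",
                         metadata={"layout": self.layout,
                                   "frame_period": self.frame_period})


# --------------------------------------------------------------- scene generation

def generate_emitters(pattern: str, n: int, region: Sequence[Sequence[float]],
                      photon_spec: float = 5500.0, seed: int | None = None,
                      **kwargs) -> list[EmitterTruth]:
    """Generate a ground-truth emitter scene.

    Parameters
    ----------
    pattern : one of 'random3d', 'coverslip_plane', 'sphere_cap', 'grid'
    n : number of emitters
    region : ((x0, x1), (y0, y1), (z0, z1)) bounds in nm
    photon_spec : expected UAF-type fluorescence per on-frame before the beam
        splitter (5500 with a 50-50 splitter gives the reference 2750 expected
        UAF-path photons)
    kwargs : 'sphere_cap' takes ``radius`` (nm) and optional ``center``
        (lateral nm pair, default the region center); 'grid' takes optional
        ``z_values`` cycled over the grid points.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    (x0, x1), (y0, y1), (z0, z1) = [tuple(map(float, b)) for b in region]
    if x1 <= x0 or y1 <= y0:
        raise ValueError("region must be non-degenerate")
    rng = np.random.default_rng(seed)

    if pattern == "random3d":
        xs = rng.uniform(x0, x1, n)
        ys = rng.uniform(y0, y1, n)
        zs = rng.uniform(z0, z1, n)
    elif pattern == "coverslip_plane":
        xs = rng.uniform(x0, x1, n)
        ys = rng.uniform(y0, y1, n)
        zs = np.zeros(n)
    elif pattern == "sphere_cap":
        radius = float(kwargs.get("radius", 7500.0))
        if radius <= 0:
            raise ValueError("sphere radius must be > 0")
        cx, cy = kwargs.get("center", ((x0 + x1) / 2, (y0 + y1) / 2))
        z_cap = min(z1, radius)
        # uniform sampling on the spherical surface restricted to z <= z_cap:
        # surface area element is uniform in z for a sphere.
        zs = rng.uniform(max(z0, 0.0), z_cap, n)
        rs = np.sqrt(np.maximum(2.0 * radius * zs - zs ** 2, 0.0))
        phi = rng.uniform(0, 2 * np.pi, n)
        xs = cx + rs * np.cos(phi)
        ys = cy + rs * np.sin(phi)
    elif pattern == "grid":
        ncol = int(np.ceil(np.sqrt(n * (x1 - x0) / max(y1 - y0, 1e-9))))
        ncol = max(ncol, 1)
        nrow = int(np.ceil(n / ncol))
        gx = x0 + (x1 - x0) * (np.arange(ncol) + 0.5) / ncol
        gy = y0 + (y1 - y0) * (np.arange(nrow) + 0.5) / nrow
        xs, ys = [a.ravel()[:n] for a in np.meshgrid(gx, gy)]
        z_values = np.asarray(kwargs.get("z_values", [z0]), dtype=float)
        zs = np.resize(z_values, n)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    tag = kwargs.get("channel_tag", "ch0")
    return [EmitterTruth(i, float(xs[i]), float(ys[i]), float(zs[i]),
                         float(photon_spec), channel_tag=tag) for i in range(n)]


def assign_blinking(emitters: Iterable[EmitterTruth], n_frames: int,
                    duty_cycle: float, seed: int | None = None) -> list[EmitterTruth]:
    """Give each emitter an independent Bernoulli on/off schedule per frame."""
    rng = np.random.default_rng(seed)
    out = []
    for em in emitters:
        mask = rng.random(n_frames) < duty_cycle
        out.append(replace(em, on_frames=mask))
    return out


# ------------------------------------------------------------------- rendering

def _pixel_gauss_1d(centers: np.ndarray, mu: float, sigma: float, pixel: float) -> np.ndarray:
    """Fraction of a Gaussian integrated over each pixel along one axis."""
    lo = (centers - pixel / 2 - mu) / (np.sqrt(2.0) * sigma)
    hi = (centers + pixel / 2 - mu) / (np.sqrt(2.0) * sigma)
    return 0.5 * (erf(hi) - erf(lo))


def _add_psf(img: np.ndarray, x: float, y: float, wx: float, wy: float,
             n_mean: float, pixel: float) -> None:
    """Accumulate the expected pixel-integrated elliptical Gaussian into img."""
    ny, nx = img.shape
    kx = int(np.ceil(5 * wx / pixel)) + 1
    ky = int(np.ceil(5 * wy / pixel)) + 1
    jc = int(np.floor(x / pixel))
    ic = int(np.floor(y / pixel))
    j0, j1 = max(jc - kx, 0), min(jc + kx + 1, nx)
    i0, i1 = max(ic - ky, 0), min(ic + ky + 1, ny)
    if j0 >= j1 or i0 >= i1:
        return
    cx = (np.arange(j0, j1) + 0.5) * pixel
    cy = (np.arange(i0, i1) + 0.5) * pixel
    ex = _pixel_gauss_1d(cx, x, wx, pixel)
    ey = _pixel_gauss_1d(cy, y, wy, pixel)
    img[i0:i1, j0:j1] += n_mean * np.outer(ey, ex)


def render_stack(emitters: Sequence[EmitterTruth], optics: OpticalModel,
                 bias: BiasSpec | None = None, n_frames: int = 1,
                 seed: int | None = None, field_shape: tuple[int, int] = (256, 256),
                 layout: str = "horizontal", background_rate: float = 100.0,
                 frame_period: float = 0.05, poisson: bool = True,
                 emccd_gain: float | None = None,
                 ) -> tuple[DualViewFrameStack, pd.DataFrame]:
    """Render a noisy dual-view frame stack plus its per-frame ground truth.

    Each half-field is ``field_shape`` pixels. The expected image of a frame
    is the sum of the uniform background and the pixel-integrated Gaussian of
    every on-emitter (elliptical in the UAF view, circular in the EPI view);
    a single Poisson draw of that expected image then gives the shot noise
    (the sum of independent Poisson contributions is Poisson in the sum).
    With ``emccd_gain`` set, EMCCD excess noise is emulated by Gamma
    amplification of the photon counts (output divided back to photon units).
    ``poisson=False`` returns the noiseless expected images.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    bias = bias or BiasSpec()
    rng = np.random.default_rng(seed)
    ny, nx = field_shape
    pixel = optics.pixel_size
    fx, fy = nx * pixel, ny * pixel

    frames = np.empty((n_frames,) + ((ny, 2 * nx) if layout == "horizontal" else (2 * ny, nx)),
                      dtype=float)
    truth_rows = []
    clipped_warned = False
    fidx = np.arange(n_frames)
    ddx, ddy = bias.drift_xy(fidx)

    for f in range(n_frames):
        uaf = np.full((ny, nx), float(background_rate))
        epi = np.full((ny, nx), float(background_rate))
        for em in emitters:
            if not em.is_on(f):
                continue
            xb, yb = em.x + ddx[f], em.y + ddy[f]
            z_app = float(bias.apparent_defocus(em.x, em.y, em.z, f, em.channel_tag))
            n_uaf, n_epi = optics.expected_counts(em.photons_total, em.z)
            wx_u, wy_u = optics.uaf_widths(z_app)
            w_e = optics.epi_width(z_app)
            if bias.affine_distortion is not None:
                xu, yu = bias.affine_distortion.apply(xb, yb)
            else:
                xu, yu = xb, yb
            clipped = not (0 <= xb < fx and 0 <= yb < fy)
            if clipped and not clipped_warned:
                warnings.warn("emitter outside the rendered field; clipped")
                clipped_warned = True
            _add_psf(uaf, float(xu), float(yu), float(wx_u), float(wy_u), float(n_uaf), pixel)
            _add_psf(epi, xb, yb, float(w_e), float(w_e), float(n_epi), pixel)
            truth_rows.append((f, em.id, em.x, em.y, em.z, xb, yb, float(xu), float(yu),
                               z_app, float(n_uaf), float(n_epi), em.channel_tag, clipped))
        full = np.concatenate([uaf, epi], axis=1 if layout == "horizontal" else 0)
        if poisson:
            full = rng.poisson(full).astype(float)
            if emccd_gain is not None:
                amplified = np.zeros_like(full)
                pos = full > 0
                amplified[pos] = rng.gamma(shape=full[pos], scale=emccd_gain)
                full = amplified / emccd_gain
        frames[f] = full

    truth = pd.DataFrame(truth_rows, columns=[
        "frame", "id", "x_true_nm", "y_true_nm", "z_true_nm",
        "x_biased_nm", "y_biased_nm", "x_uaf_true_nm", "y_uaf_true_nm",
        "z_apparent_nm", "photons_uaf", "photons_epi", "channel", "clipped"])
    stack = DualViewFrameStack(frames, layout=layout, frame_period=frame_period,
                               background_rate=background_rate)
    return stack, truth


# ------------------------------------------------- table-level (fast) simulation

def _approx_psf_sigmas(n: np.ndarray, wx: np.ndarray, wy: np.ndarray,
                       background: float, pixel: float):
    """Analytic noise model for the single-PSF estimates used by the fast path.

    Position: Mortensen-style least-squares variance per axis with the
    pixelation term and the background cross-term. Widths: half the position
    information (the classic factor-2 between location and scale of a
    Gaussian), with the same background inflation. Photon count: Poisson plus
    the matched-filter background variance ``b * 4 pi sx sy / a^2``.
    Returns (sigma_x, sigma_y, sigma_wx, sigma_wy, sigma_n).
    """
    n = np.asarray(n, dtype=float)
    a2 = pixel ** 2
    sax2 = wx ** 2 + a2 / 12.0
    say2 = wy ** 2 + a2 / 12.0
    tau = 8.0 * np.pi * np.sqrt(sax2 * say2) * background / (n * a2)
    var_x = sax2 / n * (16.0 / 9.0 + tau)
    var_y = say2 / n * (16.0 / 9.0 + tau)
    var_wx = sax2 / (2.0 * n) * (1.0 + tau)
    var_wy = say2 / (2.0 * n) * (1.0 + tau)
    var_n = n + background * 4.0 * np.pi * wx * wy / a2
    return (np.sqrt(var_x), np.sqrt(var_y), np.sqrt(var_wx),
            np.sqrt(var_wy), np.sqrt(var_n))


def simulate_localizations(emitters: Sequence[EmitterTruth], optics: OpticalModel,
                           bias: BiasSpec | None = None, n_frames: int = 1,
                           seed: int | None = None, background_rate: float = 100.0,
                           ) -> pd.DataFrame:
    """Generate per-frame localization records directly, skipping pixel rendering.

    The output table has the same columns the pixel pipeline produces
    (positions, widths, fitted photon counts for both views) plus the
    ground-truth columns, with noise drawn at the analytic single-PSF
    estimation level (see ``_approx_psf_sigmas``). This is the fast path for
    correction-stage studies, where the estimators under test are pure
    functions of localization tables.
    """
    bias = bias or BiasSpec()
    rng = np.random.default_rng(seed)
    fidx = np.arange(n_frames)
    ddx, ddy = bias.drift_xy(fidx)
    pixel = optics.pixel_size

    recs = []
    for em in emitters:
        on = fidx if em.on_frames is None else fidx[np.asarray(em.on_frames, bool)]
        if on.size == 0:
            continue
        z_app = bias.apparent_defocus(em.x, em.y, em.z, on, em.channel_tag)
        n_uaf_m, n_epi_m = optics.expected_counts(em.photons_total, em.z)
        wx_u, wy_u = optics.uaf_widths(z_app)
        w_e = optics.epi_width(z_app)
        xb, yb = em.x + ddx[on], em.y + ddy[on]
        if bias.affine_distortion is not None:
            xu, yu = bias.affine_distortion.apply(xb, yb)
        else:
            xu, yu = xb.copy(), yb.copy()

        n_uaf_true = rng.poisson(n_uaf_m, on.size).astype(float)
        n_epi_true = rng.poisson(n_epi_m, on.size).astype(float)
        sx_u, sy_u, swx_u, swy_u, sn_u = _approx_psf_sigmas(
            np.maximum(n_uaf_m, 1.0), wx_u, wy_u, background_rate, pixel)
        sx_e, sy_e, swx_e, _, sn_e = _approx_psf_sigmas(
            np.maximum(n_epi_m, 1.0), w_e, w_e, background_rate, pixel)
        bg_n_u = np.sqrt(np.maximum(sn_u ** 2 - n_uaf_m, 0.0))
        bg_n_e = np.sqrt(np.maximum(sn_e ** 2 - n_epi_m, 0.0))

        df = pd.DataFrame({
            "frame": on,
            "x_uaf_nm": xu + rng.normal(0, sx_u),
            "y_uaf_nm": yu + rng.normal(0, sy_u),
            "wx_uaf_nm": wx_u + rng.normal(0, swx_u),
            "wy_uaf_nm": wy_u + rng.normal(0, swy_u),
            "n_uaf": n_uaf_true + rng.normal(0, bg_n_u),
            "x_epi_nm": xb + rng.normal(0, sx_e),
            "y_epi_nm": yb + rng.normal(0, sy_e),
            "wx_epi_nm": w_e + rng.normal(0, swx_e),
            "wy_epi_nm": w_e + rng.normal(0, swx_e),
            "n_epi": n_epi_true + rng.normal(0, bg_n_e),
            "bg_uaf": background_rate, "bg_epi": background_rate,
            "id": em.id, "channel": em.channel_tag,
            "x_true_nm": em.x, "y_true_nm": em.y, "z_true_nm": em.z,
            "z_apparent_nm": z_app,
        })
        recs.append(df)

    if not recs:
        return pd.DataFrame()
    out = pd.concat(recs, ignore_index=True)
    out["n_uaf_sum"] = out["n_uaf"]
    out["n_epi_sum"] = out["n_epi"]
    out["pair_distance_nm"] = np.hypot(out.x_uaf_nm - out.x_epi_nm,
                                       out.y_uaf_nm - out.y_epi_nm)
    return out.sort_values("frame", kind="stable").reset_index(drop=True)
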