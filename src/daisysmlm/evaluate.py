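"""Evaluation harness: per-bead precision reports, profile histograms and
simple reconstruction renderings.

The localization precision of the instrument is measured the way bead
characterizations are done: quasi-static emitters are imaged over a few
hundred frames, localizations are grouped per bead, and the per-bead standard
deviations of the measured positions give the precision. These can then be
compared against the model CRLB curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["per_bead_precision", "profile_histogram", "render_image"]


def per_bead_precision(locs: pd.DataFrame, clustering_radius: float = 150.0,
                       min_locs: int = 50,
                       coords=("x_nm", "y_nm", "z_nm")) -> pd.DataFrame:
    """Group localizations per bead and report per-bead precision.

    Clustering is lateral radius-linkage (connected components of the
    within-``clustering_radius`` graph). Beads with fewer than ``min_locs``
    localizations are dropped. Returns one row per bead: count, mean
    positions, per-axis SDs, the pooled lateral SD
    ``sqrt((var_x + var_y)/2)``, and a flag for beads whose neighbor distance
    suggests two merged beads (nearest cluster closer than 2x the radius).
    """
    xc, yc, zc = coords
    df = locs[np.isfinite(locs[xc]) & np.isfinite(locs[yc])]
    pts = df[[xc, yc]].to_numpy(float)
    if len(pts) == 0:
        return pd.DataFrame()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(clustering_radius, output_type="ndarray")
    n = len(pts)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)

    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        if sel.sum() < min_locs:
            continue
        sub = df[sel]
        var_x = float(np.var(sub[xc], ddof=1))
        var_y = float(np.var(sub[yc], ddof=1))
        has_z = zc in sub.columns and np.isfinite(sub[zc]).sum() >= min_locs
        rows.append({
            "bead": lab, "n": int(sel.sum()),
            "x_mean_nm": float(np.mean(sub[xc])), "y_mean_nm": float(np.mean(sub[yc])),
            "z_mean_nm": float(np.nanmean(sub[zc])) if has_z else np.nan,
            "sd_x_nm": np.sqrt(var_x), "sd_y_nm": np.sqrt(var_y),
            "sd_z_nm": float(np.nanstd(sub[zc], ddof=1)) if has_z else np.nan,
            "lateral_sd_nm": np.sqrt((var_x + var_y) / 2.0),
        })
    report = pd.DataFrame(rows).reset_index(drop=True)
    if len(report) > 1:
        centers = report[["x_mean_nm", "y_mean_nm"]].to_numpy()
        ctree = cKDTree(centers)
        d, _ = ctree.query(centers, k=2)
        report["merge_suspect"] = d[:, 1] < 2.0 * clustering_radius
    elif len(report) == 1:
        report["merge_suspect"] = False
    return report


def profile_histogram(locs: pd.DataFrame, center: tuple[float, float],
                      length: float, width: float, angle_deg: float = 0.0,
                      axis: str = "longitudinal", bin_nm: float = 10.0,
                      coords=("x_nm", "y_nm")) -> tuple[np.ndarray, np.ndarray, float]:
    """Project the localizations inside an oriented box onto one box axis.

    The box is centered at ``center`` with ``length`` along the direction
    ``angle_deg`` and ``width`` across it; ``axis`` selects the projection
    direction ('longitudinal' or 'transverse'). Returns (counts, bin_edges,
    fitted Gaussian SD); the SD is NaN when fewer than 30 points fall in the
    box or the fit fails.
    """
    x = locs[coords[0]].to_numpy(float) - center[0]
    y = locs[coords[1]].to_numpy(float) - center[1]
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)      # longitudinal
    v = -x * np.sin(th) + y * np.cos(th)     # transverse
    inside = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    proj = (u if axis == "longitudinal" else v)[inside]
    half = (length if axis == "longitudinal" else width) / 2
    edges = np.arange(-half, half + bin_nm, bin_nm)
    counts, edges = np.histogram(proj, bins=edges)
    sd = np.nan
    if inside.sum() >= 30:
        centers_ = 0.5 * (edges[:-1] + edges[1:])
        p0 = (counts.max(), float(np.mean(proj)), max(float(np.std(proj)), bin_nm))
        try:
            popt, _ = curve_fit(lambda t, a, mu, s: a * np.exp(-0.5 * ((t - mu) / s) ** 2),
                                centers_, counts, p0=p0, maxfev=2000)
            sd = float(abs(popt[2]))
        except RuntimeError:
            pass
    return counts, edges, sd


def render_image(locs: pd.DataFrame, pixel: float = 20.0, mode: str = "2d",
                 coords=("x_nm", "y_nm", "z_nm"), extent=None):
    """Deterministic 2D reconstruction of a localization table.

    mode '2d': counts per pixel (total counts preserved). mode 'z_colored':
    additionally the mean z per occupied pixel (NaN elsewhere); returns
    (counts, mean_z) in that case.
    """
    x = locs[coords[0]].to_numpy(float)
    y = locs[coords[1]].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if extent is None:
        if x.size == 0:
            empty = np.zeros((1, 1))
            return (empty, empty * np.nan) if mode == "z_colored" else empty
        extent = (x.min(), x.max() + 1e-9, y.min(), y.max() + 1e-9)
    xe = np.arange(extent[0], extent[1] + pixel, pixel)
    ye = np.arange(extent[2], extent[3] + pixel, pixel)
    counts, _, _ = np.histogram2d(y, x, bins=(ye, xe))
    if mode == "2d":
        return counts
    if mode != "z_colored":
        raise ValueError("mode must be '2d' or 'z_colored'")
    z = locs[coords[2]].to_numpy(float)[ok]
    zsum, _, _ = np.histogram2d(y, x, bins=(ye, xe), weights=np.nan_to_num(z))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_z = np.where(counts > 0, zsum / counts, np.nan)
    return counts, mean_z
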