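"""Extended-depth imaging: merging sequential acquisitions at stepped focus.

Only the first slice carries the absolute SAF reference (the near-field
signal dies out a few hundred nm above the coverslip). Each subsequent slice
is matched to the already-absolute one below it by cross-correlating the 3D
histograms of their overlap region along z, so the absolute reference is
propagated upward slice by slice. A local-density filter for false-positive
removal is included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .corrections import _zshift_by_xcorr

__all__ = ["stitch_slices", "density_filter"]


def stitch_slices(slices: list[pd.DataFrame], nominal_offsets=None,
                  voxel: tuple[float, float, float] = (100.0, 100.0, 15.0),
                  min_overlap_locs: int = 500, max_shift_nm: float = 300.0,
                  z_col: str = "z_nm") -> tuple[pd.DataFrame, np.ndarray]:
    """Merge focus-stepped acquisitions into one absolute localization set.

    Each slice's ``z_col`` is in its own focus-referenced frame; slice 1 is
    taken as absolute (SAF-anchored). ``nominal_offsets`` are the nominal
    focus positions (default 600 nm steps). For slice k >= 2 the overlap
    window -- the intersection of the two slices' occupied z ranges once the
    nominal offset is applied -- is histogrammed in 3D for both slices in
    absolute coordinates and cross-correlated along z; the refined argmax
    corrects slice k's offset, and offsets accumulate.

    Returns the merged table (slice_id column added, nothing deduplicated)
    and the per-slice absolute offsets actually applied.
    """
    if not slices:
        raise ValueError("no slices given")
    if nominal_offsets is None:
        nominal_offsets = 600.0 * np.arange(len(slices))
    nominal_offsets = np.asarray(nominal_offsets, float)
    if nominal_offsets.size != len(slices):
        raise ValueError("one nominal offset per slice required")

    vx, vy, vz = voxel
    offsets = np.zeros(len(slices))
    absolute: list[pd.DataFrame] = []
    first = slices[0].copy()
    first["slice_id"] = 0
    absolute.append(first)

    for k in range(1, len(slices)):
        prev = absolute[k - 1]
        cur = slices[k].copy()
        step = nominal_offsets[k] - nominal_offsets[k - 1]
        guess = offsets[k - 1] + step
        z_prev = prev[z_col].to_numpy(float)
        z_cur = cur[z_col].to_numpy(float) + guess
        # overlap window: intersection of the two slices' occupied z ranges
        # (robust 1%-99% quantiles handle sparse tails)
        lo = max(np.quantile(z_prev, 0.01), np.quantile(z_cur, 0.01))
        hi = min(np.quantile(z_prev, 0.99), np.quantile(z_cur, 0.99))
        if hi - lo < 2 * vz:
            raise ValueError(f"slices {k - 1}/{k}: no overlap between capture ranges")
        pad = max_shift_nm
        in_prev = (z_prev >= lo - pad) & (z_prev <= hi + pad)
        in_cur = (z_cur >= lo - pad) & (z_cur <= hi + pad)
        if in_prev.sum() < min_overlap_locs or in_cur.sum() < min_overlap_locs:
            raise ValueError(
                f"slices {k - 1}/{k}: overlap occupancy below threshold "
                f"({in_prev.sum()}/{in_cur.sum()} < {min_overlap_locs})")

        cols = ["x_nm", "y_nm"] if "x_nm" in cur.columns else ["x_uaf_nm", "y_uaf_nm"]
        xy_all = np.vstack([prev[cols].to_numpy(float)[in_prev],
                            cur[cols].to_numpy(float)[in_cur]])
        xe = np.arange(xy_all[:, 0].min() - vx, xy_all[:, 0].max() + 2 * vx, vx)
        ye = np.arange(xy_all[:, 1].min() - vy, xy_all[:, 1].max() + 2 * vy, vy)
        ze = np.arange(lo - pad, hi + pad + vz, vz)
        h_prev, _ = np.histogramdd(
            np.column_stack([prev[cols].to_numpy(float)[in_prev], z_prev[in_prev]]),
            bins=(xe, ye, ze))
        h_cur, _ = np.histogramdd(
            np.column_stack([cur[cols].to_numpy(float)[in_cur], z_cur[in_cur]]),
            bins=(xe, ye, ze))
        shift = _zshift_by_xcorr(h_prev, h_cur, vz, int(np.ceil(max_shift_nm / vz)))
        offsets[k] = guess + shift
        cur[z_col] = cur[z_col] + offsets[k]
        cur["slice_id"] = k
        absolute.append(cur)

    merged = pd.concat(absolute, ignore_index=True)
    return merged, offsets


def density_filter(locs: pd.DataFrame, radius: float, min_neighbors: int,
                   coords=("x_nm", "y_nm", "z_nm")) -> pd.DataFrame:
    """Remove localizations with fewer than ``min_neighbors`` other
    localizations within ``radius`` (3D). Deterministic."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if locs.empty:
        return locs.copy()
    pts = locs[list(coords)].to_numpy(float)
    ok = np.all(np.isfinite(pts), axis=1)
    counts = np.zeros(len(locs), dtype=int)
    if ok.sum():
        tree = cKDTree(pts[ok])
        # neighbor count excluding the point itself
        counts[ok] = np.asarray(tree.query_ball_point(pts[ok], radius,
                                                      return_length=True)) - 1
    return locs[ok & (counts >= min_neighbors)].reset_index(drop=True)
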