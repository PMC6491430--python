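"""File formats: multi-page TIFF stacks in, localization CSV tables in/out.

All public coordinates are nm; camera pixels exist only inside the detection
internals. CSV output uses fixed float formatting so that identical runs are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import DualViewFrameStack

__all__ = ["read_stack", "read_localizations", "write_localizations",
           "write_table", "load_config", "save_config"]

REQUIRED_COLUMNS = ("frame", "x_uaf_nm", "y_uaf_nm")

KNOWN_COLUMNS = {
    "frame", "x_uaf_nm", "y_uaf_nm", "x_epi_nm", "y_epi_nm",
    "wx_uaf_nm", "wy_uaf_nm", "wx_epi_nm", "wy_epi_nm",
    "n_uaf", "n_epi", "n_uaf_sum", "n_epi_sum", "n_uaf_raw", "n_epi_raw",
    "n_uaf_sum_raw", "n_epi_sum_raw", "bg_uaf", "bg_epi", "pair_distance_nm",
    "z_saf_nm", "sigma_z_saf_nm", "z_astig_nm", "sigma_z_astig_nm",
    "saf_in_window", "saf_out_of_range",
    "x_nm", "y_nm", "z_nm", "sigma_x_nm", "sigma_y_nm", "sigma_z_nm",
    "sigma_x_uaf_nm", "sigma_y_uaf_nm", "sigma_x_epi_nm", "sigma_y_epi_nm",
    "weight_saf", "weight_astig", "epi_used", "saf_used", "slice_id",
    "id", "channel", "x_true_nm", "y_true_nm", "z_true_nm", "z_apparent_nm",
    "t_s",
}


def read_stack(path, layout: str = "horizontal", gain: float = 1.0,
               offset: float = 0.0, frame_period: float = 0.05,
               background_rate: float = 100.0) -> DualViewFrameStack:
    """Read a multi-page TIFF acquisition into photon units.

    Camera counts are converted as ``(raw - offset) / gain``; negative
    results clip to zero (photon counts cannot be negative).
    """
    try:
        raw = tifffile.imread(path)
    except Exception as exc:  # corrupt / truncated file
        raise ValueError(f"could not read TIFF stack {path!r}: {exc}") from exc
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise ValueError(f"expected a (frames, y, x) stack, got shape {raw.shape}")
    photons = np.clip((raw - offset) / gain, 0, None)
    return DualViewFrameStack(photons, layout=layout, frame_period=frame_period,
                              background_rate=background_rate)


def write_localizations(df: pd.DataFrame, path) -> None:
    """Write a localization table as CSV (nm units, fixed float format)."""
    df.to_csv(path, index=False, float_format="%.4f", na_rep="NA")


write_table = write_localizations


def read_localizations(path, required=REQUIRED_COLUMNS) -> pd.DataFrame:
    """Read a localization CSV; enforce required columns, warn on unknown."""
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"localization table {path!r} lacks required columns {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns in {path!r}: {unknown}")
    if "frame" in df.columns:
        df["frame"] = df["frame"].astype(int)
    return df


def load_config(path) -> dict:
    return json.loads(Path(path).read_text())


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=1, sort_keys=True))
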