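"""End-to-end drivers binding the stages into reproducible runs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import corrections, detect
from .axial import add_axial_estimates
from .calibrate import CalibrationBundle
from .fusion import fuse_localizations
from .simulate import DualViewFrameStack

__all__ = ["localize_stack", "correct_table", "process_stack"]


def localize_stack(stack: DualViewFrameStack, pixel_size: float = 100.0,
                   median_window: int | None = 10,
                   threshold_mult: dict | None = None,
                   registration=None, pair_radius_nm: float = 500.0,
                   min_photons: float = 500.0,
                   intensity_cal: dict | None = None) -> pd.DataFrame:
    """Detect, fit, pair, filter and intensity-calibrate a dual-view stack.

    ``median_window=None`` skips the temporal-median prefilter (the right
    choice for always-on bead scenes, where the running median would contain
    the PSF itself); blinking acquisitions should keep the default 10 frames.
    """
    uaf = np.asarray(stack.uaf_view(), dtype=float)
    epi = np.asarray(stack.epi_view(), dtype=float)
    if median_window is not None:
        uaf, _ = detect.subtract_temporal_median(uaf, window=median_window)
        epi, _ = detect.subtract_temporal_median(epi, window=median_window)
    mult = dict(detect.THRESHOLD_MULT)
    if threshold_mult:
        mult.update(threshold_mult)

    uaf_dets, epi_dets = [], []
    for f in range(stack.n_frames):
        for ch, view, dets in (("UAF", uaf, uaf_dets), ("EPI", epi, epi_dets)):
            for cand in detect.detect_candidates(view[f], channel=ch,
                                                 threshold_mult=mult[ch]):
                d = detect.fit_psf(view[f], cand, frame=f, channel=ch,
                                   pixel_size=pixel_size)
                if d is not None:
                    dets.append(d)
    pairs = detect.pair_views(uaf_dets, epi_dets, registration=registration,
                              radius_nm=pair_radius_nm)
    pairs = detect.quality_filter(pairs, min_photons=min_photons)
    if intensity_cal is not None:
        pairs = detect.calibrate_intensity(pairs, intensity_cal)
    return pairs


def correct_table(df: pd.DataFrame, do_tilt: bool = True, do_axial_drift: bool = True,
                  do_lateral_drift: bool = False, field_affine=None,
                  drift_subset: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Apply the SAF-referenced corrections to a table with axial estimates.

    Order: field-deformation affine (lateral), tilt (static, estimated once
    per acquisition), then the temporal axial drift, then optional lateral
    drift. Returns the corrected table and a report dict with the estimated
    plane, drift knots and affine parameters.
    """
    report: dict = {}
    out = df
    if field_affine is not None:
        out = corrections.apply_field_affine(out, field_affine)
        report["field_affine"] = field_affine.to_dict()
    if do_tilt:
        plane = corrections.estimate_tilt(out)
        out = corrections.apply_tilt(out, plane)
        report["tilt"] = {"a": plane.a, "b": plane.b, "c": plane.c,
                          "se_a": plane.se_a, "se_b": plane.se_b}
    if do_axial_drift:
        trace = corrections.estimate_axial_drift(out, subset=drift_subset)
        out = corrections.apply_axial_drift(out, trace)
        report["axial_drift_knots"] = trace.to_frame().to_dict("list")
    if do_lateral_drift:
        ltrace = corrections.estimate_lateral_drift(out)
        out = corrections.apply_lateral_drift(out, ltrace)
        report["lateral_drift_knots"] = ltrace.to_frame().to_dict("list")
    return out, report


def process_stack(stack: DualViewFrameStack, bundle: CalibrationBundle,
                  pixel_size: float = 100.0, background: float = 100.0,
                  median_window: int | None = 10, do_tilt: bool = True,
                  do_axial_drift: bool = True, use_saf: bool = True,
                  drift_subset: int = 1000) -> tuple[pd.DataFrame, dict]:
    """Full chain: localize -> axial estimates -> corrections -> fusion."""
    pairs = localize_stack(stack, pixel_size=pixel_size,
                           median_window=median_window,
                           registration=bundle.registration,
                           intensity_cal=bundle.intensity_cal)
    est = add_axial_estimates(pairs, bundle, background=background)
    corrected, report = correct_table(est, do_tilt=do_tilt,
                                      do_axial_drift=do_axial_drift,
                                      drift_subset=drift_subset)
    fused = fuse_localizations(corrected, bundle.lut, bundle.saf_curve,
                               pixel_size=pixel_size, background=background,
                               use_saf=use_saf)
    return fused, report
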