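# daisysmlm

Dual-view 3D single-molecule localization microscopy (SMLM): supercritical-
angle fluorescence (SAF) absolute axial ranging fused with strong-astigmatism
PSF-shape ranging, plus a synthetic dual-view acquisition simulator so every
stage is verifiable against ground truth.

## The problem

Astigmatic 3D SMLM encodes depth in the PSF ellipticity `w_x - w_y`, but the
measurement is referenced to the focal plane: axial drift, sample tilt and
chromatic focal shifts all corrupt it, and its precision degrades quickly
away from focus. SAF ranging — comparing the photon count of a detection
path that collects the near-field supercritical emission (EPI) with one that
blocks it (UAF) — yields the *absolute* height above the coverslip through
the decaying ratio `rho(z) = N_EPI/N_UAF - 1`, but only in the first few
hundred nm. This package implements the combined scheme: one camera images
both views; per molecule, two axial estimates

* `z_astig` from `w_x^UAF - w_y^UAF` via a calibrated lookup table,
* `z_saf` from the photon ratio via the SAF curve,

are produced, the SAF reference is used to remove tilt / axial drift /
chromatic offsets from the astigmatic heights, and the final coordinates are
the inverse-variance (CRLB-weighted) combinations

    z = (z_saf/s_saf^2 + z_astig/s_astig^2) / (1/s_saf^2 + 1/s_astig^2)

(and likewise x, y from the UAF and EPI lateral positions). The result is
drift-free, tilt-insensitive, achromatic 3D localization with a slowly
varying precision over a ~1 um capture range — extendable by stitching
focus-stepped acquisitions. See `docs/methods.md` for the full model.

Intended users: SMLM method developers and microscopists with dual-view
(SAF + PSF-shaping) setups, and anyone needing a fully simulated 3D SMLM
pipeline with ground truth.

## Worked example

```python
import numpy as np
import daisysmlm as d

optics = d.OpticalModel()                       # 100 nm pixels, focal lines 0/800 nm
bundle = d.CalibrationBundle.from_optics(optics)

# two beads, one at the coverslip and one 300 nm up, 2750 expected UAF
# photons per frame, 100 background photons/pixel
emitters = [d.EmitterTruth(0, 3000.0, 3250.0, 0.0, 5500.0),
            d.EmitterTruth(1, 9500.0, 3250.0, 300.0, 5500.0)]
stack, truth = d.render_stack(emitters, optics, n_frames=200, seed=5,
                              field_shape=(64, 128))

pairs = d.localize_stack(stack, median_window=None)       # beads: no median filter
est   = d.add_axial_estimates(pairs, bundle, background=100.0)
fused = d.fuse_localizations(est, bundle.lut, bundle.saf_curve)
print(d.per_bead_precision(fused, min_locs=30)[
    ["n", "z_mean_nm", "lateral_sd_nm", "sd_z_nm"]].round(2))
```

Output from this exact script:

```
     n  z_mean_nm  lateral_sd_nm  sd_z_nm
0  200     301.47           3.49    18.63
1  200      -0.74           2.31    11.51
```

Read: both beads are localized in every frame; the recovered mean heights
(-0.7 and 301.5 nm) match the true 0 and 300 nm; the per-frame scatter —
the localization precision — is ~2–3.5 nm laterally and 11.5 nm axially at
the coverslip (SAF-dominated) vs 18.6 nm at 300 nm depth (astigmatism-
dominated), reproducing the characteristic slow precision falloff.

## Command line

Every stage is also a subcommand of the `daisysmlm` CLI —
`simulate`, `calibrate`, `localize`, `correct`, `fuse`, `stitch`,
`evaluate`, `render` — each writing its outputs plus a JSON log of the
effective parameters and seeds:

```bash
daisysmlm simulate --preset coverslip-beads --seed 7 --out run/
daisysmlm localize run/stack.tif --no-median --calibration run/calibration.json \
          --out run/locs.csv
```

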