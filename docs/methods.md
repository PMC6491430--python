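# Methods

## The measurement model

`daisysmlm` implements dual-view 3D single-molecule localization: each
molecule is imaged simultaneously on two half-fields of one camera.

* **UAF path** — carries only the undercritical-angle fluorescence (the
  supercritical light is masked in a pupil relay) and a strong cylindrical-
  lens astigmatism with focal lines at `z = 0` (y axis) and `z = 800 nm`
  (x axis). The PSF width difference `w_x - w_y` encodes the axial position
  relative to the focus over ~1 um.
* **EPI path** — unaberrated, focused at the coverslip, and collects both
  the undercritical and the supercritical (SAF) emission. Because the SAF
  near-field coupling decays with the fluorophore's height above the glass,
  the photon-count ratio `N_EPI / N_UAF - 1` measures the *absolute* height.

The two axial readouts are complementary: the SAF height is absolute
(focus-, drift-, tilt- and chromatically-insensitive) but only precise in
the first ~300 nm; the astigmatic height covers ~1 um but is referenced to
the (moving) focal plane. The pipeline uses the SAF readout to make the
astigmatic one absolute, then fuses them — and the two lateral readouts —
by the normal-distribution combination law

    v = (v1/s1^2 + v2/s2^2) / (1/s1^2 + 1/s2^2),   s = (1/s1^2 + 1/s2^2)^(-1/2)

with model-based (Cramer-Rao) per-localization variances as weights. An
absent source carries infinite variance.

## Simulator (`simulate`)

The simulator is the oracle for every stage. Its model:

* Pixel-integrated Gaussian PSFs; elliptical on the UAF view with widths
  `w_i(z) = w0 * sqrt(1 + ((z - f_i)/d)^2)` (`w0 = 110 nm`,
  depth-of-field `d = 400 nm`, focal lines `f_x = 800`, `f_y = 0 nm`),
  circular on the EPI view focused at 0. The same law synthesizes LUTs, so
  calibration tests are self-consistent. The hyperbolic law is a stand-in:
  real calibrations are empirical, which is why the package calibrates on
  known-geometry samples rather than hard-coding the law.
* SAF ratio `rho(z) = rho0 * exp(-z / decay_depth)` with `rho0 = 0.85`,
  `decay_depth = 130 nm` — a parameterized monotone stand-in for the
  vectorial theory curve, chosen to reproduce the reference photon budgets
  (2750 expected UAF-path photons and 2750–5100 EPI-path photons per frame,
  depending on depth) and a reliable inversion window of roughly
  -50–300 nm. Any other curve object with `rho/slope/invert` plugs in.
* Photon budgets: `photons_total` (default 5500 per on-frame) is the
  UAF-type fluorescence before the 50–50 splitter; the UAF path receives
  `split * photons_total`, the EPI path
  `(1-split) * photons_total * (1 + rho(z))`. Poisson shot noise is drawn
  once per frame on the summed expectation image plus a uniform background
  (default 100 photons/pixel/frame); optional EMCCD excess noise by Gamma
  amplification. Blinking is i.i.d. Bernoulli per frame (beads: always on).
* Injectable biases act on the *apparent defocus* only (sample tilt plane,
  axial focus drift, per-channel chromatic focal offset), on lateral
  positions (drift), or on the UAF view (affine magnification distortion).
  The SAF ratio always sees the true height — exactly the physical
  asymmetry the corrections exploit.

A table-level fast path (`simulate_localizations`) samples localization
records directly at the analytic single-PSF noise level (Mortensen-style
position variance, width variance at half the position information, photon
count variance of a matched estimator). It exists because the correction
estimators are pure functions of localization tables; pixel rendering is
reserved for detection/fitting studies. What the table path does *not*
emulate: detection failures, PSF overlap, fit non-convergence, pixelation
artifacts — conclusions about those must come from the pixel path.

## Localization engine (`detect`)

1. Running temporal-median background subtraction (median of the previous
   10 frames per pixel; the first 3 frames use the head median and are
   flagged). Bead-mode pipelines skip it — always-on emitters would be
   subtracted into their own median.
2. Spot detection on the 2nd a-trous B3-spline wavelet plane; threshold =
   channel multiplier (EPI 1.0, UAF 0.8) x a robust baseline of 6 x
   1.4826*MAD of the plane. The baseline is set so that a pure-background
   frame yields < 0.1 false candidates; the channel multipliers keep the
   published EPI/UAF ratio. Local maxima closer than one PSF radius merge.
3. Per-candidate characterization on a 15x15-pixel ROI: background-
   subtracted center of mass (fit seed), then a chi-square-weighted
   least-squares fit of the pixel-integrated elliptical Gaussian with six
   free parameters (x, y, sx, sy, N, offset). Per-pixel weights are
   shot-noise + the local noise floor measured on the background ring,
   which keeps the fit near the Cramer-Rao bound at these photon levels
   (the weighting carries a ~1% multiplicative amplitude bias that cancels
   in the EPI/UAF ratio). The background reference ring is the border of
   the 2x2 um counting square (~1 um from the center) — far enough that
   defocused PSF tails do not contaminate it. A plain summation photon
   count over the counting square is also reported (`n_*_sum`) and is what
   the photon-minimum filter uses; the fitted N feeds the SAF ratio because
   the summation count's background variance (~400 pixels x 100
   photons/pixel) would multiply the SAF axial noise several-fold.
   A 5-parameter fit with the offset *fixed* to the ring estimate was
   evaluated and rejected: its nominal CRLB is lower, but propagating the
   ring-estimate noise made the realized axial precision worse.
4. Mutual-nearest-neighbor pairing of UAF and EPI detections within 500 nm
   (after applying the EPI->UAF registration); ties with a second candidate
   within 1.2x the best distance drop the match (safety over yield).
   Unmatched UAF detections survive as UAF-only records; unmatched EPI
   detections are discarded.
5. Quality filters: >= 500 UAF photons (records below are dropped); EPI
   width bounds `80 < sqrt(wx*wy) < 180 nm` and anisotropy
   `0.67 < wx/wy < 1.5` — failing these *demotes* the record to UAF-only
   rather than deleting it, because beyond ~520 nm every genuine EPI PSF
   exceeds the width bound by the shared width law while the astigmatic
   measurement is still perfectly usable; same-frame pairs closer than
   2 um are both discarded (mutual contamination). Intensity calibration
   multiplies the counts by per-channel factors (raw values kept).

## Calibration (`calibrate`)

The width-difference lookup table (LUT) is built in nominal acquisition
conditions on fluorophore-decorated microspheres of known radius touching
the coverslip, avoiding the focal-shift bias of objective scanning (that
route exists only behind an `unsafe=True` flag). Geometry: the cap
footprint center is the centroid; the radius comes from the closed-form
radial moment `E[r^2] = R*z_cap - z_cap^2/3` of a uniformly decorated cap
(assumption: uniform surface decoration; moments are insensitive to
localization-noise tails, unlike the footprint edge). Each expected-height
bin (default 25 nm, >= 50 localizations) contributes the median
`w_x - w_y`; isotonic regression enforces monotonicity; the table is stored
on a 10 nm grid with linear interpolation. `fit_saf_curve` refits
`(rho0, decay_depth)` from known-height data (>= 300 nm span required; a
residual SD above 20% of rho0 voids the valid range). Everything serializes
to one JSON bundle (LUT, SAF curve, intensity factors, registration).

## Axial estimation (`axial`)

* `z_astig`: invert `w_x - w_y` through the monotone LUT (linear
  interpolation — exact for a piecewise-linear table; out-of-range by more
  than 5 nm -> absent). Uncertainty: width-fit noise over the local LUT
  slope.
* `z_saf`: invert the ratio through the exponential curve,
  `z = -d * ln(rho_obs / rho0)`. Uncertainty: independent count variances
  propagated through the local slope. Because the log inversion is convex,
  symmetric ratio noise biases the raw height up by `~ sigma_z^2 / (2d)`
  (delta method); this Jensen term is subtracted wherever
  `sigma_z < decay_depth` (beyond that the estimate is flagged anyway).
  Without the debias, heights near the top of the reliable window are
  ~10 nm high on average, which would leak into every SAF-referenced
  correction.

## Bias corrections (`corrections`)

All estimators operate on localization tables and are closed (re-running on
corrected data yields near-null estimates). The anchor subset for the
SAF-referenced corrections is the reliable-SAF window (nominally z in
[-50, 300] nm) selected **through the astigmatic readout** (with a 150 nm
lower margin for uncorrected drift): selecting on the noisy z_saf itself
truncates its own error distribution near the window edge and biases the
anchor by tens of nm when molecules exist above the window; z_astig is
3–5x less noisy here and its noise is independent of the SAF noise, so the
kept molecules' z_saf stays unbiased.

* **Tilt** (static): least-squares plane through the per-molecule
  `z_saf - z_astig` discrepancy vs (x, y), one round of 3*MAD rejection.
  Estimated once per acquisition, before drift (tilt is static, drift is
  temporal).
* **Axial drift**: 1000-frame subsets; 3D histograms (100 nm lateral,
  15 nm axial voxels) of the anchor molecules built twice — heights from
  z_saf vs from z_astig — cross-correlated along z only. Sub-voxel
  refinement re-histograms the astigmatic heights at fractional shifts
  (exact, no interpolation aliasing) and places the peak with a
  least-squares parabola over the +-1.5-voxel scan window. The correlation
  fixes the drift *shape*; the constant level is then re-anchored on the
  robust mean residual, because the skewed SAF distribution's histogram
  peak sits ~1 nm below its (unbiased) mean. Knots at subset midpoints,
  linear interpolation, constant extrapolation; under-occupied subsets are
  skipped with a warning.
* **Lateral drift**: per-window 2D histograms cross-correlated against the
  first window (50 nm bins, parabolic sub-pixel peak). Featureless scenes
  (correlation peak weak in absolute pair mass or indistinct from the
  random-overlap background) raise an error advising fiducials.
* **Field deformation**: the cylindrical lens magnifies x and y
  differently (~3.5%); the optimal affine map UAF->EPI is estimated by
  least squares on matched pairs (mathematically the same target as image
  cross-correlation, better conditioned). The anisotropy is read from the
  singular values, the rotation from the polar decomposition. The residual
  deformation is quantified as the count-weighted mean magnitude of
  per-cell mean displacement vectors on a 5x5 grid — the raw per-pair
  distance is dominated by localization noise and is reported separately.

## Fusion (`fusion`)

Per-localization precisions are the Cramer-Rao bounds of the
pixel-integrated elliptical-Gaussian model with uniform background under
Poisson noise, computed by numerical Fisher information (6 joint
parameters, matching the fitter; pixel grid equal to the fit ROI, enlarged
to cover +-3.5 widths). The astigmatic axial bound divides the
width-difference variance (including the width covariance) by the local LUT
slope; the SAF bound divides the ratio variance (fitted-count variances
from the same Fisher matrix) by the local curve slope. Weights are
evaluated at the record's fitted photons/widths and its current height,
with one fixed-point re-evaluation at the first-pass fused height.
`use_saf=False` reproduces astigmatism-only behavior for comparisons.
`weight_curves` tabulates the CRLBs and normalized weights vs depth for
nominal budgets; beyond the EPI width-filter cutoff (w > 180 nm,
z ~ 520 nm) the EPI-derived bounds are set to infinity because those PSFs
never survive detection.

## Stitching and filtering (`stitching`)

Focus-stepped acquisitions (600 nm steps, ~1 um capture each) merge by
propagating the absolute reference upward: each slice is cross-correlated
along z with the already-absolute slice below it over their overlap window
(intersection of occupied z ranges, robust quantiles), using the same
histogram machinery as the drift correction. Offsets accumulate; nothing
is deduplicated. Only axial offsets are estimated — the slices share one
field of view. The density filter removes localizations with fewer than
`min_neighbors` within a 3D radius.

## Evaluation (`evaluate`) and benchmarks (`benchmarks`)

Bead-style precision measurement: localizations are grouped per bead by
lateral radius-linkage (150 nm), and the per-bead SDs of the measured
positions over the acquisition are the precisions (beads with < 50
localizations are dropped; suspected merged clusters are flagged). The
benchmark studies reproduce the instrument characterizations end to end:

* `precision_study` — full pixel pipeline, 10 beads at z = 0..900 nm on a
  well-spread grid (shallow anchor beads deliberately non-collinear, beads
  >= 4 um apart to clear the pair-exclusion rule), two 256x256-pixel
  half-fields, 500 frames, nominal budgets.
* `tilt_study` (2 nm/um over 30 um), `chromatic_study` (70 nm focal
  offset), `drift_study` (100 nm sinusoid, period 20k frames, 10k-frame
  acquisition, 1000-frame knots), `affine_study` (3.5% anisotropy + 0.2
  deg + 200 nm, 5000 pairs, 20 nm jitter), `volume_accuracy_study` (beads
  0–600 nm, 20 nm slow drift) — all on the table-level path.

Problem sizes are chosen so each study estimates its quantity with
standard errors well below the bound it is compared against.

## Numerical choices and degenerate inputs

* LUT inversion: linear interpolation on the stored grid; strict
  monotonicity enforced at construction (tiny tie-breaking slope after
  isotonic regression; failure raises "calibration failed").
* Non-convergent PSF fits and edge-clipped ROIs drop the detection.
* merge of two absent sources -> record dropped with a flag; a single
  source passes through unchanged.
* Correlation of constant (delta-like) height distributions has no
  sub-voxel information; the refinement then returns the scan argmax
  (voxel-center aligned data recovers integer shifts exactly).
* All randomness flows from explicit integer seeds; fixed CSV float
  formatting makes identical runs byte-identical.

## Known limitations

* The fused axial precision in the 400–600 nm band is bounded at
  ~20–24 nm under the default photon budgets: the SAF signal is gone and
  the hyperbolic width law's information content caps the astigmatic
  channel there. A steeper empirical calibration (real instruments differ)
  would improve it; the simulator's law is a stand-in.
* Gaussian PSFs only — no vectorial/dipole model, no field-dependent
  aberrations beyond the listed biases, no refractive-index mismatch.
* Single-emitter fitting: overlapping PSFs are excluded (2 um rule), not
  resolved.
* The chi-square weighting of the fit carries a ~1% multiplicative photon
  bias (cancels in the SAF ratio, harmless for the width difference).
* Lateral registration between slices in stitching is assumed from the
  shared field of view; many-slice stacks accumulate registration error.
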