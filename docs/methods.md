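# Methods

`rovocal` models the desk-side optical commissioning of a rotating,
unbaited underwater video lander: estimating the camera's horizontal
field of view (FOV) from images of a planar test pattern, fitting a
one-coefficient radial distortion model, converting the FOV between air
and water across the housing's flat port, quantifying per-channel colour
attenuation against a reference chart over distance, and simulating the
recorder's protocol state machine. Because real pool imagery is rarely
available on a desk, a synthetic target renderer generates the test
scenes with exact ground truth, and every estimator is validated by
generative round trip.

## Field-of-view estimation

A planar target with two reference edges a known `dx_cm` apart is imaged
face-on at distance `D` (cm). If the same span covers `dx_pix` pixels of
an image `N_px` pixels wide, the full horizontal FOV is

    theta = 2 * arctan( N_px * dx_cm / (2 * D * dx_pix) )

This is a pure pinhole relation; the measured span is scaled to the full
sensor width, so the pattern need not fill the frame. Inputs are
validated (`dx_pix > 0`, `D > 0`); a zero physical span gives 0°.

Because radial distortion displaces the outer grid columns by up to a
few percent (a coefficient of 1.3e-4 px⁻¹ moves a node at radius 500 px
by ~6.5 %), the pipeline measures the span only *after* fitting and
removing the distortion from the detected node coordinates. Measuring
the raw span would bias the FOV by several degrees; the ordering is
therefore: detect → match → fit distortion → undistort nodes → span →
FOV.

## Flat-port refraction

The housing images through a plane window. For a thin flat port the
chief ray bends once by Snell's law, so a full in-air FOV `theta_a`
becomes, in water of refractive index `n`,

    theta_w = 2 * arcsin( sin(theta_a / 2) / n )

and conversely `theta_a = 2*arcsin(n*sin(theta_w/2))`, which is
undefined when `n*sin(theta_w/2) > 1` (reported as a domain error).
Port thickness and the air gap between lens and window are ignored —
they shift the entrance pupil but not the asymptotic angle. The default
`n = 1.34` (seawater) reproduces both whole-degree conversions quoted
for this class of instrument (82° air → 59° water and 60° water → 84°
air). Those two printed figures imply marginally different effective
indices once rounding is considered; no single `n` is forced to satisfy
both beyond whole-degree agreement, and both are kept as separate
checks. Angles are handled in radians internally and degrees at the
API; whole-degree rounding happens only in reporting.

## Distortion model

Grid distortion is summarised by a single coefficient `d` (px⁻¹) acting
on centre-relative coordinates with `r = sqrt(x² + y²)`:

* `radial` (default): `x' = x(1 + d r)`, `y' = y(1 + d r)` — a radially
  symmetric magnification. `d > 0` pushes nodes outward (pincushion),
  `d < 0` inward (barrel).
* `literal`: `x' = x + d r`, `y' = y + d r` — the same scalar offset
  added to both coordinates. This form is kept because it matches how
  the transformation is sometimes written down in field practice, but
  it is not radially symmetric (a node on the y axis shifts
  horizontally), so the symmetric form is the default for geometric
  work. Both forms share the sign convention.

Both forms are **linear in d**, so the least-squares estimate from
matched ideal/observed node pairs has a closed form
(`d = Σ g·Δ / Σ g²` with regressor `g = (x r, y r)` or `(r, r)` stacked
over both coordinates). The fit is unweighted and non-robust, matching
the simplicity of a single-coefficient model; outlier handling belongs
to the matching stage. `GridDistortion(...).fit()` returns the
estimate, its OLS standard error, the RMS residual in px, and the
barrel/pincushion label.

The distortion centre is fixed at the image centre (no centre
refinement), and coordinates are centre-relative pixels with y
increasing downward; raster conversion is 0-based with pixel centres at
integer coordinates.

Inversion: the radial form is inverted in closed form through the
quadratic `d r² + r − r_obs = 0`, using the cancellation-free root
`r = 2 r_obs / (1 + sqrt(1 + 4 d r_obs))`; the literal form by
fixed-point iteration (a contraction whenever `|d| r_max < 0.5`, error
after 50 iterations). Image undistortion resamples by inverse mapping
(output pixel q is read from the forward-distorted location of q) with
bilinear interpolation; samples falling outside the input get a
configurable fill value, which is what produces the slightly non-square
field after correcting a pincushion image.

## Synthetic pool scenes

The generator emulates a pool calibration campaign: a flat target
carrying a black grid (9×9 nodes, 8 cm pitch, 1 cm lines by default)
and a six-patch colour chart, imaged face-on at 1–6 m. Key choices:

* **Projection.** Pinhole with `f_px = N_px / (2 tan(FOV/2))`; the
  scene's `fov_deg` is the effective FOV at the port in the scene
  medium (pass the in-water FOV for submerged shots).
* **Rendering by inverse mapping.** Every output pixel is carried back
  through the exact inverse distortion into ideal pattern space and the
  pattern evaluated there with an analytic ~1 px coverage ramp. Lines
  are therefore anti-aliased and the ground-truth node positions are
  exact to the model, not to a rasterisation.
* **Line overhang.** Grid lines extend half a pitch beyond the outer
  nodes, as on practical calibration panels, so border nodes are full
  four-arm crossings and detectable by the same rule as interior ones.
* **Target scaling with distance.** By default the fixture series
  scales the target proportionally to distance (larger panels further
  away), keeping the pixel footprint constant across 1–6 m — pool
  campaigns use grids of several sizes for the same reason. This can be
  disabled.
* **Colour attenuation.** Chart patches are filled with
  `c(D) = c_ref · exp(−k_c · D)` per channel (single-path
  Beer–Lambert, D in metres). This exponential form is the generator's
  own declared model; the analysis side fits it back without assuming
  more. Default coefficients `(k_r, k_g, k_b) = (0.6, 0.15, 0.08) m⁻¹`
  follow the seawater ordering — long wavelengths absorb fastest. The
  grid and background are rendered at full contrast at every distance:
  geometry and colour are analysed separately, and keeping grid
  contrast constant isolates the geometric round trip from the colour
  one.
* **Noise.** Additive i.i.d. Gaussian pixel noise (default σ=1 for
  fixtures, σ=2 in the validation studies), seeded; renders are
  byte-reproducible given the scene. Quantisation to 8 bits follows.

What the generator does **not** emulate: turbidity and scattering,
vignetting, veiling light, chromatic aberration, sensor noise beyond
additive Gaussian, focus/depth-of-field effects, or imperfect target
placement (distances are treated as exact, as with a tape-measured
pool). Passing round trips therefore demonstrate the correctness of the
estimators under the stated image-formation model, not robustness to
every real-water artefact.

## Node detection and matching

Detection replaces manual point-picking. Coarse candidates are local
maxima of a separable crossing response: the product of "dark along the
row" and "dark along the column" box means, which peaks where two lines
cross and stays low on isolated segments. Because that response
plateaus over roughly a line width, each candidate window is first
recentred on the contiguous above-half-maximum run of its marginal
darkness profiles. Sub-pixel refinement then fits the two line
centrelines — the across-line intensity centroid per column (and per
row), restricted to a narrow band around the centre so chart patches
and neighbouring lines stay out of the weights — as quadratics
(absorbing distortion-induced bowing) and intersects them by
fixed-point iteration. A candidate is accepted only if all four arms of
the putative crossing are dark, which rejects patch corners and line
ends; mostly-dark windows (patch interiors) are rejected outright.
On noiseless renders this localizes all 81 nodes to < 0.25 px; at
pixel-noise σ=2 the mean error stays below 0.1 px.

Matching projects the ideal grid for the known camera/target/distance,
aligns centroids, forms mutual-nearest-neighbour pairs gated at 0.55 of
the node pitch, then re-aligns on the median residual and re-matches —
the median step makes the translation estimate insensitive to any
spurious detections. Fewer than half the projected nodes matched is an
error.

## Colour measurement and attenuation fit

Patch colour is the mean RGB over the centred sub-box covering 50 % of
each patch's bounding-box area (sides scaled by √0.5) — reproducible,
robust to edge anti-aliasing, and close to what an operator sampling
the patch centre with a pipette tool would get. With
`measured = reference · exp(−k D)`, the log-domain model
`−log(measured/reference) = k·D` is a zero-intercept line, fitted per
channel by least squares pooled over patches and distances
(`k = Σ D y / Σ D²`). Channel values at or below 5/255 are excluded
before the log transform — at 6 m the red channel of saturated patches
approaches zero and would otherwise dominate the fit through log
blow-up; a channel with no usable observations is flagged unfittable
rather than zero. R² is reported in the same zero-intercept
parameterisation.

## Recorder state machine

States: STARTING → READY (boot complete, LED still) → WORKING (magnet
swipe; motor aligns, video records) ⇄ STANDBY (magnet swipe) →
SHUTDOWN (dedicated shutdown swipe, honoured **only** in STANDBY — the
structural guarantee that no run shuts down mid-recording). Timer ticks
advance the rotation only in WORKING; every other state/event pair is a
protocol error. The rotation is mechanically indexed, so the cumulative
angle is exactly `step_count × step_deg` (60° steps, six frames per
360°). Defaults encode the standard survey protocol: 30 s dwell per
frame (≈3 min per rotation) and three undisturbed rotations per
observation (≈9 min). The motor-alignment delay on entering WORKING is
a configurable constant defaulting to 0 s (its real duration is
hardware-dependent); protocol-timing figures assume 0. Pressure and
temperature come from pluggable sources (constant, ramp, seeded random
walk), sampled every 10 s by default and flushed to a CSV
(`timestamp_iso,pressure_dbar,temperature_C`) at shutdown, matching the
instrument's behaviour of writing metadata before powering off. Whether
a real unit buffers or streams these rows is an implementation detail
of the firmware; the simulator samples continuously during the session
and writes once.

## Validation set-up and problem sizes

The unit and round-trip suites run on 640×480 renders (the geometry is
resolution-independent; full 1600×1200 UXGA renders are exercised in
the fixture path). The headline recovery study uses 50 seeded
replicates at σ=2 over distances cycling through 1–6 m for FOV and
distortion, and 50 six-distance series at 320×240 for attenuation;
the acceptance script runs a 12-replicate geometry study and a
4-series colour study, which is ample for max-error reporting at these
noise levels. Observed worst cases sit far inside the acceptance
envelopes: FOV within ~0.01° (envelope 0.5°), `d` within ~5e-7 px⁻¹
(envelope 2e-5), attenuation coefficients within ~0.5 % (envelope 5 %).

## Known limitations

* One radial coefficient: no tangential component, no higher-order
  terms, no principal-point refinement — adequate for the moderate
  distortions this class of housing shows, not for fisheye optics.
* The literal distortion form is provided for completeness but is not
  geometrically meaningful off the diagonal; round trips use it only
  through its own inverse.
* The attenuation model is single-path Beer–Lambert without ambient
  veiling light; at long range in real water the fit underestimates
  contrast loss.
* The detector assumes a roughly axis-aligned grid (rows and columns
  within ~±10° of the image axes); it is not a general checkerboard
  detector.
* The FSM models the protocol, not the hardware: no battery, encoding,
  or gear-train dynamics.
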