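# Methods

This note documents the model behind `litfield`, the conventions and
defaults that matter for interpreting its output, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the method's description leaves room.

## Quantities and units

The working quantity is spectral photon radiance, photons s⁻¹ m⁻² sr⁻¹ nm⁻¹
— radiance, not irradiance: light *arriving from a direction*, which is what
an eye or a camera pixel measures.  Photon flux is used because
photoreceptors are photon counters; across the visible band the energy per
photon differs by 75% (hc/400 nm vs hc/700 nm, CODATA 2018 constants), so
energy-based units misweight the spectrum.  All results are reported as
lit = log₁₀(photon radiance).  Spectral resolution is deliberately coarse:
three 100-nm bands (blue 400–500, green 500–600, red 600–700 nm) matching a
camera's RGB channels, plus "white", defined per pixel as the per-nm average
over the 300-nm union, (R+G+B)/3.

## Camera model and calibration data

The calibration file (JSON) carries: per-channel scale constants K_ch that
map counts to absolute radiance at reference settings; sensor black and
white levels; relative gain tables versus ISO and aperture (exact-match
lookup, nearest-key fallback with a warning — the tables are sampled, not
parametric); a vignetting table V(θ) at 10° steps of off-axis angle per
calibrated aperture, interpolated linearly in θ; and the projection geometry
(equisolid model, image-circle centre and radius).  The package defines and
validates this data model; performing the physical calibration (integrating
sphere, spectroradiometers) is outside its scope.  `synthetic_calibration()`
provides a synthetic but realistic instance (distinct per-channel K, linear
ISO gain, smooth 30% rim vignetting, black 256 / white 15871 counts) used by
the simulator and tests.

Conversion is linear: L = (counts − black) · K_ch / (t · g_ISO(S) · g_ap(N)).
Counts at or above 0.99 × white level are flagged saturated (the sensor
clips there; the factor leaves margin for quantization).  After black-level
subtraction, non-positive values are clamped to 10⁻³ × the smallest positive
radiance in the frame: dark noise below the offset carries no radiance
information, and the clamp keeps the logarithmic statistics finite without
affecting any percentile a bin ever reports in practice.

Vignetting is corrected in fisheye space, where θ is native, before
remapping; applying it after remapping would require resampling the θ map
and gains nothing.

## Geometry

The camera is horizontal; the fisheye's 180° image circle covers elevation
ε ∈ [−90°, +90°] (zenith to nadir) and azimuth φ ∈ [−90°, +90°] about the
optical axis, with the horizon through the image centre row.  The radial law
is equisolid, r = 2f·sin(θ/2), i.e. r/R = sin(θ/2)/sin 45°; lenses covering
more than 180° are cropped to the 180° circle.  Only the equisolid law is
implemented; the projection field is a registry hook for other laws.

The working raster is equirectangular: square, rows of constant elevation
(row 0 = zenith), columns of constant azimuth.  Cell (i, j) of an M×M
raster covers ε ∈ [90 − 180(i+1)/M, 90 − 180·i/M); angles are evaluated at
cell centres.  Remapping is inverse-mapped nearest neighbour: each output
cell centre is projected to its real-valued fisheye preimage and copies the
nearest source pixel — deterministic, hole-free, and value-preserving (the
output multiset ⊆ input pixels), which keeps order statistics meaningful.
Preimages are clamped one pixel inside the image-circle rim so rounding can
never select a pixel outside the imaged hemisphere.  The default output size
is the image-circle diameter 2·R px, preserving equatorial sampling density.
Raster sizes divisible by the bin count avoid aliasing of row centres
against bin edges and are recommended when comparing runs at different
resolutions.

## HDR bracketing

A bracket is typically three frames at −3/0/+3 EV (1 EV = a factor 2 of
exposure; 3 EV = ×8), extending usable dynamic range by 2⁶ = 64 (1.8 lit)
over one exposure.  The merge is a two-step rule.  (1) Normalization: each
radiance-converted frame is scaled so its median matches the bracket
average, computed over pixels unsaturated in every frame so clipping cannot
bias the reference; frames with no usable pixels are dropped with a warning.
The "average" of the per-frame medians is their geometric mean by default —
the pipeline's statistics live in log space — with an arithmetic option
(the two differ by well under 1% for a calibrated bracket).  (2) Selection:
each pixel/channel takes its value from the highest-EV frame in which it is
unsaturated.  Pixels saturated in every frame keep the lowest-EV (least
clipped) value and are flagged; downstream statistics *include* them, which
mimics the eye's own saturation on direct views of light sources.  No
Debevec-style weighted blending is used: the rule is hard selection.

## Statistics

Per 3° elevation bin (60 bins; membership by row-centre elevation, half-open
intervals, top bin closed at +90°) and per band, nine statistics: mean, std,
median, p25, p75, p2.5, p97.5, min, max.  Percentiles use linear
interpolation between closest order statistics (type 7), written out
explicitly in the code so the estimator is a documented formula.  Order
statistics are computed on the linear pixel population and then converted to
lit — a monotone transform, so this equals computing them on logs.  The mean
is converted to lit; the standard deviation has no well-defined log width
and is stored in linear radiance units (the one linear column in the
spreadsheet).  Empty bins are reported missing (NaN / empty cells), never
zero.  Equirectangular pole stretching is deliberately not solid-angle
corrected: the method characterizes the radiance distribution *per elevation
angle*, so every elevation contributes equally by construction.

Contrast-spans are p75−p25 (50%) and p97.5−p2.5 (95%), in lit.  The median
is the headline radiance because replacing k of a bin's n pixels with
arbitrarily bright values can move it by at most k ranks — the package ships
`median_robustness_check`, which verifies this exact order-statistic bound.

The simplified summary covers the upper (+10°…+90°) and lower (−10°…−90°)
fields, ignoring the horizon band (±10°): per field, the white median as the
equal-weight geometric mean of bin medians (i.e. the mean of their lit
values); the 95% span between the geometric means of the bin percentile
bounds; and RGB percentages from the arithmetic mean of each colour band's
linear bin medians, normalized to 100.  Equal bin weighting (not solid
angle) is the package's choice, consistent with the per-elevation philosophy
above.

Environments (many scenes) aggregate per bin/band by the log-average
x̄ = 10^{(1/n)Σlog₁₀xᵢ} applied to medians, percentiles and means; min/max
are pooled extremes; an aggregated std is not defined and is reported
missing.  This makes the aggregate scale-equivariant (scaling one of n
scenes by c shifts it by exactly c^{1/n}) — every scene contributes equally
regardless of its absolute brightness.  The display average image is the
per-pixel geometric mean (tone-mapped for the chart only; it never feeds
statistics).

## Synthetic scenes

The generator emulates the three features that dominate real light fields:

- a per-band **elevation profile**, piecewise-linear in lit (flat ground,
  flat sky, linear horizon transition in the presets);
- **azimuthal texture**: multiplicative log-normal noise with spread σ(ε) in
  lit units, so a bin's analytic median is the profile value and its 95%
  span is 2·1.96·σ.  The texture field is shared across bands (scene
  structure, not chromatic noise), which keeps the white channel's analytic
  truth exact; independent per-band fields are available
  (`chromatic_noise=True`);
- optional **disk sources** of given direction, angular radius and radiance.

Presets anchor absolute levels to the typical regimes (sunlit ≈ 16–18,
overcast ≈ 15–16, indoor ≈ 14–15, moonlight ≈ 11, starlight ≈ 9 lit) with
blue-rich skies, red/green-rich ground, and larger σ below the horizon.
Rendering inverts the analysis chain: forward-map each fisheye pixel to its
truth cell, apply vignetting, scale by exposure, add the black level, clip
at the white level, quantize to whole counts.  Auto-exposure places the
scene's median at 5% of the white level at EV 0, so a ±3 EV bracket sits
comfortably inside the sensor's range.  All randomness comes from one named
seed; photon shot noise is not modelled (determinism first), nor are
physically based sky models, lens flare, chromatic aberration or demosaicing
— so passing recovery tests demonstrates the correctness of the *pipeline*,
not robustness to every artefact of real sensors.

## Verification scales and estimator variance

End-to-end recovery tests render scenes through the full camera model and
compare recovered bin medians and spans with analytic truth.  The package's
documented scale for these runs is an image circle of 512 px (truth raster
1024²): the zenith/nadir 3° bins then map to ≈1100 independent fisheye
pixels — the poles are where the equirectangular raster duplicates few
source pixels many times, so per-bin sample size, not bias, limits accuracy
there.  At this scale the pole-bin median estimator has a standard error of
≈0.01–0.02 lit at σ = 0.35, and worst-bin deviations around 0.04–0.05 lit
occur at some texture seeds; mid-field bins are an order of magnitude
tighter.  Unit-scale tests use smaller cameras and either restrict
assertions to mid-field bins or use noiseless scenes, for the same reason.

## Known limitations

- Physical camera calibration, raw/DNG decoding and demosaicing are out of
  scope; input is linear 3-plane TIFF plus a JSON metadata sidecar (an
  external decoder can be plugged into `read_exposure`).
- Only the equisolid fisheye law is implemented.
- White balance, colour temperature and other colour-science quantities are
  deliberately not computed; the RGB percentages are camera-band ratios, not
  colorimetry.
- The chart's dashed guide levels (starlight 9, moonlight 11, twilight 13,
  overcast 15.5, sunlight 17 lit) are orientation marks, configurable and
  without measurement meaning.
- Aggregated standard deviations across scenes are reported missing rather
  than approximated.
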