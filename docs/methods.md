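# Methods

## Image-formation model

`irmkit.optics` implements the scalar, normal-incidence three-layer model of
IRM: cover glass / medium / specimen, the medium acting as a thin film of
thickness *z* (the glass-to-specimen gap). Interface reflectances follow the
normal-incidence Fresnel formula; the two reflected beams interfere as

I(z) = I_gm + I_mc + 2√(I_gm·I_mc)·cos(4π·n_m·z/λ + δ).

Assumptions inherited from this model: a single refractive index per layer
(no intracellular structure), illumination and detection perpendicular to
the cover glass, and no numerical-aperture correction to the phase. The
reflection phase shift δ is constrained to π whenever the specimen is denser
than the medium; the constructor rejects configurations that violate this.
Polarisation (RICM-style antiflex), partial coherence and scattering are out
of scope.

Default optical constants: n_glass = 1.515 (borosilicate), n_medium = 1.33
(aqueous growth medium, refractometer value), n_cell = 1.38. The cell index
only scales fringe contrast — never fringe positions, which depend on
n_medium alone — so any plausible bacterial value gives identical height
readouts; 1.38 is a mid-range choice. For the lens specimen the "medium" is
the air gap (n = 1) and the "cell" is the lens glass (1.515).

All heights are nm, wavelengths are vacuum nm, lateral coordinates μm,
pixel indices 0-based from the top-left.

## Synthetic data: what it emulates, and what it does not

`irmkit.simulate` is the source of every test image. It renders ground-truth
gap-height maps through the interference law, then applies, in order:

1. **Diffraction blur** — Gaussian with FWHM = 0.51 λ/NA (NA 1.35 for cell
   scenes, 0.3 for the lens), applied before noise so that peak-detection
   tests face realistically blurred fringes.
2. **Background inhomogeneity** — a multiplicative smooth field
   1 + a·S(x, y), with S a normalised sum of 2–4 low-order 2D cosine terms
   (integer frequencies 0–2 cycles per field) and amplitude a = 0.3 by
   default, emulating the uneven illumination that motivates flat-field
   correction.
3. **Detector noise** — zero-mean Gaussian, sd = noise_sd × the channel's
   dynamic range, clipped at zero.

All randomness flows from one explicit seed; equal seeds give bit-identical
stacks.

Specimen families:

* **Planoconvex lens**: sag z(x) = R − √(R² − x²), contact point at the
  window centre, gap index 1 (air). The radius of curvature is a direct
  input (it is not derived from a focal length, which would also require the
  lens glass index). Default sampling 0.84 μm/px.
* **Rod-shaped cells**: ~5 μm × 0.5 μm footprints rasterised around a
  centerline polyline at 0.1 μm/px, with four basal profiles: `adhered`
  (z ≡ 0), `single_lift` (linear ramp from the attached leading pole to
  180 nm), `undulating` (attached pole, then 180 → 90 → 180 nm), and
  `pole_tilt` (body projecting upward at 60° by default).
* **Gliding movies**: each cell translates along its centerline heading at
  its velocity (defaults in the 9–16 μm/min range of gliding myxobacteria);
  frame interval 10 s, which resolves that motion at 0.1 μm/px. Lift
  parameters evolve by a Gaussian random walk (sd 20 nm/frame) reflected
  into [0, 200] nm — an intentionally structureless, aperiodic process.
  Ground-truth centroids, lift heights and per-frame centerlines are
  returned alongside the rendered frames.

Not emulated: slime trails, Brownian wobble, confocal pinhole PSF shape,
photon-counting statistics, focus drift, detector gain nonuniformity beyond
the smooth field above. Passing tests therefore demonstrate correctness of
the *analysis chain* under controlled violations (blur, smooth gain, white
noise), not robustness to every artefact of real acquisitions.

## Flat-field correction

Each channel is divided by its k×k moving average, then by a fixed divisor
(default 2). k is specimen-dependent: 1001 for the lens (large, so the
slowly varying rings are not flattened), 31 for cells (dense fringes). The
nominal even windows 1000/30 are coerced up to the next odd integer so the
window has a centre pixel. Edges use reflective padding, which avoids the
darkening a zero-padded mean would cause near borders; denominators below
10⁻⁶ × the global mean are floored and the event logged. The output is
invariant to global gain and maps uniform images to the constant 1/divisor.
Floating point is kept throughout; nothing is clipped for display.

A symmetric moving mean of a fringe pattern is phase-preserving, so
correction leaves extrema where they were in the raw image: measured on
cosine fringes (51-px period) under 0.3-amplitude backgrounds, raw-to-
corrected extremum shifts are ≤ 1 px. Note the distinction from *absolute*
accuracy: the background itself can displace raw peaks by ~2 px at that
amplitude, and division with a 31-px window (smaller than the fringe
period) removes only part of that displacement.

## Lens fringe analysis

The radial profile averages intensity in 1-px annuli around the contact
point; when no centre is supplied it is estimated as the intensity-weighted
centroid of the darkest disc (the contact point is a destructive minimum).
Peaks need a prominence of ≥ 0.1 × the channel dynamic range, are refined to
sub-bin precision by a three-point parabolic fit (clipped to ±½ bin), are
discarded within 2 bins of the profile edges, and receive consecutive
orders N = 0, 1, 2, … outward. Peak radii map to heights through the known
sag; neighbour-fringe differences give the experimental axial spacing
(mean ± sd), compared to λ/(2n) as a percent deviation
100·|exp − theory|/theory. On noise-free renders the recovered spacing is
within 1% of theory for the 488/514/543-nm lines; the simulated-lens
pipeline check requires 244 ± 2 nm at 488 nm.

## Cell topography from color ordering

Line profiles sample the two channels along a user- or simulator-supplied
centerline at one-pixel steps, averaging `width` = 3 bilinear samples
perpendicular to the local direction (0.3 μm across a 0.5-μm-wide cell).
Automatic rod segmentation is deliberately not attempted.

Classification:

* **Adhered**: both channels within 15% of their minimum (a destructive
  minimum at contact) over ≥ 2 consecutive samples. The 15% band is this
  package's operational definition; with the default optics it corresponds
  to z ≲ 23–30 nm.
* **Incline / decline**: between adjacent maxima of *different* channels,
  shorter-wavelength-first means the surface is rising, the reverse falling.
* **Anchors**: every detected maximum is pinned at the constructive ladder
  height (N + ½)λ/(2n_m), with N counted per channel since the last adhered
  stretch; stretches with no adhered reference in view are flagged
  ambiguous rather than guessed.

Traces are smoothed with a 1-sample Gaussian before peak detection and the
prominence floor is 0.05 of the dynamic range — half the lens default.
Both numbers come from the fringe physics at cell scale: a 180→90→180 nm
undulation modulates the 635-nm channel by only ~10% of its range (90 nm
lies close to that channel's 119.3-nm maximum), so a 0.1 floor misses a real
fringe, while without smoothing a 0.05 floor admits white-noise peaks at 5%
noise. With these defaults, direction classification on rendered ramps is
exact noise-free and ≥ 95% correct at 5% noise.

Basal profiles interpolate linearly through the anchors, pin adhered
stretches at 0 nm and hold end values; anchors that contradict their
segment's direction raise an error naming the interval. Heights between and
beyond anchors are bounded, not measured — the reconstruction never exceeds
the last observed order, so a true 180-nm lift is reported as ≥ 119.3 nm
(the deepest anchor seen), never extrapolated. Per-frame adhered fraction
and maximum anchor height form the adhesion time series; its aperiodicity
descriptor is the biased autocorrelation of the max-height series (a
periodic lift shows a peak > 0.5 at its period, the reflected random walk
does not).

## Velocimetry

Velocity is the along-path displacement (sum of segment lengths, matching
path-length readouts) divided by elapsed time, in μm/min; it is invariant
under rigid motions of the coordinate frame. Tracks are screened for
approximately linear trajectories before group comparisons: "linearity" is
the fraction of positional variance explained by the total-least-squares
line (the leading eigenvalue share of the position covariance), threshold
0.9 by default — chosen over y-on-x regression R² because it is rotation
invariant. Strain groups are compared with a two-sided Welch
unequal-variance test; the percent decrease is 100·(mean_a − mean_b)/mean_a.

A calibration worth knowing: for groups of 21 and 22 tracks drawn from
means 15.76 and 9.26 μm/min with sds matched to SEMs of 0.89 and 0.72, the
Welch test attains p < 10⁻⁴ in ≈ 89% of replicates (noncentral-t power
0.892 at df ≈ 39) — strongly discriminating, but not near-certain at that
stringent level.

## Numerical choices and problem sizes

* Lens checks render a 1030² field at 0.84 μm/px (R = 20 mm, ~38 rings to
  the corner); cell checks render 100×100–110×220 fields at 0.1 μm/px and
  movies of 4–30 frames. These sizes give every estimator dozens of
  fringes/steps while keeping the whole suite fast.
* Peak positions: parabolic refinement only; no deeper sub-pixel model.
* Ties/degenerate inputs: zero-length polylines, empty groups, single-peak
  channels, out-of-aperture pixels and mismatched channel shapes all raise
  errors naming the problem; overlapping cells warn and let the later cell
  win.
* TIFF stacks are float32, pages frame-major then channel, with wavelengths,
  pixel size and timestamps in the image description and a JSON sidecar.

## Known limitations

* Absolute heights exist only at fringe anchors; between anchors the
  profile is an interpolation, and above the last anchor a lower bound.
* Order counting needs an adhered stretch in view; without one, assignments
  are flagged ambiguous rather than resolved.
* The forward model ignores NA-dependent phase effects and coherence
  envelopes, so simulated contrast at high orders is more ideal than real
  confocal data.
* The classifier assumes exactly two, well-separated wavelengths.
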