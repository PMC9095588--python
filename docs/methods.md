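# Methods

## Coordinate conventions and metric quantities

All modules share one spherical convention: colatitude θ ∈ [0, π] measured
from the +z pole (equator at θ = π/2), azimuth φ ∈ [0, 2π) from +x toward
+y.  At the poles φ is mathematically undefined and returned as 0 to keep
outputs deterministic.  Cartesian positions are lab-frame micrometres; the
vesicle frame is obtained by subtracting the fitted sphere centre.

Tracked planar positions are lifted onto the sphere by two maps:
equirectangular clicks via r = R(cos φ sin θ, sin φ sin θ, cos θ), and
confocal-plane clicks via r = (x, y, ±√(R² − x² − y²)) with the sign set
by a hemisphere flag.  Points up to |‖r − c‖ − R| ≤ 10⁻⁶ R are accepted as
on-sphere; beyond that, trajectory input is radially projected onto the
sphere with a logged warning (manual clicks are never exactly on-sphere),
while strict mode raises instead.

The central angle between two on-sphere points is computed as
atan2(|r₁×r₂|, r₁·r₂) rather than arccos of the dot product: the two agree
to 10⁻¹⁰ for well-separated points, but the arccos form loses precision
exactly where it matters most here — nanometre-scale steps of jammed
defects on an 18 μm sphere are micro-radian separations.  The arc-length
speed is v = R·γ/Δt, reported in nm/s at presentation boundaries (the
package works in μm and seconds internally).

## Sphere fitting and projections

The vesicle sphere is fitted to voxels above an intensity quantile
(default 0.99, inclusive of ties so saturated shells keep their surface
voxels) by the algebraic (Coope) linear least-squares formulation:
‖x‖² = 2c·x + (R² − ‖c‖²) is linear in (c, ·).  No iterative refinement is
applied by default; on shells with SNR ≥ 5 the recovered centre and radius
are well inside one voxel.

The equirectangular projection samples, for each map pixel direction
(θ, φ), the trilinearly interpolated stack intensity at radii spanning
[R − h, R + h] (shell half-width h, default 1 μm; the radius R itself is
always one of the samples) and reduces by maximum, matching the
maximum-projection style of the imaging; a mean reduction is available.
Map pixel (0, 0) touches θ = 0 and φ = 0; pixel centres sit at
half-integer angles; default resolution is 360 × 720 (≈0.5° bins, ≈0.16 μm
at the equator of an 18 μm sphere, finer than tracking noise).  Samples
leaving the stack are clipped to its bounds with a warning.

Latitude profiles average each θ row with equal pixel weight — the profile
one reads off an equirectangular image — and normalize the trapezoidal
integral over θ to 1.  An optional sin θ weighting gives per-area density
instead.  Hemisphere projections restrict the z maximum-projection to
voxels above/below the sphere's equatorial plane.

## Speeds, angular MSDs, feature tracking

Instantaneous speeds are arc-length speeds of consecutive frame pairs and
require regular sampling.  The angular MSD is computed per component from
the angular coordinates, time-averaged over all overlapping windows of a
single trajectory (overlap maximizes data at the ~30–60 frame scale of
the movies), with the azimuth unwrapped before differencing so the 0/2π
seam injects no jumps.  No sin θ metric correction is applied to the φ
component by default — the reported quantity is exactly the coordinate
MSD ⟨(φ(t+τ) − φ(t))²⟩ — and a metric-corrected variant is a separate
option.  Scaling exponents are least-squares slopes of log MSD vs log τ;
the fit range is a user parameter defaulting to the first quartile of
lags (the short-time regime).  A subtlety worth knowing: a trajectory
circulating about the polar axis has unwrapped φ growing linearly, so its
φ-MSD is exactly (ωτ)² at **all** lags; the long-lag saturation
characteristic of bounded angular coordinates appears when the circulation
axis is tilted so the circle does not enclose the z-pole, and the tests
exercise both situations.

The sparse feature tracker is deliberately simple and deterministic:
features seed at local intensity maxima of the first frame, and each is
followed by maximizing the normalized cross-correlation of a patch
(default 15 px) within a search window (default ±10 px), with φ-periodic
wrapping, parabolic sub-pixel refinement of the correlation peak, and
track termination when peak correlation drops below 0.5.  Tracks too close
to a pole row stop rather than correlate across the pole.  Gaps are not
interpolated.  Time-averaged flow decomposes each track step's tangential
displacement on the local (e_θ, e_φ) frame, scales it to the arc-length
speed, and averages vectors on a coarse (θ, φ) grid.

## Defect statistics

Charges live in exact rational arithmetic (`fractions.Fraction`, allowed
set ±1/2, ±1), so charge sums are never floats.  The Poincaré–Hopf check
passes a configuration iff it either does not cover the full surface
(streams, vortices and partial jams are not topologically bound — the
`covers_full_surface` flag is categorical user/ground-truth input, not
inferred from images) or sums to +2.  Four-defect configurations are
summarized by the mean of the six pair angles; 109.47° (arccos(−1/3)) and
120° are the tetrahedral and planar references, and the
tetrahedral/planar/intermediate classifier requires a tolerance below half
their gap (5.26°) to keep the classes disjoint.  Configuration stability
is the temporal standard deviation of the mean pair angle; the default
"stable" reading of < 2° over 30 frames is this package's
operationalization.

## Pattern classification

Laboratory classification of vesicle patterns is by eye; here it is an
explicit decision rule over measurable features, all thresholds exposed in
`ClassifierConfig`: area coverage (sin θ-weighted fraction of map pixels
above 0.2 × the time-mean map maximum), latitude-profile peak, azimuthal
occupancy and ridge-latitude dispersion (closed rings occupy every φ
column at near-constant latitude), median structure speed, and defect
counts by charge.  Defaults — coverage thresholds 0.005/0.8, speed
thresholds 15/25 nm/s, equator band 15° — are motivated by the measured
speed scales (moving structures 40–50 nm/s, jammed ones 5–10 nm/s).  The
rule cascade: empty → globally jammed (full coverage, slow, ≥4 half
defects) → band (full coverage, moving, two +1 defects or an equatorial
closed ridge) → partially jammed (a pinned +1/2 defect, slower than
15 nm/s, coexisting with a moving structure) → vortex (closed off-ridge,
partial coverage, moving) → stream.  The per-defect speeds needed for the
partially-jammed rule are supplied alongside the defect configuration;
the feature vector is always returned so any decision can be audited.
Contradictory defect input (full coverage, charge ≠ +2) yields a warning,
not an exception.

## Density criteria

Encapsulated actin concentration converts to a membrane surface density
under the assumption that every filament is membrane-bound:
ρ = c_A·N_A·R/(3·n·L_eff) filaments/μm², with n = 370 monomers/μm.  Two
filament lengths are deliberately separate parameters: the mode length of
the log-normal length distribution (L_mode = 0.6 μm) and the effective
per-filament length used in the monomer budget (L_eff = 0.55 μm).  The
0.55 μm value is the one that makes the density range (1.8–10.7 /μm² for
100–600 nM), the packing fractions (0.007–0.04 via the rectangle
approximation φ = ρ·L·w, w = 7 nm) and the Onsager critical density
ρ\* = 3π/(2L²) ≈ 15.6 /μm² mutually consistent; the mode length gives
13.1 /μm² instead, and both are plain function arguments, never
hard-coded.

## Synthetic scenes: what they emulate and what they do not

The generators are kinematic, not mechanistic: structures move along
prescribed constant-latitude circles (streams and vortices at their
observed 45–46 nm/s, bands at 40 nm/s), and jammed defects perform
isotropic surface diffusion (tangent-plane Gaussian steps of per-component
variance 2DΔt re-projected to the sphere; the projection error is
O(step²/R²), negligible at nm steps).  Jammed initial positions are drawn
from the two-up/two-down four-point family that interpolates continuously
between the regular tetrahedron and the equatorial square, solved so the
frame-0 mean pair angle equals the requested target exactly, then randomly
rotated.  Filament lengths are log-normal with the log-location chosen so
the distribution **mode** equals the requested value (μ = ln mode + σ²);
σ_log defaults to 0.5 and is exposed.

Rendering draws each structure as a Gaussian-cross-section tube shaded by
3-D arc distance from each pixel direction to the curve, so polar area
distortion of the equirectangular grid introduces no artefacts.  Tube
intensity is modulated along the comoving arc coordinate (~6 μm texture
wavelength), which is what makes patch tracking possible — a featureless
tube sliding along itself is untrackable (the aperture problem), as real
streams would be without internal texture.  Voxel rendering uses a
flat-top radial shell profile (plateau ±1.2 μm with Gaussian shoulders):
with the plateau wider than the interpolation stencil, the radial maximum
of a uniform shell is sampled on a constant plateau and the projected map
is flat to float precision, rather than carrying the ~2% grid-anisotropy
ripple a pure Gaussian shell leaves under trilinear interpolation at
0.5 μm voxels.  All randomness flows through `numpy.random.default_rng`
seeded from the scene seed (and frame index for render noise), making
every output bitwise reproducible.

What the scenes do **not** model: filament-level collision dynamics
(stop-and-go interactions are the *motivation* for the pattern taxonomy,
not simulated here), photophysics (bleaching, blinking), motor-density
coupling, and out-of-focus/PSF effects.  Passing tests on these scenes
therefore validate the measurement pipeline — projections, speeds, MSDs,
pair angles, classification logic — not any claim that the classifier
reproduces human labels on real microscopy data.

## Problem sizes and numerical defaults

The test and acceptance workloads use deliberately desk-scale sizes
chosen as sufficient for their statistical statements: classifier
validation on 5 classes × 10 seeds at 120 × 240 map resolution over 8
frames; sphere-fit recovery on 20 noisy shells at 0.6 μm voxels;
manual-vs-feature-track consistency on a 25-frame 360 × 720 movie;
MSD exponent checks on 200–2000-frame trajectories.  Tie-breaks and
degenerate inputs are handled explicitly: pole azimuth pinned to 0,
≥3 curve samples so arc end-tapering never erases a point structure,
inclusive quantile thresholds for plateaued shells, and rejection (with
informative errors) of irregular sampling, off-sphere input beyond
tolerance, empty windows, and zero MSDs in log-log fits.

## Known limitations

* The feature tracker is single-template NCC without re-detection or
  linking; it is a reference backend, not a dense optical-flow method.
* φ-MSD near the poles mixes metric stretch into the coordinate MSD by
  design (fidelity to the coordinate definition); use the
  metric-corrected option when arc-like units are wanted.
* The classifier thresholds were designed around the synthetic suite's
  speed and coverage scales; real data will need threshold review, which
  is why every decision ships with its feature vector.
* Defect positions are input (tracked elsewhere or ground truth);
  automatic defect detection from orientation fields is out of scope.
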