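# Methods

This note records the physical model, the numerical choices, and the
deliberate simplifications behind `mlcport`, in the spirit of a methods
section: what is modeled, what is calibrated, and what the passing tests
do and do not demonstrate about real deliveries.

## Coordinates and geometry

Right-handed frame, lengths in cm: origin at isocenter, source at
`(0, 0, 100)`, beam along −z at gantry 0, leaf motion along x, leaf
widths stacked along y. Gantry rotation is applied to photons as a
rotation about the y axis after MLC transport (the MLC model itself is
gantry-invariant in the collimator frame).

The MLC occupies the slab between `z_upper` (50.9 cm from the source by
default — consistent with Varian head geometry; the exact value is
configurable because it is machine-commissioning data) and
`z_upper + physical_thickness`. Each leaf is split into an upper and a
lower half at the mid-height plane. Each half has a piecewise-constant
thickness-vs-cross-leaf-position table in physical MLC-plane
coordinates; tungsten in the upper half abuts the mid-height interface
and grows upward, lower-half tungsten grows downward, so
tongue-and-groove steps are cut from the outer leaf surfaces. Leaf-pair
tip positions are stored at the isocenter plane and divergence-projected
to the leaf mid-height by similar triangles.

**Focused leaf sides.** Varian leaves are trapezoidal in cross-section:
their sides are aligned with the divergence fan. The path integrator
therefore evaluates all cross-leaf table lookups in the *fan coordinate*
(the ray's y projected along the fan onto the table's reference plane at
leaf mid-height). A source-focused ray keeps a constant fan coordinate,
so interleaf gaps and tongue-and-groove strips act at every off-axis
position, exactly as interleaf leakage appears across the whole film in
measurements. Without this the narrow interleaf strips would wash out a
few centimeters off axis and no physical gap width could reproduce the
measured transmission.

**Leaf tips.** The leaf end is a circular arc of radius `tip_radius`
tangent to the nominal tip position at mid-height (HD120: 16 cm,
Millennium: 8 cm). For the Millennium a planar facet continues
tangentially at the 11.3° tip angle beyond the arc contact point; the
HD120 has no facet. `tip_max_thickness` optionally caps the tungsten
height in the tip zone (default: the full leaf height, i.e. no cap).
`leaf_offset` models the physical gap between nominally closed opposing
tips (calibration-dependent; default 0), applied symmetrically.

**Path integration.** The radiological path is a midpoint-rule
integration over 0.05 cm slabs through both halves; within each slab the
ray position is evaluated continuously, the half's thickness/owner is
looked up exactly (binary search in the breakpoint table), and the
tungsten presence test combines the vertical-extent condition with the
per-bank tip-penetration inequality. Against a 0.01 cm brute-force
integrator the shipped resolution agrees to well under 1% on average;
single rays grazing a feature edge can differ by up to ~1% of the
closed-leaf path, which is the tolerance used in the oracle test.

## Synthesized thickness tables and their calibration

The vendor's cross-leaf thickness tables are proprietary, so the
packaged tables are synthesized from the published construction data:
full 6.9 cm (HD120) / 6.7 cm (Millennium) body thickness, interlocking
upper/lower halves shifted by ±0.015 cm (tongue-and-groove), and
interleaf air strips at each leaf boundary where only one half's
tungsten covers the ray. One free parameter remains — the width of those
strips. Following the standard commissioning procedure of adjusting the
MLC model until the simulated transmission matches a film measurement,
the HD120 strip width was set once, by a bracketing scan, so that the
simulated mean transmission (15×17 cm² field, 5 cm depth, 12 cm
cross-leaf averaging span, 6X beam) matches the film-measured 1.2% at
the vendor-consistent tungsten-alloy density of 18.9 g/cm³. The result
is 0.015 cm, frozen into the packaged tables
(`scripts/generate_mlc_tables.py` regenerates them). The Millennium
tables keep a nominal 0.006 cm strip; no measurement is pinned to them.

Passing the transmission check therefore demonstrates that geometry,
spectrum and transport jointly reproduce the calibrated observable — it
does not demonstrate that the synthesized cross-section matches the real
leaf drawing feature by feature.

## Source model

The proprietary linac phase space is replaced by a parametric source on
a phase plane 55 cm from the target: a histogram energy spectrum
(inverse-CDF over bins, uniform within a bin) and a radial
lateral-fluence importance weight, with all photons focused at the
source point. Two editable presets are packaged: `6X` (flattened;
approximate Varian-class 6 MV bremsstrahlung shape, mild off-axis
horns) and `6X FFF` (softer spectrum, forward-peaked cone profile). The
vendor spectra are unpublished; these presets are approximations, which
is one reason the transmission calibration above is performed against
the integral measurement rather than assumed.

Histories are weighted by the jaw-field area so scored dose is per unit
incident fluence at isocenter; ratios of simulations with different
field sizes (output factors) are then meaningful. Because the model has
no collimator head scatter, output-factor trends here reflect only
MLC/jaw-shaped primary plus first-scatter fluence.

## Transport and scoring

Per history: draw `u`, interpolate the machine state, sample a photon in
the jaw rectangle, integrate its tungsten path, then

- primary: weight × `exp(-μt)` (forced transmission — the dominant
  leakage signal carries almost no variance);
- first scatter: interaction site from the truncated exponential along
  the tungsten path, Klein–Nishina energy/angle (two-branch
  composition-rejection), uniform azimuth, weight
  `w·(1−exp(−μt))·(μ_C/μ)`.

The scattered photon's residual tungsten path is approximated by scaling
the remaining primary-path areal density by the slant ratio of the z
direction cosines (clipped at 10× the total path); photons scattered
upward are discarded since they cannot reach the phantom. The true
residual path through neighboring leaves is not re-traced; this
Siebers-style choice is an assumption, second-order for the validated
observables because scatter contributes ~15% of the transmission signal.
The scatter origin is placed at the areal-density fraction of the slab
depth, an approximation with no effect at the scoring distances used.

Scoring is collision kerma in water: at each grid z-plane crossing a
photon deposits `w · E · (μ_en/ρ)(E) · exp(−(μ/ρ)_w(E) · depth)` per
unit voxel area, with `depth` either an explicit slab depth (planar
mode; slant-corrected) or the distance from the ray's entry into the
grid's bounding box (3D water-box mode). There is no electron transport
and no buildup: depths shallower than the buildup region are outside the
model's validity. Per-voxel relative uncertainty comes from 10
sequential batches (sample standard error of the batch mean).

Attenuation data are embedded total mass attenuation coefficients for
tungsten and water on standard reference grids over 0.01–7 MeV
(log-log interpolated, K-edge double node for tungsten), plus the water
mass energy-absorption coefficient. The Compton branch is computed
analytically from the Klein–Nishina total cross section (free-electron
approximation, accurate above ~0.1 MeV). Coherent scattering is not
separated out; it is negligible above ~0.3 MeV where all validated
quantities live.

## QA computations

**Absolute dose** is the linear conversion
`D_abs = D_raw × (D_cal^meas / D_cal^MC) × U` with the
monitor-backscatter term fixed at zero (appropriate when the monitor
chamber cannot be modeled); relative uncertainties are unchanged, so the
conversion commutes with denoising.

**Adaptive Savitzky–Golay filter.** Per voxel, cubic windows of
half-width 4, 3, 2, 1 are tried largest-first; the window's order-2 3D
polynomial is fitted by weighted least squares (weights 1/σ²from the
stated uncertainties) and accepted if the reduced χ² satisfies
`χ²/ν ≤ 1 + 2√(2/ν)` — a two-sigma allowance on the χ² distribution's
spread. The first accepted window supplies the fitted central value and
its covariance-derived uncertainty; if none passes the voxel is returned
unsmoothed (which is what preserves sharp penumbrae). The threshold
factor and window list are arguments; the defaults are the package's
choice since only the method, not its constants, is standardized.

**Gamma analysis.** Global-normalization gamma with dose criterion as a
percentage of the reference maximum, ROI above a threshold percentage of
that maximum, pass = γ < 1 (strict). The evaluated grid is interpolated
trilinearly on a 0.3 mm offset subgrid within a search sphere capped at
3× the DTA; offsets are processed in increasing-distance order with
early termination, which is exactly equivalent to the exhaustive search
(verified against a brute-force oracle). The measure is asymmetric under
exchanging the grids (normalization and ROI are recomputed), which is
tested and intended.

**Transmission and density calibration.** The transmission protocol
simulates paired open/blocked 15×17 cm² static fields (one bank fully
covering the field), scores a 2 mm planar grid at 5 cm depth, and
averages the voxelwise blocked/open ratio over a 12 cm cross-leaf span
in a 1 cm axial band. `calibrate_density` wraps this in a bracketing
bisection over tungsten density (monotone decreasing transmission),
sharing one seed across evaluations so the objective is smooth.

## Test patterns

Static patterns (transmission pair, odd-leaf bar) are direct aperture
constructions. Dynamic patterns are built by a minimal-time
unidirectional sliding-window sequencer: given a target 1D fluence, the
leading tip's arrival time at x accumulates the negative fluence
increments and the trailing tip's the positive ones, and sampling the
inverse trajectories at uniform meterset gives the control points. The
multibar (7/5/2 mm bars), cross-leaf gradient (pairs closing in y
order) and negative pyramid (an |x| sliding-window phase plus a |y|
reopening phase) reproduce the *intended cumulative fluence* of the
named shapes; they are equivalents of the clinical test files, not
replicas, and their accumulated ideal fluence is asserted in tests
against direct meterset integration.

The synthetic noisy dose grid (`make_synthetic_noisy_dose`) is a broad
Gaussian-edged field with independent multiplicative Gaussian noise and
matching stated uncertainties. It emulates the statistical character of
a batch-scored MC dose grid in a low-gradient region; it does not
emulate correlated noise between neighboring voxels, dose gradients at
penumbrae, or non-Gaussian tails, so the denoising result bounds
filter performance only for the smooth-region regime it models.

## Problem sizes and determinism

The shipped validation runs use 10⁶ histories for the transmission
ratio (the deterministic primary estimator makes the blocked-field
signal nearly noise-free, so the open-field statistics dominate), a 50³
grid for the denoising study, and 300k histories for the in-suite
transmission check; these sizes put every stochastic check several
standard errors inside its tolerance while keeping the whole suite at
around half a minute. Every stochastic operation takes an explicit seed
(NumPy `SeedSequence` spawning per batch); identical seeds give
bit-identical dose arrays, which is tested.

## Known limitations

- No electron transport: buildup-region and surface doses are out of
  scope; comparisons are valid at depths ≥ d_max.
- No phantom scatter: scored kerma omits in-water scatter, so absolute
  depth-dose shapes are primary-kerma shapes, adequate for ratios
  (transmission, output factors without head scatter) and pattern
  comparisons at fixed depth.
- No pair production or photoelectric secondaries in tungsten; above
  ~5 MeV the single-Compton model undercounts scatter slightly.
- Scattered-photon residual paths are slant-scaled, not re-traced.
- Spectrum presets are approximations; users with measured spectra
  should supply their own tables (plain CSV).
- Deliverability constraints (leaf speed, dose-rate limits) are not
  enforced beyond geometric validity of apertures.
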