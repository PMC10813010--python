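# Methods

## Model

`skullray` treats each transducer element as an independent geometric ray
aimed at the sonication target, and the skull as a single effective fluid
layer bounded by two interfaces (water→skull, skull→brain). Per channel the
model produces a total intensity transmission

    T_total = T_ws · (1 − A_p) · T_sb ∈ [0, 1],

and aggregates channels as sonication efficiency (mean over active channels,
×100) and delivered energy (sum, unit input power per channel; a common drive
phase and amplitude is assumed, so no aberration correction is modelled).

Assumptions worth stating explicitly:

- **Fluid acoustics only.** No shear-mode conversion, no frequency-dependent
  attenuation, no standing waves, no focal-pressure or bioheat computation.
  The quantity of interest is transmitted energy, not focal pressure.
- **One effective skull layer.** The cortical–trabecular–cortical sandwich is
  not modelled as four interfaces; its heterogeneity enters through the
  solidity μ (bulk absorption) and the mean HU between the tables
  (density/speed). This matches the structure of the transmission formula
  above rather than a layered-media computation.
- **Threshold segmentation.** The skull is wherever the (smoothed) HU profile
  lies inside a window, default 1155–3000 HU. Channels whose rays never meet
  the window are "water paths" and transmit fully by policy; channels whose
  refracted ray leaves the volume without an inner-table crossing are
  deactivated and logged.
- **Critical angle.** A channel at or beyond asin(c₁/c₂) at the outer table is
  deactivated (total reflection; clinical systems switch such channels off to
  avoid skull heating and shear waves). Equality is included: it transmits
  zero energy and is numerically indistinguishable from "greater than".

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| skull window | (1155, 3000) | HU | threshold segmentation of bone |
| ρ_min, ρ_max | 1000, 2200 | kg/m³ | HU→density calibration range |
| HU_min, HU_max | 300, 2000 | HU | HU→density calibration range |
| velocity curve | (1000→1500) … (2200→3000) | kg/m³ → m/s | monotone density→speed map |
| a_min, a_max | 0.2, 8.0 | dB/mm | absorption bounds of the solidity law |
| β | 0.5 | — | absorption exponent |
| water | ρ=1000, c=1500 | kg/m³, m/s | coupling bath |
| brain | ρ=1040, c=1560 | kg/m³, m/s | medium past the inner table |
| tilt range | ±15, step 1 | degree | frontal/sagittal scan grid |
| TDS weights | 1, 0.25, 0.25, 0.5 | — | factor weights |

The density calibration bounds are configurable because published HU→density
fits vary by scanner and kernel; the defaults span water to dense cortical
bone. The density–velocity curve ships as a monotone piecewise-linear default
anchored at water (1000 kg/m³ → 1500 m/s) rising to 3000 m/s at ρ_max; an
experimentally calibrated curve can be substituted via the YAML config
(`velocity_curve: {densities: [...], speeds: [...]}`).

Two deliberate formula choices:

- **Intensity-mode interface coefficients.** The standard oblique-incidence
  pressure coefficient 2Z₂cosθᵢ/(Z₂cosθᵢ + Z₁cosθₜ) exceeds 1 into a stiffer
  medium (water→bone ≈ 1.6), which would make "efficiency" unbounded. The
  default is therefore the intensity coefficient
  4Z₁Z₂cosθᵢcosθₜ/(Z₂cosθᵢ + Z₁cosθₜ)², guaranteed in [0,1] and symmetric at
  normal incidence, so T_total is a true energy fraction; `mode: pressure`
  preserves the pressure form for comparison.
- **Solidity vs porosity in the absorption law.** The empirical law is
  implemented as a = a_min + (a_max − a_min)·μ^β with μ the solidity, which
  assigns *maximum* absorption to solid bone — a convention that makes dense
  shells attenuate ~80 dB and efficiencies of order 10⁻⁶ %. Physically one
  can argue the exponent base should be the porosity 1 − μ (solid bone at
  a_min, trabecular bone higher); `AbsorptionParams(exponent_base="porosity")`
  selects that reading and yields clinically plausible fractions. The default
  keeps the solidity form; all relative quantities (tilt ranking, improvement
  percentages, symmetry nulls) are insensitive to the choice because it
  rescales every channel's bulk loss monotonically. dB converts to an
  intensity fraction as A_p = 1 − 10^(−a·t/10).

## Numerical choices

- **Voxel traversal.** The 3D-DDA enumerates every voxel a segment crosses by
  merging the parametric half-integer plane crossings of the three axes;
  simultaneous crossings (exact corner hits) merge into a single diagonal
  step, which matches a dense sample-and-round oracle and is deterministic.
- **Profile smoothing.** The 26-neighbor mean (center excluded) is computed
  once per volume as a convolution and cached; boundary voxels average their
  existing neighbors only, so no HU is invented outside the scan. Smoothing is
  applied once (not iterated).
- **Collision localization.** Profile values are box averages over whole
  voxels, so each value is anchored at its chord *midpoint* — anchoring at the
  voxel entry point would bias the crossing by half a chord, and the chord
  length varies with direction (1 voxel along axes, √3 along diagonals),
  which made that bias direction-dependent. The threshold crossing is then
  linearly interpolated between the two bracketing midpoints, giving
  sub-voxel collision points. (A higher-order refinement that resampled the
  smoothed field trilinearly was tried and measured noisier; it is not used.)
- **Normals.** The 5×5×5 Zucker–Hummel kernels weight each offset by
  component/‖offset‖², evaluated on raw HU at the voxel nearest the collision
  point, scaled per-axis for anisotropic spacing, and sign-flipped to oppose
  the incoming ray (this handles the inner table, where the intensity
  gradient points backwards along the ray). A vanishing gradient raises a
  degenerate-normal error; inside `trace_channel` that channel is deactivated
  and logged rather than aborting the sonication.
- **Solidity.** Peaks are local maxima (≥ both existing neighbors, endpoints
  included); with fewer than two maxima the segment endpoints are used and the
  fallback is logged. μ is a trapezoidal integral ratio, clamped to (0, 1].
- **Skull properties per channel.** The refraction step needs the skull speed
  before the inner collision is known, so a provisional speed is taken from
  the in-window mean HU along the straight ray; the reported density, speed,
  and transmission coefficients are then recomputed from the profile between
  the actual collision points. At near-normal incidence the two coincide.
- **Rotation convention.** Tilts rotate element positions rigidly about the
  target (so the focus stays on-target): extrinsic Rx(ax) then Ry(ay). Zero
  tilt returns the input positions bit-for-bit, making the (0,0) scan cell
  identical to a plain simulation. Order effects are below one grid step
  within ±15°.
- **Ties.** The best/worst scan cells are the first maximal/minimal cells in
  sorted (ax, ay) order — deterministic under exact ties.

## What the phantoms emulate — and what they do not

The shell phantom is a sphere: cortical HU 1800, trabecular HU 1300 (optional
hemispheric porosity reduction and/or shell thinning toward a chosen axis),
brain 40 HU, water 0 HU, optional Gaussian CT noise, voxelized by
voxel-center radius with no partial-volume blur. It gives analytic collision
radii, radial normals, and known layer HU — which is what the geometric and
symmetry tests need. It does *not* emulate: aspherical calvaria, sutures,
spatially varying cortical thickness ratios, beam-hardening or streak
artifacts, gantry-tilted or oblique acquisitions, or realistic HU
distributions. Passing tests therefore validate the geometry, acoustics
arithmetic, and optimization machinery — not clinical accuracy on real heads.

Synthetic treatment tables draw a per-treatment heating efficiency (default
0.5–3.5 °C/kJ) and generate sonications with ΔT = HE·energy + noise
(energies 2–12 kJ); inefficient treatments receive proportionally more
sonications and aborts, mirroring the clinical pattern that poor heating
forces stepwise re-sonication. The TDS correlation *signs* on such cohorts
are meaningful; the magnitudes are a property of the generator, not of any
patient population.

## Resolution and test problem sizes

Voxel discretization enters the energy exponentially through the absorption
term (≈8 dB/mm of thickness error), so per-channel energies are noisy at
coarse pitch: at 2 mm the per-channel spread on a noise-free concentric
phantom has cv ≈ 1.3, at 1 mm ≈ 0.35, at 0.5 mm ≈ 0.16. The geometry-level
checks (normals, collisions) run at 1–2 mm, where their one-voxel tolerances
are meaningful. Energy-aggregate checks use CT-realistic sub-millimeter
phantoms: the rotational symmetry null (a concentric shell must deliver the
same energy at every tilt) uses 0.4 mm voxels, where the residual grid-noise
spread over a 7×7 tilt grid is ≈1.7 % of the mean; the constructed-optimum
recovery uses 0.5 mm voxels, 256 elements, a 60° aperture and a 5° grid step.
Clinical skull CT is ~0.5 mm in-plane, so these are the realistic operating
resolutions of the method rather than stress settings.

The optimum-recovery construction deserves a note: under a full 90° cap, a
smooth hemispheric *porosity* gradient creates a transmissivity peak that
stays inside the aperture at every tilt, so delivered energy barely depends
on tilt and the argmax is noise-dominated. A shell-*thinning* gradient with a
60° aperture makes coverage of the favorable patch genuinely tilt-dependent;
the best tilt then tracks the thinning axis (frontal +10° in the tests)
across seeds, with strictly positive improvement over the untilted reference.

## Known limitations

- Single-layer skull acoustics; no shear waves, no phase information, no
  focal-pressure estimate — rankings of transducer poses, not absolute
  dosimetry.
- The absorption-law convention changes absolute efficiencies by orders of
  magnitude (see above); only relative comparisons are convention-free.
- Threshold collision detection inherits threshold sensitivity: bone below
  the window lower bound (severely porous diploë) shortens the detected
  skull segment, which is also what a clinical threshold-based tracer would
  see.
- Min–max TDS normalization makes scores cohort-relative; scores from
  different cohorts are not comparable.
- Axis-aligned volumes only; oblique direction matrices are rejected at load.
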