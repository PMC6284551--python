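# Methods

This note records the models behind `stereoplacenta`, the parameter
choices that matter, and what validation on synthetic phantoms does and
does not establish.

## Phantoms and ground truth

Phantoms are built from analytic primitives so every reference value is
exact:

- **Sphere** (calibration primitive): closed-form volume and surface.
- **Shell**: an inner ball ("fetal capillary") wrapped in a
  constant-thickness membrane, surrounded by "maternal blood space". Every
  through-membrane intercept has true length equal to the thickness
  parameter, making it the calibration target for the thickness estimator.
- **Placenta analogue**: an ellipsoid (default semi-axes 1250 × 1250 ×
  650 µm) partitioned into three axial bands along the vertical
  (chorionic-plate-normal) axis — decidua basalis, junctional zone,
  labyrinthine zone, default volume fractions 0.15 / 0.30 / 0.55. Band cut
  heights are solved from the cumulative ellipsoid volume, so the zone
  fractions are exact by construction. The labyrinth carries fetal
  capillary tubes (default 180, radius 14 µm) and maternal channel tubes
  (default 130, radius 16 µm): finite cylinders parallel to the sectioning
  axis, placed by rejection sampling with every pair of tube surfaces at
  least `tau_true` (default 5 µm) apart — the guaranteed interhaemal
  membrane thickness. Placement is bounded (default 10,000 tries per tube)
  and fails loudly naming the violated constraint rather than silently
  relaxing it.

Because the primitives are disjoint and analytic, composite ground truth
(band volumes, tube volumes and surfaces) is closed form. An independent
voxel oracle (`voxelize` / `voxel_volumes` / a marching-cubes surface
oracle) cross-checks the closed forms in the test suite at stated
resolutions; it is a verifier, not the source of truth.

**Scale.** The default phantom is ≈ 4.25 mm³ — roughly two orders of
magnitude below a term rat placenta — with tube counts chosen for
statistical adequacy (tens of vessel profiles per high-power field, ≥100
cycloid intersections and ≥200 grid points per placenta at the default
grids) and desk-scale runtimes. Stereological estimators are
scale-equivariant, so recovery at this scale exercises exactly the same
arithmetic and sampling design as at organ scale.

**What the phantom does not emulate:** trabecular labyrinth geometry,
vascular branching, staining texture, section deformation/shrinkage, and
segmentation error. Passing tests therefore demonstrate correctness of the
estimators and sampling design given correct labels, not robustness to
imaging artefacts.

## Sectioning and sampling design

Sections are planes perpendicular to the chorionic plate (constant-x
planes), so the vertical axis lies in every section — the vertical-sections
design required by the cycloid surface estimator. The virtual microtome
cuts the block exhaustively at `t_sec` (default 7 µm) with a uniformly
random phase; systematic uniform random (SUR) selection takes `n_select`
(default 10) sections with period `k = floor(total/n)` from a uniform
random start. Every probe overlay (point grid, cycloid grid, intercept
line grid) draws a random offset uniform over one fundamental tile — the
randomization that design-based unbiasedness rests on; none of it is
optional.

Points take the label of the (half-open) pixel containing them. Cycloid
arcs are polylines sampled at half-pixel arc-length steps; boundary
crossings are counted against a Gaussian-smoothed (σ = 1 px), bilinearly
interpolated indicator of the structure mask rather than the raw binary
raster. This matters: the raw pixel boundary is a staircase whose
perimeter exceeds the true boundary's by up to 4/π, and counting against
it inflated surface estimates by ~19% in development; against the smoothed
sub-pixel boundary the sphere surface is recovered to within 1%.

Orthogonal intercepts start where horizontal SUR lines cross the
fetal-capillary boundary and march along the local outward normal
(estimated from a σ = 2 px Gaussian-smoothed capillary mask) in
quarter-pixel steps until first entering a maternal blood space. Rays that
leave the raster, exceed a length cap, or re-enter the capillary are
dropped.

## Estimators: two deliberate readings

- **Cavalieri multiplier.** The volume is `V = d · a_p · ΣP` with `d`
  the distance between *sampled* planes (`k · t_sec`). Multiplying the
  point total over sampled sections by the full block thickness instead
  would overestimate k-fold; the sphere-recovery test pins the correct
  reading.
- **Plane-of-sectioning correction.** The orthogonal-intercept correction
  is the multiplicative constant `8/(3π) ≈ 0.8488` applied per intercept
  before harmonic averaging. A thin-shell argument shows it is exact for
  this geometry: sectioning a thin spherical shell at height `h = R sin φ`
  gives apparent width `≈ τ/cos φ`; intercept starts are proportional to
  the sectioned circumference (`∝ cos φ`) and `h` is uniform, so
  `E[1/w] = (1/τ)·∫cos³φ dφ / ∫cos²φ dφ = (8/(3π))/τ` — the corrected
  harmonic mean is `τ` exactly in the thin-shell limit. The literal
  reading `(8/3)·π ≈ 8.38` inflates thickness roughly ten-fold and fails
  shell recovery by the same factor; both behaviours are asserted in the
  tests.

The cycloid estimator is grouped as `Sv = 2·ΣI / (l_p · ΣP(ref))` — the
only bracketing with consistent units (`l_p · ΣP(ref)` is the test length
deployed in the reference space).

Lengths are micrometres throughout the estimators; the diffusion-capacity
boundary converts to centimetres, where the Krogh coefficient for oxygen
(`17.3·10⁻⁸ cm² min⁻¹ kPa⁻¹`) lives. Quantities passed across that
boundary carry unit tags and wrong-dimension inputs raise, so a µm value
cannot silently masquerade as cm.

For placental efficiency the per-surface denominator is reported three
ways (per FC surface, per MBS surface, and per their sum), since "fetal
capillary and maternal blood space areas" admits both readings.

## Densitometry

OD calibration is a monotone piecewise-linear interpolant through
step-tablet anchors (transmission law `gray = white·10^-OD` in the
synthetic tablet); queries outside the calibrated range clamp with a
warning. Band quantification integrates a lane profile over a window above
a rolling-minimum (grey-opening) baseline — deliberately simple plumbing,
since film-scan extraction details are not the point. Exposures within the
linear range are reconciled under the model
`recorded = gain_e · truth_lane`: with known gains by averaging
gain-corrected readings, otherwise by joint log-least-squares across lanes
with the reference exposure's gain fixed at 1. Readings at ≥98% of full
scale are treated as saturated and excluded. Normalization divides by the
β-actin lane intensity and scales so the control-group mean is exactly 1 —
an identity the tests enforce for arbitrary inputs.

## Statistics

- **Two-factor GLM** (dam-level outcomes): OLS of
  `outcome ~ hypoxia * mitoq` with sum-to-zero (−1/+1) coding; each term
  is tested by removal given all others, i.e. Type III — the convention
  matching mainstream ANOVA software for unbalanced designs like
  16/16/18/16 litters. An empty cell drops the interaction with a warning.
- **Litter-nested LMM** (fetus-level outcomes): dam random intercept, REML
  via a 1-D profile over the variance ratio λ = σ²_litter/σ²_resid
  (block-wise Woodbury identities make each profile evaluation O(n));
  fixed-effect tests use Satterthwaite denominator df computed from
  finite-difference gradients of the contrast variance and the observed
  REML information. λ̂ = 0 is handled as an explicit boundary (the fit then
  coincides with OLS and df revert to residual df). Fixed effects agree
  with an independent reference implementation to ≤1e-4 on random tables;
  type-I error calibrates to 0.05 ± 0.01 over 2000 null simulations.
- **Repeated measures** (gestational time courses): group × day fixed
  effects with a dam random intercept — equivalent to classical
  repeated-measures ANOVA under compound symmetry, and chosen over
  sphericity-corrected ANOVA because it is simpler to validate and
  degrades gracefully with unbalanced days. Per-day joint group contrasts
  are reported. Multi-df effects use Satterthwaite df averaged over the
  effect's contrast basis.

No multiple-testing correction is applied by default (significance at
P < 0.05 per comparison, matching the design convention); a
Benjamini–Hochberg pass can be layered on the emitted p-values if wanted.

## The synthetic study and its defaults

The four-group study (N/H/HM/NM, 16/16/18/16 litters, 8 fetuses per
litter, one male placenta per litter analysed) programs multiplicative
group effects on phantom generation: hypoxia +14% total volume and +20%
capillary surface; hypoxia+MitoQ additionally +15% maternal channel
volume; fetal body weight unaffected. Between-litter variability is
lognormal with CV 8%, back-computed from typical SEMs of term placental
and fetal weights at these litter counts; blot expression programs a 1.8×
hypoxia effect with CV 20%. These are study conditions, set once — not
tuning knobs.

Per placenta the pipeline mirrors the two-magnification protocol: whole
low-power SUR sections (25 µm/px) for Cavalieri volume and zone fractions,
and one high-power window (2 µm/px, 600 µm wide) on the section nearest
the midline for FC/MBS densities, cycloid surfaces and membrane
intercepts. A single midline window oversamples tubes relative to the
whole labyrinth, so labyrinth vascular quantities carry a multiplicative
sampling bias (~+10–30% depending on geometry) that is *shared across
groups* — group contrasts and detection power are unaffected, but absolute
labyrinth surfaces should be read with that in mind. Total volume and zone
fractions are recovered essentially unbiasedly.

## Numerical choices

- Grid defaults: Cavalieri/zone point grid 100 µm (a_p = 10⁴ µm²);
  high-power point grid 25 µm; cycloid tiles with l_p = 100 µm (sphere
  validation) / ~32 µm (labyrinth window); intercept line spacing 25 µm.
  Chosen by the pilot-precision rule (≥200 points, ≥100 intersections per
  placenta) and recorded in the pipeline config.
- REML profile optimized by bounded scalar minimization on λ ∈ [0, 10⁴],
  xatol 1e-10, with an explicit λ = 0 boundary comparison.
- Ties/degeneracies: empty intercept samples, empty reference point sets,
  zero-point Cavalieri counts and all-saturated lanes are errors or
  warnings, never silent zeros (except `ΣP = 0 → V = 0` with a low-count
  warning, which is the estimator's honest value).
- Determinism: every stochastic routine takes an explicit RNG or seed;
  identical config + seed reproduces byte-identical phantoms, tables and
  pipeline artefacts (the manifest digests enforce this).

## Known limitations

- Tubes are parallel to the sectioning axis rather than isotropically
  oriented; the cycloid estimator's isotropy guarantees are validated on
  the sphere, while the placenta-analogue surfaces inherit the
  single-window bias described above.
- The membrane thickness of the placenta analogue is a guaranteed
  *minimum* separation; its realized intercept distribution is wider than
  a real interhaemal membrane's, so `tau_h` on the composite phantom is a
  pipeline-consistency readout, not a recovery target (the shell phantom
  is the recovery target).
- No coefficient-of-error prediction formulas are provided; precision is
  characterized empirically by Monte Carlo spread.
- Image-analysis realism (staining, deconvolution, segmentation) is out of
  scope by design.
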