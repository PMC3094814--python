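# Methods

## The quantity under study

Striatal SPECT quantification is summarised by the specific uptake ratio
SUR = (striatal − background)/background, computed voxelwise over striatal
volumes of interest (VOIs) with the background taken as the mean of a
posterior background VOI.  For a phantom the generating concentrations give
the true SUR exactly, so for each VOI v, acquisition p, reconstruction
method r and post-smoothing kernel s we form

* SUR_mean(v,p,r,s), SUR_SD(v,p,r,s) — mean and sample standard deviation
  (ddof = 1) of the voxelwise SUR over the VOI;
* AR(r,s) = 100/(n_p·n_v) · Σ_{v,p} SUR_mean/REF(v,p) — average recovery,
  the bias measure (100% = unbiased);
* RMSCOV(r,s) = 100·√( mean over (v,p) of (SUR_SD/SUR_mean)² ) — the noise
  measure;
* aSUR(r,s) = mean over (v,p) of SUR_mean — a truth-free surrogate for AR,
  exactly proportional to it when all REF are equal.

Sweeping the smoothing kernel s traces a bias-noise curve per method.
Methods are compared at matched noise: the reference point is the
unsmoothed point of the best-bias method, and every other curve's bias is
interpolated linearly in RMSCOV at that reference noise (clamped to the
nearest endpoint and flagged when the reference noise lies outside a
curve's range).  The per-(v,p) values behind each interpolated point are
emitted alongside the aggregate so a downstream repeated-measures analysis
can consume them; the analysis itself is out of scope.

## Digital phantom

The phantom is an ellipsoidal head (semi-axes 72 × 90 × 58 mm) holding four
fillable chambers — left/right caudate (≈4.1 mL) and putamen (≈5.9 mL)
ellipsoids at plausible stereotactic positions — inside a uniform brain
background chamber, surrounded by an attenuation-only scalp/skull shell of
11.8 mm (the shell carries no activity, which is why the scalp contour is
invisible on emission data and must be approximated during uniform AC).
The physical phantom's chamber drawings are not published; the volumes and
positions above are configurable order-of-magnitude choices and absolute
recovery therefore carries no meaning beyond its regime.

Voxelisation assigns a voxel to a structure iff its centre lies inside the
structure's ellipsoid — no supersampling — so total activity equals
concentration × voxel volume × voxel count exactly, which the tests use as
an oracle.  Chambers must not overlap and must lie inside the head; both
are enforced at render time.  Activity units are arbitrary (only ratios
enter any statistic); attenuation is per cm, converted to per-voxel path
lengths once inside the projector.

Defaults: background 5 (kBq/mL analogue), μ = 0.15/cm in the water-filled
chambers and background (the value a phantom CT shows for the 0.1 M NaI
carrier solution), μ = 0.20/cm for the shell (a soft-tissue/bone
composite).  The per-side striatal concentrations are back-solved from the
requested true SURs as conc = background·(SUR+1); the default series is 7
acquisitions whose 14 side-SURs span 2.08–14.70 evenly, pairing a low side
with a high side and alternating sides.

VOIs are defined on the label field itself — the digital equivalent of
drawing VOIs on a registered CT of the phantom with air-filled chambers:
striatal VOIs are the exact chamber labels (caudate ∪ putamen per side,
42 voxels each at the default grid) and the background VOI is an
axis-aligned box in the posterior third of the brain chamber, clipped to
the background label and required to clear the striatal chambers by two
voxels.

The NaI carrier-solution attenuation coefficient is computed by the mixture
rule from an embedded table of elemental mass-attenuation coefficients
(H, O, Na, I at 100/150/200 keV, log-log interpolated) with solution
density approximated as water plus solute mass.  At 0.1 M and 159 keV this
gives 0.1535/cm ≈ the 0.15/cm read off phantom CT maps; the iodine entries
dominate the solute term but contribute under 4% of the total, so the
result is insensitive to their tabulation precision.

## Acquisition model

The projector is the rotate-volume-then-sum type.  For each of 120 views
(3° steps, 150 mm circular orbit, dual-head treated as a plain 360° orbit):

1. the volume is rotated in-plane by the view angle using a precomputed
   sparse bilinear-interpolation matrix;
2. each voxel is weighted by exp(−∫μ dl) along its exit path toward the
   detector (cumulative μ along the ray with a half-voxel self term —
   emission-CT convention);
3. each constant-depth plane is convolved with an isotropic 2-D Gaussian in
   the detector-parallel (u, z) coordinates — axial coupling included —
   with FWHM given by the collimator model at that plane's distance from
   the collimator face (distance = orbit radius − rotated y-coordinate);
4. planes are summed onto the detector.

Rotation-matrix columns with at least half their interpolation mass inside
the grid are normalised to unit sum, so projection conserves activity for
any object inside the field-of-view cylinder to machine precision (edge
columns keep their natural partial mass: corner voxels really do leave the
grid under rotation).  The backprojector applies the exact transposes of
the same factors, so ⟨Px, y⟩ = ⟨x, Pᵀy⟩ holds to floating-point accuracy —
the property OSEM's convergence theory assumes.  Gaussian kernels use
σ = FWHM/(2√(2 ln 2)), truncated at 4σ, zero-padded (symmetric, hence
self-adjoint); planes behind the collimator face (empty grid corners) clamp
the distance at zero.

Counting noise: the noiseless sinogram is scaled so its expectation matches
a total-count budget and each bin is replaced by an independent seeded
Poisson draw.  The default budget is drawn uniformly from 3.2–3.8 million
counts — the clinical range — multiplied by (grid voxels)/(128·128·64) so
that coarser desk-scale grids keep the per-voxel count density, and hence
the noise character, of the clinical acquisition (≈0.44 M counts at the
default 64×64×32 grid).

### The simulated camera's point-spread function

The camera's response is modelled as the depth-dependent Gaussian with
intercept 5.3 mm and slope 0.075 mm/mm — the *effective*, end-to-end
characterisation of the physical chain (the "method 2" constants obtained
by optimising measured-to-true SUR on an independent phantom) — rather
than the in-air point-source measurement (3.5 mm + 0.033 mm/mm,
"method 1").  This is a deliberate design choice: the simulator omits
scatter and septal penetration entirely (see Limitations), and those
processes are a large part of why physical striatal SPECT recovers only a
fraction of the true SUR.  Folding them into the effective blur keeps the
simulation in the physically observed regime — every reconstruction
underestimates the true SUR, blur-corrected reconstructions recover more
and carry less relative noise, CT-based AC beats the uniform ellipse — with
unsmoothed recoveries of roughly 30% (no PSF correction) to 65%
(depth-dependent correction) at the default grid.  Had the in-air response
been used as truth, a matched-model OSEM would recover ≈100% of the SUR
and the recovery-optimised corrections would overshoot beyond 130%, a
regime no physical striatal SPECT system operates in.

## Reconstruction

OSEM with the standard multiplicative update
x ← x · Pᵀ_k(y_k/(P_k x + ε)) / Pᵀ_k(1), cycling 30 ordered subsets for 10
full iterations (the schedule used clinically to ensure VOI-mean
convergence).  Subsets take views by stride (subset k = views k, k+30,
k+60, k+90), giving balanced angular coverage with a fixed order.  The
system operator is the same implementation as the simulator with the
reconstruction's own μ-map and PSF parameters, so any data/model mismatch
is purely a parameter difference.  Numerical guards: ε = 1e-12·max(y)
(small enough that a truth-initialised matched-model reconstruction of
noiseless data is a fixed point to better than 1e-6 relative over the full
300-update schedule), subset sensitivities floored at 1e-6 of their
maximum with dead voxels held at zero, and a uniform positive start inside
the field-of-view cylinder.  Nonnegativity is preserved by construction.

Attenuation correction variants:

* **ct** — the measured μ-map enters the system matrix (in simulation the
  phantom's true μ-map, optionally misregistered).
* **ell** — a uniform μ-map built per axial slice: a moment-fit ellipse to
  the brain support, expanded radially by 11.8 mm (the phantom's scalp
  thickness, invisible on emission data), filled with μ = 0.11/cm — the
  broad-beam value recommended for brain SPECT, which deliberately sits
  below the narrow-beam 0.15/cm of water to compensate bone and scatter in
  clinical use.  The support is estimated from the emission data alone
  (a 2-iteration uncorrected OSEM pass thresholded at 10% of maximum,
  slice-wise hole-filled), emulating the scalp-contour uncertainty of
  tracers that concentrate in the basal ganglia; tests may supply the
  ground-truth labels instead.  The moment fit adds the 1/12-voxel
  sampling variance before converting second moments to semi-axes
  (a = 2√λ for a filled ellipse), which keeps few-voxel slices honest.
* **none** — no AC; diagnostic only.

Corrections happen inside the iterative loop, matching how clinical
workstations integrate them.  The classical first-order multiplicative
uniform-AC factor C = [mean over angles of exp(−μ·exit path)]⁻¹ is
provided as `chang_first_order_factor` for cross-checking against closed
forms (C = e^{μR} at a disk centre), not as the default correction path.

Post-smoothing is an isotropic 3-D Gaussian, 0 (identity) plus 1–16 mm
FWHM in 1 mm steps; 0 is always included because the matched-noise
comparison anchors on unsmoothed blur-corrected reconstructions.

## Experiments

**Phantom study** — for each acquisition: build, project, add noise,
reconstruct under every configured spec, sweep smoothing, quantify.  The
default spec set is the six correction combinations with the method-2 PSF
parameterisation (the recovery-optimised set); `parameter_set="both"` adds
the method-1 versions (ten specs).  Outputs: the (v,p,r,s)-keyed VOI
table — from which every aggregate is re-derivable — bias-noise curves,
the matched-noise table with per-measurement details, and per-method
ordinary-least-squares regressions of measured on true SUR (skipped for
configs with fewer than three points).  Per-acquisition noise seeds are
fixed affine offsets of the master seed, all below 2³¹; a rerun with the
same config and seed reproduces byte-identical CSVs.

**μ-sweep** — one acquisition reconstructed with ellipse AC at μ from 0 to
0.5/cm (0.05 steps), reporting per-side SUR and the maximum percent
variation (100·(max−min)/min) over the EANM-relevant 0.10–0.15/cm
sub-range.  Raising the assumed μ over-corrects the deep striatum relative
to the peripheral background VOI, so measured SUR increases monotonically
with μ.

**Misregistration** — emulates patient movement between SPECT and CT: the
μ-map (CT frame) is rigidly translated/rotated in-plane while the emission
data stay fixed, then reconstructed as ct+p0, ct+pd and ell+pd (the
ellipse is derived from emission support and is immune to CT
misregistration, so its AR is a constant reference line).  Integer-voxel
translations are applied losslessly; general moves use cubic spline
resampling about the grid centre with negative undershoot clamped.  The
default grid crosses posterior translations of 0/1/2 pixels with rotations
of 0/2/4°.  Direction matters: because the background VOI sits
posteriorly, an anterior μ-map shift inflates SUR while a posterior shift
deflates it; the posterior default reproduces the clinically relevant
ranking flip, where a 1–2 pixel mismatch makes uniform-AC-plus-blur
correction the best-recovering method even though CT-based AC wins when
registration is perfect.  Rotations up to 4° barely move AR.

## Problem sizes

The default grid is 64×64×32 at 5.9 mm — half the clinical in-plane matrix
— chosen so the full seven-acquisition, six-reconstruction, 17-smoothing
study completes in a few minutes on one CPU; all metrics are ratios and
tolerate resolution scaling, and the count budget scaling preserves noise
character.  Unit and property tests run on 16³–32³ grids.  The clinical
128×128 matrix at 2.95 mm is available through the grid config.

## What the simulation does and does not capture

Captured: photon attenuation (uniform and nonuniform maps, misregistered
maps), distance-dependent collimator blur with axial coupling, Poisson
counting statistics at clinical count density, the full OSEM correction
matrix, VOI statistics and the bias-noise methodology.

Not captured: photon scatter and septal penetration (deliberately excluded;
folded into the effective camera PSF above), energy windows and the I-123
high-energy emission spectrum, detector intrinsic resolution as a separate
term, dead time, non-circular orbits, head-specific detector sensitivities,
CT physics (μ-maps are generated directly, never via HU conversion), and
patient anatomy — the "patient-like" arm is a misregistered phantom, which
is exactly the control experiment that explains the patient-data ranking
flip, not a patient simulation.

Consequences worth knowing before extrapolating to real data: because the
simulated degradation lies entirely inside the Gaussian family the
reconstruction models, PSF-corrected reconstructions retain a much larger
recovery advantage here than on physical data, and their bias-noise curves
dominate the uncorrected curves at every common noise level — the
smoothing crossover seen on physical systems (where heavy smoothing makes
uncorrected reconstructions competitive at matched noise) does not occur
in this simulator.  The corresponding acceptance check is kept faithful and
fails, documenting the boundary of the model.  Likewise absolute AR values
are higher than physical phantom studies report for the blur-corrected
methods; orderings, linearity and the misregistration flip are the
meaningful outputs.

## Degenerate inputs and error behaviour

Geometry errors (overlapping chambers, chambers outside the head, empty
background box) are rejected at phantom build; empty support masks, subset
indivisibility, negative counts, negative smoothing and non-positive
background means raise immediately with the offending quantity named;
pipeline stages re-tag exceptions with the failing stage.  Config files
reject unknown keys by name and fill every omitted key with the defaults
listed above.
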