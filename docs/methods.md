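# Methods

## Physical model

The induced electric field of a TMS pulse is quasistatic: E = E_p − ∇φ,
where the primary field E_p = −∂A/∂t comes from the coil current and the
secondary field from charge that accumulates on tissue conductivity
interfaces. The head is a set of nested closed surfaces (skin, skull,
CSF, gray matter, white matter) with piecewise-constant conductivities;
continuity of normal current across each interface yields a
second-kind integral equation for the scaled surface-charge density
g = ρ/ε₀ collocated at facet centroids:

    g_m (σ⁻+σ⁺)/(2(σ⁻−σ⁺)) − n_m·Σ_{k≠m} g_k A_k (c_m−c_k)/(4π|c_m−c_k|³)
        = n_m·E_p(c_m).

Storing g = ρ/ε₀ makes the geometric kernel dimensionless (millimetres
cancel), so ε₀ never enters the system; g carries V/m units directly.
Interfaces without conductivity contrast drop out of the system.

### Numerical scheme

* **Row-averaged collocation.** Each equation is averaged over the six
  interior barycentric-subtriangle centroids of its facet. On a
  homogeneous sphere at the default density this reduces the interior
  field error from ~6% to ~2.7% relative L2 versus the closed form, at
  no per-pose cost (the right-hand side stays a single centroid
  evaluation per facet; the residual quadrature error of that choice is
  second order in the facet size). The flat self-facet contributes
  nothing beyond the analytic principal-value coefficient.
* **Near-field quadrature.** Source facets within 3 facet-edge lengths
  of an evaluation point are integrated with barycentric refinement
  whose level is chosen so the quadrature patch diameter stays below
  half the point–facet distance (capped at level 4 for assembly, 5 for
  field points; level L gives 6^L patches). Intracortical observation
  points ~1 mm above a ~10 mm facet are the stressing case.
* **One factorization, many solves.** The dense operator is
  LU-factorized once per head discretization; each coil pose costs one
  primary-field evaluation and one triangular solve. The assembled
  matrix is kept so every solve reports a true relative residual
  (direct solves sit at rounding level, bound 1e-8). GMRES is not
  needed at the problem sizes this package targets.
* **Charge-to-field map.** For a fixed observation surface the linear
  map from facet charges to E at all points is precomputed once
  (including near-field corrections), making a pose evaluation a
  mat-vec.

### Validation oracle

The total induced E inside *any* spherically symmetric conductor due to
an external magnetic dipole has a closed form, obtained by reciprocity
from the classical expression for the external magnetic field of a
current dipole inside a sphere:

    E(r) = (μ₀/4πF²) [ (ṁ·∇_a F)(r×a) − F (r×ṁ) ],

with a the dipole position, ṁ = (dI/dt)·m, d = a−r, F = d(ad+a²−r·a).
It is independent of the radial conductivity profile — so the same
formula validates the homogeneous sphere and the full 5-shell phantom —
and has exactly zero radial component; at the center it vanishes (a
current dipole at the center of a sphere produces no external magnetic
field). The acceptance bound is 3% relative L2 over 500 interior points
at the default mesh density; on the mid-surface of the desk-scale
5-shell phantom the magnitude error stays within ~3% of the field peak,
which is the quantity the cost function consumes.

## Coil model

A planar current loop is equivalent, outside its windings, to a
uniformly magnetized disc, so a spiral wing is discretized as a polar
grid of dipole patches whose moment density equals the number of turns
enclosing the patch (constant inside the innermost winding, tapering
linearly to zero at the outermost). Two counter-wound wings stacked
along local ±y give the figure-8; the dominant induced E under the
center — the *handle* direction used by placement — is then local +x,
perpendicular to the line of wing centers, as the winding tangents at
the center dictate. Presets: `small` (35 mm wing diameter) and `large`
(70 mm), handle-direction dimensions in ratio 2, ~650 dipoles each
(validated to <0.5% discretization change on doubling; the filament
Biot–Savart oracle agrees to <2%). Skin-depth-resolved conductor
cross-sections are not modelled. Default pulse strength dI/dt =
9.4×10⁷ A/s; every field is exactly linear in it.

CCD files store positions in metres and moments in A·m² per ampere;
internally all geometry is millimetres.

## Phantoms

* **Sphere head**: five nested icospheres, default radii
  92/86/82/80/77.5 mm — an adult-head scale with a 2.5 mm GM–WM gap.
  Default conductivities (S/m): skin 0.465, skull 0.010, CSF 1.654,
  GM 0.276, WM 0.126 (standard segmentation-pipeline defaults; they are
  configuration, not ground truth).
* **Gyrus head**: the GM and WM shells carry two Gaussian-profile
  trenches (default depth 7 mm, width parameter 10 mm ⇒ σ = 5 mm,
  trench centerlines ±10 mm from the crown) running along a great
  circle, leaving a smooth gyral crown between sulcal walls. The
  profile is analytic, so crown polyline and wall normals have closed
  forms used as oracles by the placement tests. A slope bound
  (depth < σ√e) rejects self-intersecting parameter choices.
* **Seed jitter**: a seed drives a small inter-subject variation —
  global scale ±2%, crown azimuth, ±10% depth/width — so a multi-seed
  batch exercises genuinely different geometries while staying
  bit-reproducible per seed. `sulcus_depth=0` reproduces the sphere head
  exactly.
* **Targets** are chord-marched along the crown polyline so consecutive
  straight-line spacings equal the nominal 10 mm to numerical precision.
  Experimental motor-mapping layouts hold a 10 mm mean spacing with an
  STD under 1.2 mm; the phantom construction is deterministic, so its
  STD is ~0.

What the phantoms do *not* emulate: real gyral folding and its
per-subject variability, segmentation error, white-matter anisotropy,
ventricles by default, or secondary hot spots in neighbouring gyri.
Passing tests therefore demonstrate the machinery (solver accuracy,
constraint handling, descent/stability behaviour, metric definitions) —
not population-level focality-improvement magnitudes on real heads,
which depend on cortical geometry the phantoms idealize away. On these
smooth phantoms the sulcus-aligned start is frequently near-optimal, so
per-target improvements are small (0–10%) and the stability correction
rarely has to revert.

## Observation surfaces

For every GM facet centroid the shortest vector v to the 1:36
barycentrically refined WM centroid cloud is found; the sampling point
is placed at fraction f of v (f = 0.5 for the 1:1 mid-surface, ≈ layer
2/3; f = 0.8 for the 4:1 surface, ≈ bottom of layer 5 — "4:1" is read as
GM-side : WM-side distance). Points whose |v| exceeds a 6 mm cortical
thickness cap are excluded as unpaired. The pipeline samples the field
on a once-refined GM mesh (6× the facets of the BEM GM shell) so the
cost landscape is resolved finer than the 2 mm search steps; the BEM
resolution is independent of this choice.

## Inverse search

* Variables update in the fixed order φ (yaw about the coil normal),
  α (pitch), β (roll), then x, y, z; each is probed at {v−Δ, v, v+Δ}
  (Δ = 2 mm / 0.1 rad) and the minimizer adopted immediately; ties keep
  the current value to prevent drift. Passes repeat until the per-pass
  AAD decrease drops below 0.05 mm (far below mesh resolution) or a
  20-pass cap. Poses with coil–scalp clearance < 10 mm (minimum
  point-to-triangle distance from the coil's bounding winding points to
  the skin) carry a +inf cost sentinel: no forward solve is spent on
  them and they are never adopted.
* A restricted `tangential3` mode varies only the yaw and two
  scalp-tangential translations, re-seating the coil perpendicular to
  the skin after each move (the translations are parameterized in the
  coil plane at the current pose).
* **Defocalization** DF is the 13-term mean of AADₙ/AAD_final over the
  unperturbed pose (n = 0, ratio exactly 1) and the 12 single-variable
  perturbations ±1.5 mm / ±0.1 rad. Ratios are not clamped at 1; a raw
  mean slightly below 1 is reported as-is. Infeasible perturbations are
  skipped with a log line. A 12-term variant (dropping n = 0) is a
  config switch and changes DF by well under 1%.
* **Stability correction**: if DF ≥ 1.25 at the accepted solution, the
  trace is reverted one accepted update at a time (whole passes, via
  config) until DF < 1.25; an input on which no iterate qualifies
  raises rather than silently returning an unstable pose.
* The initial sulcus-aligned pose is lifted by the sub-millimetre amount
  occasionally needed when the faceted skin puts the measured clearance
  marginally below the hard constraint.
* The descent was adopted against an exhaustive grid-search oracle; the
  acceptance suite reproduces that check on a 245-pose grid (within 5%
  of the grid optimum, and never better than it on a superset grid).

## Metrics

AAD thresholds reference the field's *own* maximum at each pose,
recomputed during optimization (not frozen at the initial pose). ARD
field values average the 4 nearest observation nodes per target
(10-node variant by config); edge targets average over the neighbours
that exist. Peak deviation is the distance from target to the
*unweighted* centroid of nodes at/above the 99th magnitude percentile.
Field loss = 100·(‖E‖_initial/‖E‖_final − 1) at the target (negative =
gain). Batch summaries report mean and sample (n−1) STD per metric, a
two-sided paired t-test on ARD after vs before, and the map value
DF_cond·DF_coil·AAD with the conductivity-uncertainty factor
DF_cond = 1.05.

## Problem sizes and determinism

The batch pipeline uses skin/skull shells at 320 facets and CSF/GM/WM at
1280 (≈4.5k charge unknowns, one ~30 s assembly + factorization per
phantom, ~0.2 s per pose evaluation), six targets on the seed phantom
plus one
mid-crown target on four jittered phantoms — ten inverse runs in
roughly ten minutes on one CPU. All stages are deterministic given the
seed; pose evaluations are memoized on the rounded pose vector, so
repeated evaluations are bit-identical.

## Known limitations

* Piecewise-constant collocation BEM: relative error grows at deep
  interior points where the induced field is small, and closely spaced
  coarse shells (2.5 mm gaps under ~10 mm facets) degrade pointwise
  accuracy off the hot spot; pose *comparisons* are much less affected
  because the discretization error is strongly correlated across poses.
* The AAD landscape is piecewise constant in the suprathreshold node
  set; with desk-scale observation spacing (~4–5 mm) descent can stall
  one grid step from the continuum optimum. The acceptance tolerance on
  the exhaustive-search comparison reflects exactly this quantization.
* No white-matter anisotropy (a structural limitation of the
  surface-charge formulation), no FMM acceleration, no MRI-derived
  geometry, no multi-target joint optimization.
* The geodesic, field-weighted subthreshold cost alternative is named
  but not implemented.
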