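# Methods

`podomech` quantifies the 3D architecture of podosome actin networks from
traced filament coordinates and evaluates the elastic force model that
explains how a sub-micrometre actin core protrudes with nanonewton forces.
This note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The physical picture

A podosome is a dense core of short, steep, bent actin filaments (~200 nm
radius) standing on the basal membrane, surrounded by longer, flatter
*radial* filaments that connect it to an adhesion ring. Two candidate force
sources are evaluated against each other:

1. **Polymerization at the membrane** (Brownian ratchet). A filament growing
   perpendicular to the membrane stalls at

       f_a = (kBT / δ) ln(C / C_c),

   with δ = 2.75 nm the elongation per added monomer, C the monomer
   concentration and C_c the critical concentration. A filament inclined at
   θ to the membrane pushes with leverage 1/sin θ, so the membrane-proximal
   ("protrusive") portions — all points within 10 nm of the membrane —
   contribute in total

       F_polym = f_a Σ_i 1 / sin(θ_i).

   At C = 150 µM and C_c = 0.06 µM the stall force is 11.4 pN; at the
   typical C = 50 µM it is 9.8 pN. The conventional reporting value fixes
   ln(C/C_c) = 7, i.e. ~10 pN.

2. **Stored bending elasticity**. Filaments are semiflexible polymers with
   bending energy

       u = (κ/2) ∫ ‖∂t/∂s‖² ds,   κ ≈ 4×10⁻²⁶ N·m²,

   t(s) the unit tangent at arc length s. The total core energy U_core
   (sum over all joints with radial distance ≤ r_core) relaxes over the
   compression δh = ε_core·h_core, giving

       F_elastic = U_core / (ε_core · h_core),
       P = F_elastic / (π r_core²),
       Y = P / ε_core   (cross-checked against Y = Y_a φ², Y_a = 2.3 GPa),
       σ = F_elastic / (2π r_core sin θ_radial),

   where ε_core is the mean per-filament compressive strain
   1 − end-to-end/contour of core filaments, h_core the core height, φ the
   actin volume fraction of the core cylinder, and σ the tension the radial
   meshwork must carry to balance the elastic push.

On the default synthetic podosome the pipeline reports F_polym ≈ 0.45–0.5 nN
against F_elastic ≈ 60–80 nN: summed polymerization pushing cannot account
for nanonewton protrusion, stored network elasticity can. The
polymerization *energy* budget ((total core length/δ)·ln(C/C_c) ≈ 1.2–1.4
×10⁵ kBT) still exceeds the stored elastic energy (~9×10⁴ kBT), so
polymerization in the bulk can load the spring even though it cannot push
the membrane directly.

### The kBT discrepancy

The Methods-level constant list gives kBT = 4.11×10⁻²¹ J, but the printed
stall forces (11.4 pN at 150 µM, 9.8 pN at 50 µM) are reproduced only with
kBT ≈ 4.00×10⁻²¹ J (T ≈ 290 K); at 4.11×10⁻²¹ J they come out ~3% higher
(11.7 / 10.1 pN). Both constants are exposed; the library default is
4.11×10⁻²¹ J and the validation of those two printed values pins
4.00×10⁻²¹ J.

## Discrete geometry

- **Resampling.** Polylines are resampled by linear interpolation at uniform
  arc spacing a = 3 nm (every point then carries equal weight). The segment
  count is round(L/a), so the realized spacing is L/round(L/a); endpoints
  are retained exactly. Filaments with contour < 2a are excluded and
  counted. Spacing measured on chords equals a only for smooth curves —
  traced filaments are smooth at the 3 nm scale.
- **Tangents** are normalized forward chords (the last point inherits the
  final chord). On points sampled from a circle the angle between
  consecutive chords is exactly a/R, so curvature and bending energy are
  exact on arcs — the reason this scheme was chosen over splines or central
  differences.
- **Curvature** γ = arccos(t_i·t_{i+1})/a per interior joint, with the dot
  product clamped to [−1, 1] (near-parallel unit vectors can exceed 1 in
  floating point; the resulting curvature floor is ~5×10⁻⁹ nm⁻¹).
- **Joint energy.** The printed per-joint form (κ/2)γ² is an energy *per
  unit length*; each joint is therefore weighted by the arc length it
  represents so that joint energies sum to the continuum integral. Interior
  joints own half of each flanking segment (weight a); the first and last
  joints additionally absorb the terminal half-segments (weight 1.5a).
  Weights then always total the contour (n−1)a, which makes the discrete
  energy of a uniform-curvature arc exactly κL/(2R²) — without the end
  correction the plain interior-joint sum carries an O(a/L) deficit (~3% at
  L ≈ 111 nm) that would violate the 10⁻³ arc-oracle tolerance. Without the
  per-length weight altogether, per-filament energies are wrong by ~7
  orders of magnitude.
- **Strain** uses the raw polyline (resampling changes it by <1%).
  Orientation to the membrane is the unsigned θ = arcsin(|t·n̂|) ∈ [0°, 90°],
  matching how orientation statistics are reported.

## Radial profiles

Observables are binned by cylindrical distance from the core axis (the line
through the core centre along the membrane normal — the podosome is an
axial structure; spherical radii would be wrong beyond the core) in
contiguous 25 nm bins. Local observables (orientation, density, energy
density) average per point; non-local ones (length, strain) average per
filament weighted by the filament's point count in the bin. Densities
divide by annulus volume (area × slab height, default 400 nm); only in/out
ratios are interpreted, and those are slab-independent. Empty bins are NaN,
never zero, so they cannot drag fits down.

**Core centre.** The in-plane mode of a Gaussian-smoothed point density,
tie-broken by the centroid, user-overridable. The default bandwidth is
150 nm — of the order of the core radius. A much narrower kernel (e.g.
50 nm) reliably locks onto single steep filaments, which project as dense
vertical columns, and misses the true centre by 50–110 nm; at 150 nm the
flat-topped core disc convolves into a single peak and errors stay ≤ 30 nm.

## Fits

**Core radius.** All profiles except strain are fitted with the
four-parameter transition

    m(r) = ½[(a + b) + (b − a) tanh((r − r0)/rs)],

and r0 of the *orientation* fit defines r_core (density, length and energy
fits are reported as cross-checks). Numerical choices:

- bins are weighted by point count (a bin mean's variance is 1/count);
  with equal weights the fit is captured by near-empty far-tail bins and
  r0 runs to the domain edge. Unweighted fitting remains available.
- values are normalized by their maximum before optimisation (energy
  densities are ~10⁻²³ in J/nm³; plateau parameters must be O(1) for the
  optimizer).
- bounds keep the plateaus within the data range ± one range, r0 inside
  the profiled domain and rs between a tenth of a bin and the domain span;
  initialisation is data-driven (inner/outer-third plateaus, steepest
  smoothed slope among well-populated bins) with a five-point multistart of
  r0 across the domain interior. A fit whose r0 pins to the domain edge is
  flagged as a failure, never silently replaced.
- a constant profile is flagged unidentifiable.

The orientation estimator carries a systematic outward bias of ~+8%
(filaments are extended objects and the denser core pushes the mixed
orientation crossing outward of the placement boundary); the per-podosome
scatter is ~±7%. Core-radius statements are therefore made on means over
several podosomes, matching how the measured mean (203 ± 38 nm over ten
podosomes) is reported. The density/length cross-check fits can addition-
ally be captured by the outer extinction tail of the observation domain,
where the tanh model is misspecified; they are reported but not used.

**Correlation length.** C(ds) = ⟨t(s)·t(s+ds)⟩ over all same-filament pairs,
pooled across filaments; region membership (core vs outside) requires both
points of a pair inside (resp. outside) r_core, so boundary-straddling
pairs are excluded. Lags with at most half the lag-0 pair count are
discarded (statistical power); the shortest lag is always kept. The fit of
exp(−ds/lc) is in linear space (log space is undefined for the near-zero or
negative C reached at long lags); if all retained C ≥ 0.999 the ensemble is
effectively straight and lc = ∞ is flagged instead of a number. Fitting is
per network, with pooling available by passing several networks' tracks.

## The synthetic generator

The generator emulates the *measured statistics* of podosome networks so
every downstream stage is testable without tomograms:

- **Worm-like chains.** Each step rotates the tangent by a Gaussian angle of
  variance 2·step/lc about a uniformly random transverse axis; since
  ⟨cos α⟩ = exp(−σ²/2) for Gaussian α, the ensemble tangent correlation is
  exactly exp(−ds/lc) per construction. lc = 1.68 µm (core) / 2.41 µm
  (surround), both far below the thermal persistence length κ/kBT ≈ 10 µm —
  the generated filaments are "actively deformed" by construction. A
  111 nm chain at lc = 1.68 µm has mean strain ≈ L/(6 lc) ≈ 0.011, the
  right order for the measured 1.6% core compression.
- **Placement.** 300 core filaments start uniformly over the 200 nm core
  disc (the in-plane distribution is not constrained by any measurement;
  uniform is the explicit config choice), 850 radial filaments uniformly
  per unit area over the 200–600 nm annulus pointing ±radially, both at
  truncated-normal elevations (47 ± 22° / 23 ± 21° on [0°, 90°]) and
  truncated-normal lengths (111 ± 46 / 166 ± 120 nm, floor 2 steps).
  Sample-mean tests compare against the analytic truncated-normal means.
- **Density contrast.** The radial count of 850 was calibrated once so the
  measured core/surround point-density contrast is ~3.0 (seeds 1–6:
  2.8–3.2), the top of the measured 2–3× band, which puts the energy-
  density contrast at 3.5–4.1, inside the reported 3–10 bracket. (A count
  of ~1020 realizes a 2.5× contrast and is used in one profile test.)
- **Protrusive subpopulation.** 45 filaments planted inside the
  membrane-proximal layer (start z < 7 nm, ascending, 61 ± 6°). The layer
  (z < 10 nm) is *reserved* to this class: core/radial chains are floored
  at z = 10 nm, so the configured count is recoverable ground truth rather
  than being confounded by passing core filaments.
- **Non-penetration.** Chains that would cross their floor are first
  flipped upward (mean-path check) and otherwise redrawn (up to 30×); the
  ensemble is thus a WLC conditioned on staying above the floor. Specular
  reflection — the obvious alternative — is only a last resort because a
  fold at 3 nm spacing injects ~4×10³ kBT of spurious bending energy per
  event, which would corrupt the core energy budget.

What the generator does **not** emulate: excluded volume, crosslinkers and
branch points (named but unquantified elastic contributions), filament
polarity, polymerization kinetics, segmentation noise (broken/merged
traces), and the missing-wedge anisotropy of tomographic reconstruction.
Passing tests therefore show that the *pipeline* recovers what it assumes
from data that satisfy those assumptions — not that real segmentations do.

## Mechanics conventions

- U_core sums joint energies with radial distance ≤ r_core; ε_core averages
  strain over filaments with the majority of their resampled points inside
  r_core (point-count weighting mirrors the non-local profile rule);
  h_core is the 2.5–97.5 percentile extent of core point heights above the
  membrane (robust to stray outliers; how the height was measured is not
  otherwise defined).
- Protrusive portions are the maximal run of consecutive points within
  [0, 10] nm of the membrane, ≥ 2 points, one portion per filament; θ_i is
  the portion's mean point orientation. Portions flatter than 1° are
  excluded from the 1/sin θ sum with a warning (the leverage diverges;
  observed angles are ~61 ± 6°).
- Pressure uncertainty is first-order propagation,
  ΔP = (2F/πr³)Δr + ΔF/(πr²).
- All unit conversions (J↔kBT, N↔pN/nN, Pa↔kPa/MPa, N/m↔mN/m, nm↔µm↔m) go
  through one module; the computation spans ~12 orders of magnitude and
  unit slip is its dominant failure mode.

## Problem sizes

The analysis scripts and test suite run four synthetic podosomes of ~1200
filaments (~60 000 resampled points) each, 500-filament ensembles for
correlation-length recovery at lc ∈ {1.68, 2.41, 10} µm, and 100-replicate
noise studies for the transition fit — sizes at which every recovery
contract in the tests holds with margin while a full run stays in seconds.

## Known limitations

- The elastic force is an order-of-magnitude estimate by construction: it
  assumes all stored bending energy is releasable, ignores crosslinker and
  non-bending elastic storage, and inherits the ±8% core-radius bias
  quadratically in the pressure.
- The Amira spatial-graph importer is best-effort: the exporting dialect is
  not fully public; VERTEX/EDGE/POINT sections are parsed, unknown sections
  are skipped with a warning, and coordinates are scaled by a user-supplied
  voxel size.
- Whether the per-podosome Young's modulus should average Y over podosomes
  or divide averaged P by averaged ε is ambiguous in the source reporting
  (13.2 vs 12.7 MPa); the per-podosome report computes Y = P/ε_core per
  network and leaves aggregation to the caller.
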