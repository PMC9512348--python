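# Methods

## Scope and model overview

`fifplan` models the forward-planning half of rectal 3DCRT: given tumor
volumes and bony landmarks, it constructs field apertures from clinical
border rules, computes dose with a simplified photon model, and iteratively
homogenizes the plan with wedges, beam-weight optimization and
field-in-field (FIF) blocking subfields. Everything runs on synthetic
voxel phantoms; no imaging, segmentation or machine data is required.

Coordinates are fixed throughout: x = patient-left, y = patient-anterior,
z = patient-superior, millimetres. Beams are coplanar and isocentric with
SAD 1000 mm; gantry 0° is anterior, 90° patient-left, 180° posterior,
270° patient-right. The beam's-eye-view (BEV) frame on the isocentric
plane has BEV-y along patient z for every coplanar beam and BEV-x
completing the right-handed frame; divergent projection scales a point at
source distance d by SAD/d.

## The synthetic pelvis phantom

The phantom is an elliptic cylinder of unit-density soft tissue
(half-width 170 mm, half-thickness 125 mm, 240 mm scanned length, 2.5 mm
isotropic voxels by default) containing:

* a **sacrum** — a posterior midline slab (half-width 55 mm, posterior face
  at y = −85) whose anterior face slopes forward to the promontory at the
  L5/S1 level (z = +85);
* two **iliac wings** — large lateral bone plates flanking the pelvis;
* a spherical presacral **GTV** (radius 22 mm, just anterior to the
  sacrum) and a nodal **GTVn** (radius 14 mm) on the posterior pelvic
  sidewall;
* optional seeded **bowel-gas pockets** (ellipsoids of zero density) in
  the anterior abdomen, off by default.

Bone is modelled as a 2 mm cortical shell (1.8 g/cm³ analog) over a
trabecular interior of 1.08 g/cm³, typical of the elderly, often
osteopenic rectal-cancer population; this gives beams realistic
water-equivalent excess along bony paths (≈ 1–1.5 cm per crossing) rather
than the several-centimetre shadows a solid-cortical model would cast.
Landmarks (L5/S1 junction, obturator foramen bottom, pelvic brim at the
inlet half-width of 68 mm, sacral extents) are analytic parameters of the
spec, not image-derived — the border rules can therefore be tested
exactly. Identical specs (including the seed, which only drives gas
pockets) produce bit-identical phantoms.

The geometry was designed so the default plan reproduces the dose
topology the clinical workflow is built around: with 2:1:1 weights and
60° wedges the plan shows a posterior/posterolateral hotspot
(hotspot dose percentage ≈ 113%, V107 ≈ 27% of pROI) that lateral
subfields can reach, a flat interior near 100–104%, and mild lateral-edge
structure from opposed-lateral entrance dose. What the phantom does *not*
model: sagittal asymmetry of real patients, skin irregularity, femoral
heads, bladder/bowel filling, CT calibration. Passing tests therefore
demonstrate the algorithmic contracts (border rules, ROI algebra,
optimizer behaviour, loop termination and monotonicity) on an idealized
but anatomically plausible pelvis — not dosimetric accuracy on real CTs.

## Mask morphology

Uniform expansions (3 cm GTV, 2 cm GTVn for primary fields; 2 cm for
boost) and erosions (1 cm RHD→pROI) are Euclidean, implemented with exact
distance transforms on the voxel grid, so "expand by m" means precisely
the set of voxel centres within m of the input. Expansion/erosion are
dual and monotone; both properties are asserted in the suite against a
brute-force pairwise-distance oracle.

## Dose engine

The engine is a deliberately small surrogate for a TPS dose calculation.
Per beam, the dose per unit weight at voxel i is

    B(i) = PDD(d_i) · (SAD / s_i)² · T(i) · W(i)

* `PDD` — linear build-up to d_max = 25 mm, then exp(−μ_eff (d − d_max))
  with μ_eff = 0.027 /cm, the ~2.7 %/cm depth-dose falloff of a 15 MV
  beam past build-up. `d_i` is the radiological depth: cumulative density
  along the beam direction, computed with parallel rays along the
  (cardinal) gantry axis — divergence is retained in the inverse-square
  term and in aperture projection, where it matters for geometry, and
  neglected only in the depth integral, where its effect over a 40 cm
  field at SAD 1000 is sub-millimetre.
* `T` — transmission sampled from an isoplane map: 1 in the MLC opening,
  2% under leaves inside the jaws, 0 outside the jaws, blurred with a
  3 mm Gaussian standing in for penumbra.
* `W` — wedge factor, linear in BEV-x and 1 on the axis:
  `W = clip(1 − g·heel·x, 0.2)`, with slope g = μ_eff·tan(wedge angle) so
  the mid-depth isodose tilts by the nominal angle under the same PDD
  model. Lateral wedges default to heel-posterior (thick end reducing
  the posterior dose), and mirroring a beam mirrors the heel.

Per-beam dose is exactly linear in beam weight; the plan dose is
`D(i) = Σ_j α_j B_ij`. Only cardinal gantry angles (0/90/180/270°) are
supported by the depth model — the workflow uses nothing else.

Limitations by construction: no scatter kernels, no electron
contamination, no heterogeneity correction beyond radiological depth, no
tongue-and-groove. The engine preserves exactly the features the FIF
algorithm exploits: depth falloff, divergence, bone attenuation, MLC
blocking, wedge tilt, linear weight response.

## Planning ROI algebra

With fitted primary beams, the region of high dose (RHD) is the geometric
intersection of the in-field frustums (a voxel is in-field iff its
divergent projection lies inside the beam's MLC opening) with the body.
The pROI — the PTV surrogate used for normalization and coverage — is the
RHD eroded 1 cm. LTRT (flanks) is the lateral-overlap region minus the
1 cm-expanded RHD; APPA (anterior) is the PA (or AP∩PA) region minus the
same expansion; in 3-field geometry only the PA beam forms APPA. The
geometric (not dose-threshold) reading of "overlap" is used because the
RHD must exist before any dose has been normalized.

## Normalization and weight optimization

Normalization rescales all voxels by Rx/D_p (volume mode: D_p is the dose
covering q% of an ROI, computed by descending sort with
k = ⌈q·n/100⌉; point mode: trilinear sample). Default: Rx covers 99% of
the pROI; the boost normalizes to 98% of the boost volume. The operation
is idempotent and its coverage post-condition is exact up to voxel
quantization.

The weight objective is a sum of one-sided quadratics per ROI:
targets (pROI, ω = 1) below Rx; LTRT/APPA (ω = 0.5) above 0.9·Rx; RHD
(ω = 1) above the hotspot level (107% of Rx). The ω values and the OAR
tolerance are package defaults — chosen so coverage dominates, flank dose
is a soft constraint, and the RHD term ties the optimizer to the FIF
goal. Voxels are subsampled deterministically (every k-th ROI voxel in
scan order, 10% by default); tests evaluate at full sampling. The
objective is convex (one-sided quadratics of affine functions) with an
analytic gradient; it is minimized by a named solver from a registry
(L-BFGS-B default; TNC, SLSQP, Powell registered) under per-beam bounds
min MU/total MU ≤ α_j ≤ max MU/total MU (primaries 5–100 of 100 total;
subfields 1–30). The normalization factor is held fixed during a solve
and refreshed immediately afterwards. A failed or non-improving solve
returns the initial weights with a failure flag and the loop proceeds.

Initial weights are 2:1:1 for PA:LT:RT (4-field adds AP at ratio 1),
normalized to sum to one. Subfields enter at their minimum MU fraction
and are free variables in every subsequent solve.

## Hotspot analysis and subfield construction

A hotspot is a fully connected component of {D > p%·Rx} with volume
≥ 8 cm³; connectivity defaults to 26 (face+edge+corner) because clinical
hotspot clouds are visually contiguous, and is configurable to 6. The
*hotspot dose percentage* — the headline homogeneity measure — is the
supremum of thresholds at which such a component still exists, found by
bisection to 0.1% resolution; equivalently, the dose percentage of the
hottest connected 8 cm³.

To build a subfield, the (largest-only by default) hotspot mask is
truncated distal to the isocentric plane (protecting the far side from
over-blocking), ray-trace projected into the parent lateral's BEV using
conservative voxel footprints (per-voxel corner projection; for cardinal
beams the footprint equals the exact convex hull), and each disconnected
2D object is covered by extending the nearer MLC bank across it. The
subfield aperture is the parent opening minus that single blocking shape;
it inherits the parent's gantry, isocenter and jaws, carries no wedge
(its purpose is local blocking), and starts at the minimum MU fraction.
A projected hotspot that misses the parent opening, or whose blocking
would close every leaf pair, yields a no-op and the loop falls back to a
weights-only step.

## The FIF loop

Each pass: renormalize → measure the hotspot dose percentage → if at or
below target, stop (condition 1). Otherwise optimize weights (reverting
them if the renormalized hotspot worsened — the revert-on-worsening
mechanism is this package's operationalization of the monotone-acceptance
requirement), re-check, and if still hot add one subfield on the next
side of the LT/RT alternation (LT first). If the post-subfield,
re-optimized, renormalized hotspot percentage exceeds its pre-subfield
value, the subfield is removed (condition 3) — the loop then stops, or,
if stall relaxation is enabled, raises the target by 1% and continues.
The subfield budget (default 6) gives condition 2. Exactly one subfield
is added per accepted iteration; the history records every pass, and
across accepted records the hotspot percentage is non-increasing by
construction.

Boost planning reuses the machinery without FIF: two opposed lateral
boost beams with 15° wedges, normalized so 5.4 Gy covers 98% of the boost
volume (the boost-frustum overlap eroded 1 cm, intersected with the
pROI; erosion before intersection, following the order in which the
volumes are constructed).

## Numerical choices and degenerate inputs

* Aperture rasterization at 2 mm isoplane pixels on a 400×400 mm grid;
  MLC is a 120-leaf Millennium layout (forty 5 mm central pairs, twenty
  10 mm peripheral pairs).
* MLC fitting has two modes: *cover* (out-field; opening ⊇ aperture,
  ≤ 1 leaf width excess per edge row) for treatment fields, *within*
  (in-field; opening ⊆ aperture, largest contiguous run per pair) for
  blocking shapes. Empty apertures close all pairs at the midline.
* Hotspot-percent comparisons in the loop use the 0.1% bisection
  resolution; "worse" means strictly greater.
* Erosion that empties a mask warns and returns an empty mask (not an
  exception); normalization on a zero dose raises, and the loop surfaces
  it with the failing ROI named.
* Tie-break: when both border-rule candidates are equal the
  landmark-derived provenance is reported.

## Known limitations

The dose surrogate is not commissioned physics; absolute doses are analog
units scaled by normalization, and plan quality statements transfer to
real TPS calculations only qualitatively. Aperture rules implement one
institution's guideline with fixed default margins ("~2 cm from the
pelvic brim" is taken as exactly 20 mm, configurable). Subfields are
restricted to the lateral fields, as in the experimental configuration
modelled; AP subfields and non-coplanar beams are out of scope. The
boost stage adds no subfields. Corner blocks apply to the PA field only;
whether they should persist when tumor-derived borders fire is a clinical
judgement left to configuration.
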