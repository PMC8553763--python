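# Methods

## Measurement model

The pipeline treats a tooth volume as a three-tissue scene (enamel > dentin
> pulp-space lumen ≈ background in X-ray attenuation) and derives all
morphology from the segmented canal lumen:

* **Tissue segmentation.** 3-class multi-level Otsu on the (lightly
  presmoothed, σ = 0.5 voxel) histogram of the cropped volume; manual
  thresholds can be supplied when a histogram lacks three modes.  The tooth
  is the largest 6-connected mineralised component.  The lumen is recovered
  *geometrically*, not by intensity alone: per-axial-slice hole filling of
  the tooth cross-section marks the enclosed cavity, which keeps the canal
  separate from exterior background even though foramina connect the two and
  they share an intensity class.  Cavity specks below 60 voxels are treated
  as noise.  Openings are found afterwards as lumen–exterior contact
  components, so the physiological/accessory partition covers every exit
  exactly once.
* **Landmarks.** CEJ = most apical slice containing enamel (supplied by
  config for decoronated teeth); apex = most apical dentin voxel; DEJ = most
  apical enamel–dentin contact.  Root thirds divide [CEJ, apex] into three
  equal spans, per root for two-rooted teeth (each root from the CEJ to its
  own apex).  Thirds are measured along the slice axis; phantoms are
  generated axis-aligned, where this coincides with the anatomical root
  axis.  Tilted real scans should be reoriented before analysis — a
  limitation, recorded in the per-tooth report via the axis-convention
  field.
* **Canal graph.** The lumen is thinned to a curve skeleton (3D thinning),
  converted to a graph whose edges carry their centerline voxels, lengths
  and radii (Euclidean distance transform; per-edge caliber is the *median*
  over the interior of the chain, because junction-adjacent values are
  inflated by the adjoining canal).  Medial-axis thinning retracts endpoints
  by roughly one local radius, so exterior openings are attached as explicit
  exit nodes at the centroid of each lumen–exterior contact component.
  Spurious leaf branches are pruned when shorter than
  max(0.1 mm, 2 × local radius) unless they lead to an exit.
* **Edge roles.** Main edges are those on a chamber→physiological-foramen
  route through the wide subgraph (caliber ≥ 0.9 × the 0.2 mm canal
  threshold, plus the terminal segments of physiological exits).  Terminal
  branches to sub-threshold openings are accessory; thin edges with both
  attachments on the main system are connecting canals — loop-type (L) when
  the in-main path between the attachments crosses no main junction,
  communicating (C) otherwise.  RCC digits are read at the coronal-limit
  plane of each third as the number of 2D (8-connectivity) lumen components
  containing a main-edge centerline voxel; this excludes components
  attributable to accessory or connecting canals and blind diverticula, and
  equals the plain flood-fill count whenever no such feature crosses the
  plane.
* **Foramen metrology.** For each exit, cross-sections are sampled along the
  smoothed terminal centerline, normal to the local tangent (so oblique
  exits are not overestimated), as sub-voxel contours at the iso-level
  midway between the lumen and dentin intensity means.  The constriction is
  the minimal-area section, searched coarse-to-fine with a 3-tap smoothed
  area profile and excluding sections within 2.6 voxels of the surface
  (contours there are distorted by the exit flare meeting the root surface).
  W/N are the exact max/min Feret diameters of the contour's convex hull;
  D is the Euclidean distance from the constriction centroid to the
  lumen–exterior contact centroid.  A monotonically flaring exit yields
  D = 0 with a flag.
* **Classification.** Physiological iff W ≥ 0.2 mm — the threshold is
  applied to the wide diameter, because reported narrow diameters of
  physiological foramina go well below 0.2 mm, so the criterion cannot act
  on N.  Shape: irregular when the relative RMS deviation of the contour
  from its best-fit ellipse exceeds 8 % ("more than two different
  diameters", operationalised; configurable); else oval iff W − N ≥ 0.02 mm;
  else round.

Key tunables (all in `PipelineConfig`, echoed into every report):
foramen threshold 0.2 mm, oval difference 0.02 mm, irregularity residual
0.08, apical window 3.5 mm, prune length 0.1 mm, main-canal caliber 0.2 mm.

## Phantom generator

Phantoms realise a specified RCC code per root exactly: the canal count
profile changes by smooth-stepped splits/merges centred by default at the
midpoint of the third in which the digit transition occurs, so the count at
each third's coronal limit equals the digit.  Each physiological foramen
ends in an elliptic constriction with specified axes (W, N) and orientation,
placed D above the anatomical opening (D quantised to the voxel grid; the
ground truth records the realised value), flaring at 0.30 mm/mm towards the
surface; the feeding canal is kept wider than any constriction so the
minimal cross-section is the constriction.  Accessory canals are thin
(< 0.2 mm) channels from a main canal to the root surface within a chosen
third; connecting canals are 0.12 mm channels that loop back to the same
canal (L) or bridge two canals (C).  Two-rooted phantoms bifurcate the
dentin envelope and the canal territories inside the middle or apical third
only.  Tissue intensities are background 0, lumen 0 (the extracted-tooth
pulp space is radiolucent), dentin 120, enamel 220, with partial-volume
(coverage) shading at edges and additive Gaussian noise (default SD 8, i.e.
about 7 % of the dentin–lumen contrast; micro-CT of extracted teeth is
low-noise).  Identical spec + seed gives bitwise-identical volumes; cohort
generation jitters only continuous nuisance geometry (root length,
curvature, ellipse orientation, exit-layout rotation), never the discrete
structure.

What the phantoms do **not** emulate: reconstruction artifacts (beam
hardening, rings), cementum and periodontal tissues, root curvature beyond
a mild bow, oblique tooth orientation, isthmuses/fins, and resorption or
caries.  Passing the validation suite therefore demonstrates that the
measurement chain is correct under the stated image model, not that it is
robust to every artifact of real scanners.

## Validation cohorts and problem sizes

The reference cohort realises the published 101-tooth mandibular-canine
composition: 98 single-rooted teeth over nine RCC codes (modal `1-1-1/1`
n = 73), shapes among the 79 one-foramen teeth 72 oval / 6 round /
1 irregular, 13 single-rooted teeth with exactly one accessory canal
(7 middle, 6 apical thirds), one loop-type and one communicating connecting
canal, and 3 two-rooted teeth (one with a buccal middle-third accessory
canal).  The metrology cohort draws W, N, D for 79 one-foramen phantoms
from truncated normals matching the published one-foramen statistics,
coupling W and N comonotonically — anatomically, large foramina are large in
both axes; as a consequence every draw satisfies N < W and is oval, matching
the reference shape distribution.  The discrepancy in the source tables
between accessory-*foramina*-per-tooth counts and accessory-*canal*
locations is resolved in favour of the canal-location counts (the quantity
the pipeline measures); the published overall constriction-to-opening
distance that conflicts with the per-stratum table is likewise resolved in
favour of the per-stratum values.

Phantom sizes are a package choice: validation cohorts use 6.6 mm roots
with 1.8 mm crowns and slim envelopes at the default 0.02 mm voxels
(threshold features stay ≥ 5 voxels), which keeps a 180-phantom validation
run at a few minutes on one CPU.  Generator defaults for standalone use are
anatomically fuller (16 mm root, 11 mm crown); all geometry is configurable
and every measured quantity is scale-free or set directly by the spec.
The acceptance script's threshold sweeps (t6, t7) apply the classification
rules to exactly constructed diameters, because they probe the rule
boundary ("≥" vs ">"), which voxel-measurement error at the boundary would
otherwise obscure; measurement accuracy is validated separately by the
metrology cohort.

## Numerical choices and edge cases

* Percentages print half-up to one decimal, lengths to two decimals
  (`round_half_up`, not banker's rounding), matching tabulation conventions
  in the field.  Table denominators: RCC and foramen-count tables use the
  root-group size, accessory locations the whole cohort; single-rooted
  connecting-canal "none" uses the single-rooted count.  Denominators are
  recorded in the table metadata.
* The MAF (master apical file) recommendation is a pluggable policy: the
  default reproduces the published per-stratum pairs (1 foramen → 45/50,
  2 → 40/45, 3 and 4 → 40) and is flagged HEURISTIC because no closed rule
  derives them (a mean W of 0.32 mm maps to size 40, which contradicts any
  simple ceiling rule); an `iso-ceiling` policy (smallest ISO size strictly
  greater than mean W) is provided as the documented alternative.
* Degenerate inputs: empty lumen → `0-0-0/0` flagged "no canal"; missing
  enamel → CEJ must be supplied; three or more roots → unsupported-anatomy
  error; all-background volume → explicit error; per-tooth failures in a
  batch are isolated and logged.
* Ties at digit planes resolve by 2D 8-connectivity; a split is counted in a
  digit only if still separate at the third's coronal limit.

## Known limitations

* Thirds and digit planes follow the slice axis; strongly tilted or curved
  roots need reorientation (the principal-axis alternative is logged as an
  open design seam rather than silently applied).
* L/C typing assumes connecting canals are thin relative to main canals
  (caliber rule); a connecting canal at main-canal caliber would be read as
  a canal limb — at the digit planes this matches how a cross-section reader
  would count it.
* Accessory opening diameters are estimated from the exit contact-component
  area, which overestimates slightly on oblique surface exits; the value is
  used against a 0.2 mm threshold with ample margin for the modelled
  0.06–0.19 mm range.
* Two-rooted root-territory assignment uses the perpendicular bisector of
  the root centroids below the bifurcation; buccal/lingual labels follow the
  second grid axis, i.e. they rely on consistent specimen orientation.
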