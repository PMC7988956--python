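# Methods

This note documents the models implemented in `carposhape`, the assumptions
behind them, the defaults that matter, and the numerical choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pipeline overview

Per-specimen inputs are a calibrated density volume (isotropic voxels, HU
with a linear HU→vBMD calibration, or vBMD directly), a closed triangulated
surface mesh in millimetres, and a landmark file (named homologous points,
ordered segment polylines, region boundary loops). Processing order:

1. **Imaging preprocessing** — HU < 0 clamped to 0 (non-osseous tissue),
   left-side specimens mirrored across the sagittal mid-plane (triangle
   winding re-flipped to keep outward normals), linear vBMD calibration,
   threshold segmentation of the largest connected component to a closed
   mesh (marching cubes), automated closing of nutrient foramina
   (morphological closing of the voxelized solid; channels wider than the
   configured diameter are reported, never silently removed).
2. **Correspondence** — segment landmarks resampled to equal counts at equal
   arc-length spacing; a reference specimen (minimal summed Procrustes
   distance of its landmark set to all others) TPS-warped to every specimen
   on the full landmark set; warped vertices attached by nearest-point
   projection; labels shared through the common triangulation.
3. **Statistical surface model** — non-scaling generalized Procrustes
   (translation + rotation only, det(R) = +1 enforced), PCA of the aligned
   vertex coordinates, ±k·SD shape synthesis, morphometrics.
4. **Averaged density model** — isotropic reference grid inside the mean
   shape; per specimen a TPS from mean-shape surface points (plus interior
   control layers, below) carries every inside node into the specimen, where
   the volume is sampled trilinearly; node-wise averaging over specimens;
   concentric zone segmentation and statistics.
5. **Virtual probing** — disk-averaged vBMD profiles along an entry→exit
   cylinder (default diameter 3 mm).

All stages share one right-handed millimetre frame; voxel (i, j, k) sits at
`origin + voxel_size·(i, j, k)` with array axes matching world x, y, z.

## The phantom family

Real HR-pQCT collections of cadaver wrists cannot be redistributed, so the
test substrate is an analytic phantom: a two-lobed solid of revolution
(quarter-ellipse pole caps blended through cos²-shaped necks into a circular
waist), flattened on the dorsal side by capping y at `dorsal_width / 2`, and
bent progressively about the waist. Generative parameters (all independent
in the population model):

| parameter | default | SD (population) | unit | role |
|---|---|---|---|---|
| length | 27.0 | 2.5 | mm | long-axis extent before bending |
| proximal_radius | 6.5 | 0.5 | mm | proximal lobe radius |
| distal_radius | 7.5 | 0.5 | mm | distal lobe radius |
| waist_radius | 5.2 | 0.35 | mm | minimal neck radius |
| waist_axial_position | 0.5 | 0.04 | — | waist location as fraction of length |
| dorsal_width | 6.5 | 0.8 | mm | dorsal flattening cap (2·half-height) |
| bend_angle | 20 | 4 | ° | bend about the waist, toward dorsal |

The size defaults are set to the adult scaphoid's reported population
morphometry — mean length ≈ 27 mm, waist orthogonal diameters ≈ 10–11 mm,
total surface ≈ 1050–1150 mm², bone volume ≈ 2.4 cm³ — so that zone
geometry (shell thickness relative to core size) is anatomically plausible.
The default mesh resolution (`n_subdiv=16` → 2,050 vertices) is the
package's working scale; any vertex budget is available via
`n_rings`/`ring_size` (e.g. 641 × 78 gives exactly 50,000 vertices and
99,996 triangles, the closed genus-zero identity T = 2V − 4).

Landmarks are placed through the exact surface map: pole tips, four waist
compass points, eight region-margin points, four longitudinal crest
segments, and boundary loops for the five surface regions (four articular
cartilage facets — radius, lunate, capitate, trapezium/trapezoid — and the
dorsal rough strip). Region labels are assigned per triangle in the
(axial-fraction, angle) parameter plane.

Density volumes carry three concentric zones by exact depth below the mesh
surface: peripheral (depth ≤ 1 mm, mean 549.4 mg HA/cm³), intermediate
shell (1–3 mm; subregion means medial 376.2, proximal 379.0, distal 346.5,
lateral 389.1) and centre (depth ≥ 3 mm, mean 225.6), plus additive
Gaussian noise (default SD 60 mg HA/cm³, clamped at 0; set 0 for exact
recovery experiments). Zone means are population values for the scaphoid's
cortical/subchondral shell, trabecular mantle, and low-density core. Default
voxel size is 0.3 mm (0.082 mm, the HR-pQCT working resolution, remains a
config option but is not needed at desk scale).

What the phantoms do **not** emulate: trabecular microarchitecture, cortical
porosity, vascular foramina (except as drilled test channels), within-zone
density gradients, scanner beam-hardening or noise correlation, and real
anatomical asymmetries. Passing recovery tests therefore demonstrates
correctness of the geometry/statistics machinery, not clinical validity on
real scans.

## Numerical choices

* **TPS**: 3D kernel U(r) = r; block system solved densely; λ = 0 (pure
  interpolation) by default, λ > 0 exposed for noisy landmarks. Coplanar or
  duplicated controls are rejected with conditioning diagnostics. Control
  counts used here (hundreds to ~3,000) keep the dense solve well under a
  second.
* **Inside test**: scanline parity on regular grids — per (y, z) column one
  +x ray, crossings accumulated per column. Columns are jittered by a
  deterministic sub-nanometre irrational offset so rays never strike mesh
  edges exactly; nodes exactly on a face are a measure-zero half-open
  convention.
* **Closest point on surface**: KD-tree over triangle centroids proposes 32
  candidates; the exact point–triangle distance is minimized over them.
* **GPA**: initial reference is the raw average of the centred shapes (so an
  already-aligned set is a fixed point and re-alignment is the identity),
  falling back to the first shape if orientations cancel; tolerance 1e-7 mm
  RMS on the mean, max 100 iterations; rotations via SVD with the
  reflection branch excluded — chirality is never mirrored.
* **PCA**: SVD of the centred (N × 3V) matrix; covariance divisor N − 1;
  modes below 1e-10 of the leading singular value are dropped. Sign
  convention: the positive direction of each mode extends the mean along its
  long axis (axial position-weighted projection; second axis if ~0).
* **Morphometrics**: long axis = first principal axis of the vertex cloud;
  waist = minimal-area cross-section over 100 stations spanning the central
  60% of the length (sections measured on the convex hull of the plane
  intersection; diameters = maximal in-plane extent and its perpendicular
  extent, returned ascending). For shapes with no interior necking the
  minimum sits at the scan-band edge by construction. Dorsal width = mean
  cross-sectional chord of the dorsal-labelled strip over 20 axial bins.
  The mean model's descriptors and the mean of per-specimen descriptors are
  computed by distinct code paths and generally differ.
* **Averaged model**: TPS controls are a uniform subsample of 800 homologous
  surface vertices *plus matched control layers at 1, 2, 3 and 4 mm inward
  normal offsets* (smoothed vertex normals; offset pairs that collide with
  the opposite surface, e.g. across a thin waist, are dropped). A
  surface-only TPS scales interior depths with specimen size and smears
  fixed-millimetre structures such as the cortical shell; the offset layers
  pin absolute depth. Before sampling, each specimen volume is extended into
  the background by nearest-inside values so that trilinear samples just
  inside the surface are not diluted by background zeros (a partial-volume
  artefact). Both refinements are switchable (`control_layers=()`,
  `extend_background=False`).
* **Zones**: node depth is the exact distance to the mean surface. Depth
  bands default to 1 mm / 3 mm. Subregions: outer axial thirds along the
  oriented long axis are the proximal/distal-pole subregions; the middle
  third splits into medial/lateral halves by the angle about the axis,
  measured from the +z-anchored reference direction. The generator and the
  segmentation share one axis-orientation convention (long axis toward +x)
  so recovery experiments compare like with like; on real data the oriented
  axis should be supplied from anatomical landmarks.
* **Probing**: stations equally spaced; per station an equal-area polar disk
  pattern (3 rings at √-spaced radii × 8 spokes) is sampled trilinearly and
  averaged — equal-area spacing makes the plain mean an unbiased disk
  average. Samples outside the volume (or outside the averaged model's
  interior) are NaN and excluded; `mode="line"` gives centre-line sampling.
* **Degenerate inputs**: identical training shapes yield a flagged
  degenerate PCA (zero variance, no modes) rather than an error; empty
  zones become empty table rows; pathways fully outside the field are
  rejected; segmentation thresholds above the global maximum raise with
  diagnostics.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's working desk scale: phantom meshes at 2,050
vertices (recovery experiments) and 800–1,200 vertices (unit tests);
populations of 40–43 specimens for the form-model studies, 10 noise-free
specimens at 0.3 mm voxels and 0.3 mm grid spacing for the averaged-density
study; probe profiles at 100 stations. The synthetic studies' variance
structure is dominated by the length mode, so the first variance fraction
of a default population (~70%) is a property of the phantom family, not a
claim about real anatomical variation.

## Known limitations

* Nearest-point projection after TPS warping assumes the warp lands close
  to the target surface; grossly mis-landmarked specimens are flagged by
  the projection residual, not repaired.
* Zone-mean recovery is limited by trilinear partial-volume mixing at zone
  boundaries (one voxel wide) and residual warp error; at 0.3 mm voxels the
  centre-zone mean is biased upward by a few percent. Finer voxels shrink
  this proportionally.
* The medial/lateral subregion split needs an oriented axis; the default
  +x / +z convention is only meaningful for data in the package's canonical
  frame.
* Cross-section areas use the convex hull of the section, exact for convex
  sections (all phantoms) and an overestimate for strongly concave ones.
* `close_foramina` re-meshes through a voxel grid: output vertex count and
  sharp-feature fidelity depend on the chosen pitch.
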