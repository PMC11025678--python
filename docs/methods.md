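# Methods

## Model and assumptions

The segmentation operates on a reconstructed RI tomogram n(x, y, z) on a
regular voxel grid (pitches dx, dy laterally, dz axially, all in μm).  Its
core assumptions are:

- **One cell per z column.**  Each 2D seed label corresponds to exactly
  one cell, and nothing else of that cell's material lies outside its
  extruded x-y footprint.  Stacked cells (spheroids, organoids) and
  interleaved high-density clusters violate this and are out of scope.
- **Cellular material is RI-continuous.**  The cell's dry component forms
  one connected body with n strictly above the medium.  Cells whose dry
  material is fragmented (e.g. extreme water uptake) will be truncated to
  their largest connected part.
- **The cell rests on the dish.**  The per-slice voxel count rises to its
  maximum near the cell bottom; artifacts below that level (dish-surface
  roughness) are separated by the z-floor rule, not by connectivity.

## Pipeline definition

Per cell k with 2D seed S_k:

1. Extrusion: E_k(z, y, x) = S_k(y, x) for every z.
2. Rough segmentation: R_k = n · 1[E_k = k] · 1[n > n_medium].  The
   inequality is strict: voxels exactly at the background level are
   removed.
3. z-floor: let c(z) = #{(y, x) : R_k(z, y, x) > 0} and
   ĉ(z) = c(z)/max c.  The floor index is the smallest z (scanning up
   from the dish at z = 0) with ĉ(z) ≥ 0.5; slices below it are zeroed.
   Normalizing by the maximum slice count makes the threshold scale-free;
   slices above the floor are kept even if ĉ later dips below 0.5 — the
   cell top is trimmed by connectivity, not thresholding, so non-monotone
   profiles cannot amputate the cell body.
4. Per-slice 2D cleanup: in each slice keep only the largest connected
   component at 8-connectivity.
5. 3D cleanup: keep the single largest component at 26-connectivity.

Sub-steps run in exactly this order.  Component ties are broken toward
the component containing the earliest voxel in (z, y, x) raster order
(scipy's labeling enumerates components in that order, so "first maximal
label" implements the rule).  Cells are processed independently; results
do not depend on processing order.  Empty cells (no voxel above the
medium inside the footprint) are skipped with a warning, not an error.

## Morphometrics

- OPD(y, x) = Σ_z mask·(n − n_medium)·dz — the z-integral is a Riemann
  sum with slab thickness dz, with no sub-voxel interpolation, matching
  the voxel-count volume definition.
- dry mass = (1/α)·Σ OPD·dx·dy with α = 0.19 μm³/pg (specific refraction
  increment of cellular dry matter, expressed as volume per pg).  Mass is
  computed on the **final** mask, after all cleanup.
- volume = voxel count × dx·dy·dz.
- Agreement metrics: pixel accuracy |P∩T|/|T| (a recall — it cannot
  penalize over-segmentation, so IoU and Dice are always reported with
  it); Hausdorff distance uses voxel centers and Euclidean distance in
  physical μm.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ri_scale` | 10000 | stored integer = round(RI × ri_scale); mandatory, never guessed from data — a silent misscale corrupts dry mass |
| `medium_ri` | 1.337 | background RI (aqueous medium); instrument-configured. `estimate_medium_ri` (histogram mode) exists but is off by default |
| `z_floor_fraction` | 0.5 | normalized count level declaring the cell bottom |
| `connectivity_2d` | 8 | per-slice component adjacency (4 or 8) |
| `connectivity_3d` | 26 | volumetric component adjacency (6, 18, 26) |
| `alpha` | 0.19 μm³/pg | dry-mass conversion constant |
| `min_area_px` | 50 | built-in seeder: smallest 2D component kept |

TIFF stacks are read bottom-of-dish first (`z_top_first` flips); the
z-floor rule is direction-sensitive, so the convention is explicit
configuration, not inference.

## Phantom generator

Phantoms are uniform-RI ellipsoids on a uniform background, optionally
truncated at a base plane: preset cells are half-ellipsoid **domes**,
because an adherent, spread cell has its largest cross-section at the
substrate.  This matters twice over: it is the morphology for which a
half-maximum z-floor is well-posed (a full floating ellipsoid reaches
half its maximal cross-section well above its bottom, so the rule would
clip ~15% of it — a real limitation of the method for rounded, poorly
adherent cells), and uniform bodies give closed-form oracles
V = πabc(2/3 − f + f³/3) for base fraction f and mass = Δn·V/α.

Noise terms:

- **Debris**: high-RI spheres (radius 0.2–0.4 μm) placed with ≥ 0.3 μm
  clearance from cell surfaces.
- **Fringe**: an additive sinusoid over (x, y) confined to a band of low
  z slices with a −0.3·amplitude DC shift.  Interferometric fringe
  artifacts in reconstructions concentrate near the substrate reflection
  plane and modulate around (mostly below) the background level; a
  full-height, zero-mean bright fringe would leave half of every
  footprint column above threshold at all z and is not solvable by any
  threshold-plus-connectivity scheme.  The generator warns when cell
  contrast does not exceed the fringe amplitude.
- **Floor roughness**: random voxels (fill fraction 0.15, Δn 0.02) in
  the lowest slices, below the cell base.

Standard presets use a 128×128×64 grid at 0.15 × 0.15 × 0.2 μm pitch
(19.2 × 19.2 × 12.8 μm field), cells with Δn = 0.04 and semi-axes 4–5 μm
laterally — a small adherent cell of ≈ 35 pg dry mass.  One seeded
generator drives all randomness; identical specs are bit-identical.

What phantoms do **not** emulate: internal RI structure of real cells,
missing-cone reconstruction anisotropy, partial-volume edge voxels, and
photon noise.  Passing on phantoms therefore demonstrates algorithmic
correctness (the pipeline recovers exactly the body it should, and noise
of the modeled kinds does not perturb it), not instrument-level accuracy
on real cells.

## Numerical choices

- Phantom voxelization samples body interiors at voxel centers
  ((k + ½)·pitch), so a face lying on a voxel boundary is counted
  midpoint-accurately; closed-form vs voxelized volume agrees well within
  3% at preset resolution (and to ≪ 1% for the presets).
- The built-in 2D seeder is deterministic: Otsu threshold on the MIP,
  hole filling, euclidean distance transform, regional maxima merged over
  a (2·10+1)² footprint, markers ordered by descending peak height then
  raster order, watershed flooding in marker order, sub-`min_area_px`
  components dropped, labels renumbered 1..n.  It is a convenience
  stand-in for an external 2D segmenter, which always takes precedence
  when supplied, and makes no equivalence claim to any particular tool.
- Binary 0/255 2D masks are rejected unless explicitly binarized, to
  avoid silently merging touching cells into one label.
- uint16 encoding checks range on write; decode→re-encode is exact at
  integer precision.

## Known limitations

- Pixel accuracy as defined ignores false positives; use IoU/Dice for
  symmetric comparisons.
- The z-floor rule assumes the bottom-most high-count slice belongs to
  the cell; debris layers thicker than the cell's own footprint count at
  0.5·maximum would defeat it.
- Single-threaded; per-cell independence makes parallelism trivial for
  callers but none is built in.
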