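# plateforge

Semi-automatic, patient-specific curved reconstruction-plate templating for
anterior pelvic ring fracture surgery planning — from a CT-like volume to a
print-ready STL plate template, with every stage testable on synthetic
phantoms. **All geometry is in millimetres** (STL carries no units; mm is
the fixed convention end to end, matching DICOM spacing).

The pipeline:

1. **segment** (`plateforge.imagevol`) — load a DICOM series / NRRD / NIfTI
   volume, threshold-segment bone from soft tissue (the threshold is always
   explicit; typical bone windows start around 200–400 HU but are *not*
   hard-coded), split connected fragments, erase operator-identified
   components (e.g. femurs), and extract a marching-cubes isosurface.
2. **reduce** (`plateforge.reduction`) — virtual fracture reduction: mirror
   a hemipelvis across a (default mid-sagittal, always overridable) plane,
   align fragments by ordered landmark pairs (closed-form Kabsch, optional
   ICP refinement), and compose fragments into one model.
3. **plan-plate** (`plateforge.plateplan` + `plateforge.plategen`) — project
   the surgeon's ordered anchor clicks onto the surface, build a smoothed
   on-surface path (Catmull–Rom spline → projection → endpoint-fixed
   Laplacian smoothing with re-projection), bridge residual fracture gaps
   with straight chords (*wrap*), and apply the **mid-line rule**: a
   residual path shorter than half a plate unit is cropped, anything from
   half a unit up earns one more unit, so the path length is always a whole
   number of units. Units from a catalog (four editable placeholder
   families; the dimensions are repository defaults for a generic 3.5 mm
   reconstruction plate, **not** vendor data) are then posed along the path
   with their profile parallel to the bone surface, and a clearance
   threshold (default 0.2 mm, nominal standoff 0.5 mm) guarantees the
   template never penetrates the bone: any offending unit is pushed out
   along its surface normal by the smallest sufficient offset (bisection to
   1e-3 mm). Output: binary STL + JSON sidecar (frames, screw axes,
   clearance report, inter-unit bend angles).
4. **synthetic** (`plateforge.synthetic`) — parametric phantoms with ground
   truth: spheres, tori, ridged sheets, a swept elliptical tube as a
   superior-pubic-ramus *analog*, two-intensity CT-like voxelization
   (default 0.8×0.8×3.0 mm), plane-cut fractures with known rigid
   displacements, and seeded noisy anchor sampling. Everything is
   deterministic under a fixed seed.

## CLI

```bash
plateforge make-phantom --kind swept_tube --out-stl bone.stl --out-nrrd ct.nrrd
plateforge segment --in ct.nrrd --low 300 --out-stl segmented.stl
plateforge reduce --fragments a.stl --fragments b.stl --landmarks pairs.json --out reduced.stl
plateforge plan-plate --bone reduced.stl --anchors pts.json --unit civic --out template.stl
plateforge run --config run.yaml --out out/        # chained stages + manifest
```

`run` executes the stages named in a YAML config (any ordered subset of
`phantom → segment → reduce → plan`), writes every artifact plus a
`manifest.json` with SHA-256 hashes and timings, and echoes the effective
config next to the outputs; reruns are byte-identical. Anchor files are
ordered JSON points: `[{"x":…,"y":…,"z":…}, …]` in mm, proximal→distal.

## Notes and interpretation choices

- "Mid-line of the fixation plate unit" is read as **half the unit length**
  (the transverse mid-line through the screw hole); the tie at exactly half
  a unit rounds **up**.
- Units are posed independently (no inter-unit hinge) and concatenated, not
  Boolean-unioned, in the exported STL; FDM slicers handle overlapping
  shells. Inter-unit bend angles are recorded in the sidecar so the
  operator can check that bends fall between screw holes.
- DICOM support covers uncompressed explicit-VR little-endian series (the
  common CT export); NRRD/NIfTI are the fully supported containers.
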