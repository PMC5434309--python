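# microgrind

3D reconstruction and morphometry for **serial microgrinding** (block-surface
imaging): a resin-embedded specimen — the motivating case is a human temporal
bone with the middle-ear ossicles in situ — is ground down in runs of ~35 µm,
every freshly exposed surface is stained and photographed, and the material
itself is destroyed.  Unlike µCT, which only separates calcified from
non-calcified material, the stained surfaces distinguish bone, cartilage,
vessels and soft tissue, so the fine intra-osseous vessel networks and
cartilage islands of the ossicles can be reconstructed and measured.

The package provides the full software side of that workflow:

1. **phantom** — a virtual-grinding simulator: analytic specimens (spheres,
   ellipsoids, capsules, tubes with tissue labels), three vertical fiducial
   columns, per-run caliper readings rounded to 1 µm, tilted cut planes,
   Mann-Dominici-style stain colors with show-through of structures below
   the transparent resin — plus exact ground truth for every slice.
2. **registration** — sub-pixel fiducial detection, least-squares similarity
   (Procrustes) per slice, and exact inclined-plane recovery from the three
   remaining-thickness measurements: pose
   `z(x,y) = g_x x + g_y y + c` per run.
3. **segmentation** — Gaussian color-model classification of the stained
   surfaces into {resin, bone, cartilage, vessel, soft tissue, fiducial},
   sub-pixel contour extraction, and import of manually traced contours.
4. **reconstruction** — tilt-aware nearest-plane rasterization into a label
   volume, watertight marching-cubes surfaces, and contour lofting with a
   voxel fallback for branchings.
5. **morphometry** — tetrahedral mesh volumes, not-calcified fraction,
   channel-diameter distributions (skeleton × distance transform), local
   wall thickness with a 150 µm diffusion-limit screen, and
   histology-vs-µCT style report comparison.

See `docs/methods.md` for the model, parameters and numerical choices.

## Worked example

The bundled configuration grinds a bone sphere (r = 500 µm) carrying an
axial 50 µm vessel channel through 34 virtual runs of 35 µm, with caliper
quantization, abrasion noise and per-slice placement jitter, then runs
registration, segmentation, reconstruction and morphometry:

```sh
microgrind all examples/two_sphere.yaml
# or: python -m microgrind.cli all examples/two_sphere.yaml
```

prints (abridged):

```json
{
  "structures": {
    "sphere_phantom": {
      "class_volumes_um3": { "bone": 520777020.9, "vessel": 1268227.6 },
      "class_volumes_mm3": { "bone": 0.52078, "vessel": 0.00127 },
      "volume_method": "mesh-tetra",
      "not_calcified_pct": 0.361,
      "vessel_diameters": { "median_um": 40.0, "n_samples": 81 },
      "bone_thickness": {
        "diffusion_limit_um": 150.0,
        "flagged_fraction_pct": 21.58,
        "fully_diffusion_supplied": false
      }
    }
  }
}
```

Reading the numbers: the tetrahedral volume of the reconstructed bone
surface is 5.208e8 µm³ against the analytic 5.216e8 µm³ (sphere minus
channel), a 0.16 % error after the full noisy pipeline; the not-calcified
fraction recovers the channel/sphere ratio (analytic 0.375 %); the vessel
diameter reads 40 µm for the 50 µm channel — one 10 µm voxel low, the stated
resolution of the estimator at this voxel size; and the diffusion screen
correctly reports that a solid 500 µm sphere has a core farther than 150 µm
from any surface (a thin-walled stapes-like arch instead passes with zero
flagged voxels).  Artifacts land in `out/two_sphere/`: slice TIFFs and the
caliper CSV, `poses.json`, per-slice label PNGs, `label_volume.nrrd`,
STL/PLY surfaces, `report.json`/`report.csv`, and `run.log` with artifact
checksums.

The stages are also available individually (`microgrind simulate`,
`register`, `segment`, `reconstruct`, `measure`, `compare`) and as a library
(`microgrind.phantom`, `.registration`, `.segmentation`, `.reconstruction`,
`.morphometry`, `.pipeline`).

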