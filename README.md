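# prophase3d

Chromosome segmentation, karyotyping and spatial statistics for 3D image
stacks of late-prophase human nuclei.

Serial block-face scanning electron microscopy (SBFSEM) can capture an
entire nucleus at ~11 nm pixels and 25 nm sections. In late prophase the
chromatin has condensed into 46 discrete chromosomes — each a pair of
parallel sister chromatids joined at the centromere — so a single stack
contains a complete, individually measurable karyotype. `prophase3d`
turns such a stack into biology: labeled chromosome objects, per-object
morphometry, chromosome identities, and the radial/neighborhood
organization of the nucleus. It is written for microscopists and nuclear
organization researchers who want the measurement chain scripted,
deterministic and testable rather than driven by manual annotation tools.

The pipeline:

1. **Segmentation** — per-slice bilateral denoising, intensity band
   thresholding at three standard 16-bit contrast bands (narrow
   38,445–41,264 reveals the bright axial core; medium 37,596–43,832 the
   chromosome body; wide 37,498–41,346 adds a dim halo), then
   26-connected component labeling with a size filter.
2. **Morphometry** — per object: volume V (voxel count × voxel volume),
   geodesic centerline length split at the centromeric constriction into
   arms p ≤ q, centromere index CI = 100·p/(p+q) by length and by volume,
   mean diameter, and DNA content n_bp = V / 5.80 nm³·bp⁻¹ (reported in
   Mbp).
3. **Identification** — objects are matched one-to-one to the 46 slots of
   a 46,XY template by minimizing
   Σ w_v|Δvol%| + w_l|Δlen%| + w_c|ΔCI| (Hungarian algorithm, features
   standardized over the reference slots), classified into cytogenetic
   groups A–H, and validated by regressing V on reference Mbp (expected
   slope 5.80×10⁶ nm³/Mbp).
4. **Spatial analysis** — distance of each chromosome from the nuclear
   center of mass, five equal-width radial regions (center → periphery),
   OLS regressions of radius on volume and on gene density, and a
   symmetric neighbor matrix from 3D surface proximity.

Because no stack of this kind is publicly deposited, the package includes
a **synthetic nucleus generator**: a 7.2 µm spherical nucleus packed with
46 paired-chromatid chromosome solids sized from a packaged reference
karyotype (GRCh38 Mbp, gene densities, canonical centromere indices),
rendered with the graded intensity profile that makes the three bands
select nested envelopes, with optional noise and a gene-density-dependent
radial placement bias — plus a voxel-exact truth table. The whole test
suite validates the pipeline closed-loop against these phantoms.

## Worked example

```python
from prophase3d import (PhantomConfig, generate_phantom, segment_stack,
                        measure_all, assign_karyotype, validate_assignment,
                        build_spatial_report, load_reference)

ref = load_reference()
stack, truth_labels, truth = generate_phantom(PhantomConfig.coarse(seed=42), ref)
labels = segment_stack(stack, band="medium")
print("objects:", len(labels.object_ids()))

morph = measure_all(labels)
assignment = assign_karyotype(morph, ref)
report = validate_assignment(assignment, morph, ref)
print("complete:", assignment.is_complete,
      "groups:", len(assignment.groups_present))
print(f"volume ~ Mbp slope: {report.slope:.3e} nm^3/Mbp, r^2 = {report.r_squared:.4f}")

spatial = build_spatial_report(labels, morph, assignment, ref)
print("gene-density regression r^2: %.3f" % spatial.gene_density_regression[2])
```

prints

```
objects: 46
complete: True groups: 8
volume ~ Mbp slope: 5.722e+06 nm^3/Mbp, r^2 = 0.9998
gene-density regression r^2: 0.002
```

All 46 chromosomes are recovered as separate objects; the assignment
fills every slot of the 46,XY template across all eight cytogenetic
groups; measured volumes track reference DNA content with a slope within
1.5% of the 5.80×10⁶ nm³/Mbp packing ratio; and with no radial placement
bias in the generator the gene-density regression is, correctly, flat.
Generating `PhantomConfig.coarse(seed=..., radial_bias=40.0)` instead
produces phantoms whose gene-rich chromosomes sit nearer the nuclear
center (negative regression slope).

The same stages are available as a CLI:

```bash
prophase3d simulate --out phantom --seed 42
prophase3d segment phantom/stack.tif --out labels.tif --band medium
prophase3d measure labels.tif --out morphometry.csv
prophase3d identify morphometry.csv --out assignment.csv
prophase3d spatial labels.tif morphometry.csv --assignment-csv assignment.csv
prophase3d run-all --seed 42 --out-dir run42     # everything, plus manifest
```

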