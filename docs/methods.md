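# Methods

`prophase3d` analyzes 3D image stacks of a single late-prophase human
nucleus — the kind produced by serial block-face scanning electron
microscopy (SBFSEM) — and identifies all 46 chromosomes from morphometry
alone. Because no public volume of this kind is deposited, the package
ships a synthetic nucleus generator with voxel-level ground truth; every
downstream stage is validated closed-loop against phantoms.

## The synthetic nucleus

**What it emulates.** A spherical nucleus of diameter 7.2 µm containing a
full diploid 46,XY chromosome set. Each chromosome is a pair of parallel,
touching, capsule-shaped sister chromatids with a Gaussian radius
constriction at the centromere. The rendered 16-bit intensity falls
monotonically from a bright axial core (41,000 counts at the chromatid
axis) through the body surface (37,550) and a dim halo to the nucleoplasm
background (33,000). These levels are chosen so the three standard
contrast bands carve nested envelopes per chromosome:

* narrow band (38,445–41,264): the axial core, ~74% of the body
  cross-section;
* medium band (37,596–43,832): the chromosome body. The solid is sized so
  its volume equals the chromosome's reference DNA content times the
  5.80 nm³/bp protein–DNA packing ratio; the medium envelope tracks it to
  within ~2%;
* wide band (37,498–41,346): body plus halo, ~1.8× the medium envelope
  cross-section. Note the wide band is not an interval superset of the
  medium band; only narrow ⊂ medium holds exactly.

**Geometry.** Chromatid radius is 230 nm for chromosome 1 and scales as
(Mbp)^(1/3). The scaling keeps small acrocentrics slender enough that
their centromeric constriction lies outside the spherical end-cap — with
a constant radius, a chromosome-21-sized solid physically cannot carry a
centromere index below 20. Chromatid axes are offset by 1.8 radii (a
slight overlap guarantees each rasterized pair is a single 26-connected
object, while the constriction locally separates the chromatids as in
micrographs). Arms follow a circular arc with a total turn drawn
uniformly from [0, `bend_deg`] (default 20°). Centerline length is solved
numerically so the analytic solid volume (union cross-section integrated
along the arc, plus end caps, minus the constriction deficit) matches the
DNA-implied target. Homolog volumes are jittered by ±1% so pairs are
near-identical but never equal; larger jitter makes the closest
chromosome types (e.g. 10 vs 12, separated by 0.4% in Mbp) genuinely
indistinguishable by volume.

**Placement.** Chromosomes are placed largest-first: cheap rejection
sampling (random position in the feasible sphere, random orientation and
bend) backed by an exhaustive fallback that rasterizes the rod once and
enumerates *every* collision-free integer grid placement by FFT
correlation with the blocked mask, drawing one at random. Solids keep at
least one background voxel between them (a 1-voxel clearance dilation),
which guarantees noiseless medium-band labeling can never merge two
chromosomes. A wider clearance shell is configurable, but at the default
nucleus size and DNA density the 46 near-straight rods occupy ~18% of the
sphere and sequential packing with a 3-voxel shell jams — verified by the
exhaustive search finding zero feasible placements — so 1 voxel is the
default. With `radial_bias` β > 0, placements are weighted by
exp(−β·((r/R) − (1−ĝ))²), ĝ the min–max normalized gene density: each
chromosome prefers a target radius that moves from the periphery (ĝ = 0)
to the center (ĝ = 1). A purely attractive bias (acceptance decaying
with radius at a gene-density-dependent rate) does not work here: long
chromosomes are placed first and are geometrically forced through the
central region, so the center saturates before the small gene-rich
chromosomes (19, 17, 22) are placed. The target-radius form pushes the
early gene-poorer large chromosomes outward as far as packing allows,
leaving central space; strong bias (β ≈ 40) then yields a negative
gene-density–radius regression slope in ≥9 of 10 seeds, emulating the
radial organization reported for lymphocyte nuclei. The trend is weak
(R² of a few percent), as packing geometry still dominates — consistent
with the weak correlations observed in real prophase nuclei.

**What the phantom does not model:** electron-optics artifacts (charging,
curtaining, slice registration), the nuclear envelope and nucleolus,
chromatin substructure, and truly serpentine chromosome conformations.
Passing the closed-loop tests therefore shows the measurement chain is
correct on idealized geometry at the stated noise level, not that
segmentation would succeed on arbitrary real material.

**Grids.** The full-resolution grid is 11×11 nm pixels with 25 nm
sections. All tests and the acceptance script use the 4× coarser
benchmark grid (44×44×100 nm), on which a complete phantom builds in
~20–40 s; geometry is identical, only voxelization error grows.

## Segmentation

Per-slice bilateral filtering (edge-preserving; window 2r+1 pixels,
range scale in raw counts) is available for noisy stacks; thresholding is
inclusive on both band bounds; components are 26-connected by default
(diagonal-touching chromatids must not fragment; anisotropic voxels make
6-connectivity fragile) and filtered at the voxel count of a 0.2 µm
sphere — far below any chromosome. Labels are renumbered by descending
size. Merged objects are reported, never silently split; a seeded
watershed splitter (distance-transform maxima as seeds) is available
behind an explicit call.

## Morphometry

**Centerline and length.** The object's voxels form a 26-connected graph
with anisotropic Euclidean edge weights. A two-pass farthest-point search
yields the two geodesically most distant voxels (the chromosome tips) and
every voxel's canonical arc coordinate s = (d_u − d_v + D)/2, which is
monotone along the object and indifferent to which chromatid a voxel
belongs to. Voxel centroids over consecutive s-bins give a fold-free
polyline running on the chromosome axis. Reported length is the Euclidean
arc of the smoothed polyline plus the farthest-voxel projection beyond
each end (raw graph distances are not used as lengths: lattice paths
overestimate off-axis Euclidean distance by up to ~15%). On the noiseless
coarse phantom, lengths recover to within 3%. Alternative centerline extractors
were rejected for cause: topological thinning of a chromatid pair yields
a ladder skeleton, and radius-penalized geodesics zigzag between
chromatids; both inflate length by tens of percent.

**Centromere.** Each voxel is assigned to its nearest centerline sample;
per-sample voxel count divided by local sample spacing gives the
cross-section (linear mass) profile, which dips to ~30% at the
centromere because both chromatids constrict together. The smoothed
profile's minimum — searched within the central 10–90% of arc length and
additionally clear of the end caps plus the smoothing half-span, where
tip taper would leak in — is refined by a local parabola. A profile whose
dip is below 25% of the window median is flagged unreliable; with an
expected chromosome identity the canonical index is used as a prior,
otherwise the flagged value is reported. The 10–90% window (rather than a
narrower central window) is required by acrocentric chromosomes, whose
centromere sits below 20% of arc length by definition. The p arm is the
shorter side; centromere indices recover to within ~4–5 points at the
benchmark voxel size.

**Other quantities.** Volume is voxel count × voxel volume; DNA content
is volume / 5.80 nm³ per bp, reported in Mbp; arm volumes partition the
voxels by the plane through the centromere orthogonal to the local
tangent; mean diameter is twice the mean distance-transform value along
the centerline (for a chromatid pair the centerline runs on the seam, so
this is an effective core diameter, not the full two-chromatid width);
length and volume genome-percentages are normalized so each column sums
to 100 over a nucleus.

## Identification

Identification is cast as a linear assignment problem over the 46 slots
of a 46,XY (or 46,XX) template. The cost of pairing object i with slot j
is w_v·|vol%ᵢ−vol%ⱼ| + w_l·|len%ᵢ−len%ⱼ| + w_c·|ciᵢ−ciⱼ|, features
standardized by their standard deviation over the reference slots;
defaults w_v = w_l = 1, w_c = 0.5 (the index is the noisiest feature).
Reference volume and length shares are both taken proportional to Mbp
(the reference table carries no independent length scale). The Hungarian
algorithm returns the globally optimal matching; within each pair the
larger-volume object is homolog "a". Validation regresses measured
volume on reference Mbp (expected slope 5.80×10⁶ nm³/Mbp) and flags
chromosomes whose volume deviates more than 25% from the DNA-implied
value.

Known limitation: chromosome X (156.0 Mbp, CI ≈ 39) lies inside the
group-C volume and CI range (chromosome 7: 159.3 Mbp, CI ≈ 38), so under
measurement noise of a few percent an X↔C confusion is the one
assignment error these features cannot exclude; on the noiseless phantom
the assignment is exact up to homolog swaps.

## Spatial analysis

The nucleus center is the volume-weighted centroid of all chromosome
voxels (an optional explicit center, e.g. from a nuclear envelope mask,
overrides it). Radii are centroid distances; the radial axis is split
into five equal-width regions labeled center → periphery. Radius is
regressed (OLS) on measured volume and on reference gene density. Two
chromosomes are neighbors when their minimum voxel-center separation is
at most the cutoff plus one voxel diagonal — the voxel-resolution reading
of "surfaces within the cutoff", which makes touching objects neighbors
at cutoff 0. The cutoff has no published value; the default 250 nm is
surfaced in every report. The matrix is computed by one anisotropic
distance transform per object and is symmetric with an all-false
diagonal; matrices ordered by karyotype name (1a, 1b, …, 22b, X, Y) when
an assignment is supplied.

## Reference table

24 rows (autosomes 1–22, X, Y): GRCh38 sequence lengths in Mbp (248.9 for
chromosome 1 down to 46.7 for chromosome 21), protein-coding genes per
Mbp (chromosome 19 the most gene-rich; 18 and Y gene-poor), centromere
indices from assembly centromere positions with acrocentric values set at
16–17 (cytogenetically sensible and geometrically representable — see
the radius-scaling note above), and cytogenetic groups A–G plus H for
the sex chromosomes. The indices serve only as soft priors in
identification.

## Numerical and policy choices

* Determinism: one `numpy` PCG64 generator seeded from the config drives
  all randomness; identical config + seed reproduces stacks, labels and
  truth tables bit-for-bit.
* Coordinates: arrays are (z, y, x); spacing is quoted (x, y, z) in nm;
  physical position of voxel (k, j, i) is ((i+0.5)sx, (j+0.5)sy,
  (k+0.5)sz). All reported geometry is nm / nm³ / Mbp.
* Voxel spacing provenance: explicit argument > JSON sidecar; a mismatch
  is an error, a missing spacing is an error, never a guess.
* Ties: component labels renumber by (size desc, first occurrence);
  assignment ties resolve by table order; centromere candidates tie
  toward the arc midpoint.
* Degenerate inputs: empty karyotypes produce an empty (all-background)
  phantom; single-voxel objects have zero length; constant-intensity
  stacks pass through the denoiser unchanged; constant covariates are a
  regression error.
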