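"""Synthetic prophase-nucleus phantom with voxel-level ground truth.

Emulates the geometry that serial block-face SEM reveals in a late-prophase
human lymphocyte nucleus: 46 rod-like chromosomes (22 autosome pairs plus X
and Y for a male karyotype) packed inside a ~7.2 µm sphere.  Each chromosome
is a pair of parallel, touching, capsule-shaped sister chromatids with a
radius constriction at the centromere separating the p and q arms.  The
rendered 16-bit intensity decays monotonically from a bright axial core at
the chromatid axis to the body surface and then through a dim halo to the
nucleoplasm background, so that the three standard contrast bands carve
nested envelopes (narrow: axial core; medium: chromosome body, sized to the
reference DNA content via 5.80 nm^3/bp; wide: body plus halo).

Every phantom is accompanied by a truth table (per-object volume, arm
lengths, centromere index, centroid and radial position) so that the
downstream segmentation, morphometry, identification and spatial modules
can be validated against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .containers import ImageStack, LabelVolume
from .reference import NM3_PER_BP, ReferenceKaryotype, load_reference
from .segmentation import BAND_PRESETS

__all__ = ["PhantomConfig", "PlacementError", "make_chromosome_solid", "generate_phantom"]

#: fractional depth of the centromeric radius constriction
_CONSTRICTION_DEPTH = 0.45
#: Gaussian sigma of the constriction along the arc, nm
_CONSTRICTION_W = 150.0
#: chromatid centre separation in units of chromatid radius (<2: slight
#: overlap guarantees the rasterized pair is one 26-connected object)
_SEP_FACTOR = 1.8
#: reference Mbp at which chromatid_radius_nm applies; radius scales with
#: (mbp / _MBP_REF)^(1/3) so small acrocentrics stay slender enough for
#: their centromere to sit outside the spherical end-cap
_MBP_REF = 248.9


class PlacementError(RuntimeError):
    """Raised when a chromosome cannot be placed inside the nucleus."""


@dataclass
class PhantomConfig:
    """Generator parameters; defaults are the full-resolution acquisition.

    ``voxel_nm`` is the (x, y, z) spacing: 11 nm in-plane pixels and 25 nm
    serial sections at full resolution.  :meth:`coarse` returns the 4x
    down-sampled benchmark grid (44, 44, 100 nm) on which a complete
    phantom builds in seconds.
    """

    voxel_nm: tuple[float, float, float] = (11.0, 11.0, 25.0)
    nucleus_diameter_nm: float = 7200.0
    volume_scale: float = 1.0
    axis_level: int = 41000
    edge_level: int = 37550
    background_level: int = 33000
    noise_sd: float = 150.0
    radial_bias: float = 0.0
    bend_deg: float = 20.0
    seed: int = 0
    karyotype: str = "XY"
    chromosomes: Sequence[str] | None = None
    chromatid_radius_nm: float = 230.0
    homolog_jitter: float = 0.01
    clearance_voxels: int = 1
    margin_voxels: int = 2
    max_attempts: int = 30000
    fft_orientations: int = 60
    placement_restarts: int = 2
    # halo shape: intensity knee just below the wide-band minimum at
    # halo_knee_dnorm chromatid radii, background beyond halo_end_dnorm
    halo_knee_level: int = 37490
    halo_knee_dnorm: float = 1.4
    halo_end_dnorm: float = 1.7

    def __post_init__(self) -> None:
        self.voxel_nm = tuple(float(v) for v in self.voxel_nm)
        if any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel spacing must be positive")
        if self.nucleus_diameter_nm <= 0:
            raise ValueError("nucleus diameter must be positive")
        if not (0 <= self.homolog_jitter < 0.5):
            raise ValueError("homolog_jitter must be in [0, 0.5)")
        if self.radial_bias < 0:
            raise ValueError("radial_bias must be >= 0")
        narrow, medium = BAND_PRESETS["narrow"], BAND_PRESETS["medium"]
        wide = BAND_PRESETS["wide"]
        if not self.background_level < narrow.min_intensity:
            raise ValueError("background_level must sit below the narrow band")
        if not self.edge_level < medium.min_intensity:
            raise ValueError("edge_level must sit below the medium band minimum")
        for band in (narrow, medium, wide):
            if not band.min_intensity <= self.axis_level <= band.max_intensity:
                raise ValueError(f"axis_level must fall inside the {band.name} band")
        if not (
            self.background_level
            < self.halo_knee_level
            < self.edge_level
            < self.axis_level
        ):
            raise ValueError("intensity levels must increase background -> axis")

    @classmethod
    def coarse(cls, **overrides) -> "PhantomConfig":
        """Coarse benchmark grid: 44 x 44 x 100 nm voxels, noiseless."""
        defaults = dict(voxel_nm=(44.0, 44.0, 100.0), noise_sd=0.0)
        defaults.update(overrides)
        return cls(**defaults)

    # -- derived quantities ------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        sx, sy, sz = self.voxel_nm
        d = self.nucleus_diameter_nm
        m = self.margin_voxels
        return (
            int(math.ceil(d / sz)) + 2 * m,
            int(math.ceil(d / sy)) + 2 * m,
            int(math.ceil(d / sx)) + 2 * m,
        )

    @property
    def center_nm(self) -> np.ndarray:
        """Physical (x, y, z) centre of the grid in nm."""
        nz, ny, nx = self.grid_shape
        sx, sy, sz = self.voxel_nm
        return np.array([nx * sx / 2.0, ny * sy / 2.0, nz * sz / 2.0])

    def chrom_ids(self) -> list[str]:
        if self.chromosomes is not None:
            return [str(c) for c in self.chromosomes]
        return ReferenceKaryotype.karyotype_chrom_ids(self.karyotype)


# ---------------------------------------------------------------------------
# chromosome geometry
# ---------------------------------------------------------------------------


@dataclass
class _Geometry:
    """Local-frame chromosome geometry prior to placement."""

    centerline: np.ndarray  # (N, 3) xyz nm, centred on the origin
    radii: np.ndarray  # (N,) local chromatid radius, nm
    arc: np.ndarray  # (N,) cumulative arc length from the p end, nm
    normal: np.ndarray  # unit offset direction between chromatid axes
    R: float  # nominal chromatid radius
    sep: float  # chromatid axis separation
    L: float  # centerline length
    s_c: float  # constriction position along the centerline arc
    p_len_nm: float
    q_len_nm: float
    ci_percent: float
    target_volume_nm3: float

    def chromatid_points(self) -> tuple[np.ndarray, np.ndarray]:
        off = (self.sep / 2.0) * self.normal
        pts = np.vstack([self.centerline + off, self.centerline - off])
        rad = np.concatenate([self.radii, self.radii])
        return pts, rad


def _union_area(r: float, d: float) -> float:
    """Cross-section area of two circles of radius r with centres d apart."""
    if d >= 2 * r:
        return 2 * math.pi * r * r
    lens = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(
        4 * r * r - d * d
    )
    return 2 * math.pi * r * r - lens


def _caps_volume(r: float, d: float) -> float:
    """Volume of the union of two spheres of radius r with centres d apart."""
    v = 2 * (4.0 / 3.0) * math.pi * r**3
    if d < 2 * r:
        v -= (math.pi / 12.0) * (4 * r + d) * (2 * r - d) ** 2
    return v


def _radius_profile(s: np.ndarray, R: float, s_c: float) -> np.ndarray:
    dip = _CONSTRICTION_DEPTH * np.exp(-((s - s_c) ** 2) / (2 * _CONSTRICTION_W**2))
    return R * (1.0 - dip)


def _constriction_pos(L: float, R: float, ci: float) -> float:
    """Arc position of the constriction for a target centromere index.

    The p-arm extent is measured from the chromatid tip (which overhangs
    the centerline by one cap radius), so ``s_c = ci * (L + 2R) - R``,
    clamped away from the cap so the constriction remains resolvable.
    """
    s_c = (ci / 100.0) * (L + 2 * R) - R
    return float(np.clip(s_c, 0.1 * L, 0.5 * L))


def _solve_length(V: float, R: float, sep: float, ci: float) -> float:
    """Centerline length whose analytic solid volume equals ``V``."""

    def vol(L: float) -> float:
        s_c = _constriction_pos(L, R, ci)
        s = np.linspace(0.0, L, 400)
        areas = np.array([_union_area(r, sep) for r in _radius_profile(s, R, s_c)])
        return float(np.trapezoid(areas, s)) + _caps_volume(R, sep)

    lo, hi = 1.0, 4.0 * V / _union_area(R, sep)
    if vol(hi) < V:
        hi *= 4
    if vol(lo) > V:
        raise ValueError("target volume smaller than the chromatid end caps")
    return float(optimize.brentq(lambda L: vol(L) - V, lo, hi, xtol=1.0))


@dataclass(frozen=True)
class _Sizing:
    """Per-object dimensions; fixed once, independent of placement attempts."""

    R: float
    sep: float
    L: float
    s_c: float
    p_len_nm: float
    q_len_nm: float
    ci_percent: float
    target_volume_nm3: float


def _size_chromosome(
    mbp: float, canonical_ci: float, config: PhantomConfig, jitter_factor: float = 1.0
) -> _Sizing:
    V = config.volume_scale * jitter_factor * mbp * 1e6 * NM3_PER_BP
    R = config.chromatid_radius_nm * (mbp / _MBP_REF) ** (1.0 / 3.0)
    sep = _SEP_FACTOR * R
    L = _solve_length(V, R, sep, canonical_ci)

    extent = L + 2 * R
    if extent >= config.nucleus_diameter_nm:
        raise PlacementError(
            f"chromosome of {mbp} Mbp needs {extent:.0f} nm, longer than the "
            f"{config.nucleus_diameter_nm:.0f} nm nucleus at this volume scale"
        )
    s_c = _constriction_pos(L, R, canonical_ci)
    p_len = s_c + R
    q_len = (L - s_c) + R
    return _Sizing(
        R=R,
        sep=sep,
        L=L,
        s_c=s_c,
        p_len_nm=p_len,
        q_len_nm=q_len,
        ci_percent=100.0 * p_len / (p_len + q_len),
        target_volume_nm3=V,
    )


def _build_geometry(
    sizing: _Sizing, config: PhantomConfig, rng: np.random.Generator
) -> _Geometry:
    L, R, sep, s_c = sizing.L, sizing.R, sizing.sep, sizing.s_c
    ds = min(max(min(config.voxel_nm) / 2.0, 8.0), 25.0)
    n = max(2, int(math.ceil(L / ds)) + 1)
    s = np.linspace(0.0, L, n)

    theta = math.radians(rng.uniform(0.0, config.bend_deg)) if config.bend_deg > 0 else 0.0
    if theta < 1e-6:
        pts = np.column_stack([s, np.zeros(n), np.zeros(n)])
    else:
        rho = L / theta
        pts = np.column_stack(
            [rho * np.sin(s / rho), np.zeros(n), rho * (1.0 - np.cos(s / rho))]
        )
    pts -= pts.mean(axis=0)

    return _Geometry(
        centerline=pts,
        radii=_radius_profile(s, R, s_c),
        arc=s,
        normal=np.array([0.0, 1.0, 0.0]),
        R=R,
        sep=sep,
        L=L,
        s_c=s_c,
        p_len_nm=sizing.p_len_nm,
        q_len_nm=sizing.q_len_nm,
        ci_percent=sizing.ci_percent,
        target_volume_nm3=sizing.target_volume_nm3,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _rasterize(
    points_nm: np.ndarray,
    radii: np.ndarray,
    config: PhantomConfig,
    grid_shape: tuple[int, int, int],
    pad_dnorm: float,
) -> tuple[tuple[slice, slice, slice], np.ndarray] | None:
    """Normalized-distance field of a chromatid point cloud on the grid.

    Returns ``(bbox, d_norm)`` where ``d_norm`` is distance to the nearest
    axis sample divided by that sample's local radius, evaluated at voxel
    centres within a bounding box padded to ``pad_dnorm`` radii.  ``None``
    if the bounding box misses the grid entirely.
    """
    sx, sy, sz = config.voxel_nm
    spacing = np.array([sx, sy, sz])
    pad = pad_dnorm * float(radii.max()) + spacing.max()
    lo = (points_nm.min(axis=0) - pad) / spacing - 0.5
    hi = (points_nm.max(axis=0) + pad) / spacing - 0.5
    nz, ny, nx = grid_shape
    dims = (nx, ny, nz)
    lo_i = [max(0, int(math.floor(v))) for v in lo]
    hi_i = [min(dims[a] - 1, int(math.ceil(hi[a]))) for a in range(3)]
    if any(hi_i[a] < lo_i[a] for a in range(3)):
        return None
    bbox = (
        slice(lo_i[2], hi_i[2] + 1),
        slice(lo_i[1], hi_i[1] + 1),
        slice(lo_i[0], hi_i[0] + 1),
    )
    zz = (np.arange(lo_i[2], hi_i[2] + 1) + 0.5) * sz
    yy = (np.arange(lo_i[1], hi_i[1] + 1) + 0.5) * sy
    xx = (np.arange(lo_i[0], hi_i[0] + 1) + 0.5) * sx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tree = cKDTree(points_nm)
    dist, idx = tree.query(centers, k=1)
    d_norm = (dist / radii[idx]).reshape(Z.shape)
    return bbox, d_norm


def _intensity_profile(d_norm: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Monotone intensity falloff: quadratic core, two-knee linear halo."""
    a, e = float(config.axis_level), float(config.edge_level)
    k, bg = float(config.halo_knee_level), float(config.background_level)
    d1, d2 = config.halo_knee_dnorm, config.halo_end_dnorm
    out = np.full(d_norm.shape, bg)
    core = d_norm <= 1.0
    out[core] = a - (a - e) * d_norm[core] ** 2
    inner = (d_norm > 1.0) & (d_norm <= d1)
    out[inner] = e - (e - k) * (d_norm[inner] - 1.0) / (d1 - 1.0)
    outer = (d_norm > d1) & (d_norm <= d2)
    out[outer] = k - (k - bg) * (d_norm[outer] - d1) / (d2 - d1)
    return out


@dataclass
class ChromosomeSolid:
    """A rasterized chromosome in its local frame (not yet placed)."""

    voxels: np.ndarray  # (M, 3) zyx voxel indices within the local grid
    d_norm: np.ndarray  # normalized-distance field over the local bbox
    bbox: tuple[slice, slice, slice]
    skeleton_nm: np.ndarray  # (N, 3) xyz centerline polyline
    centromere_arc_nm: float
    p_len_nm: float
    q_len_nm: float
    ci_percent: float
    volume_nm3: float  # voxel-counted solid volume
    target_volume_nm3: float
    chromatid_radius_nm: float


def make_chromosome_solid(
    entry, config: PhantomConfig, rng: np.random.Generator | int | None = None
) -> ChromosomeSolid:
    """Build one chromosome solid (two parallel chromatids) on the grid.

    ``entry`` is a reference-table row (needs ``mbp`` and ``canonical_ci``).
    The solid is centred in a grid of the configured spacing; the medium
    contrast envelope of the rendered solid matches
    ``volume_scale * mbp * 1e6 * 5.80 nm^3`` to within a few percent.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sizing = _size_chromosome(float(entry["mbp"]), float(entry["canonical_ci"]), config)
    geom = _build_geometry(sizing, config, rng)
    pts, rad = geom.chromatid_points()
    pts = pts + config.center_nm
    res = _rasterize(pts, rad, config, config.grid_shape, pad_dnorm=1.05)
    if res is None:
        raise PlacementError("chromosome does not intersect the grid")
    bbox, d_norm = res
    solid = d_norm <= 1.0
    vox = np.argwhere(solid)
    vox += np.array([bbox[0].start, bbox[1].start, bbox[2].start])
    voxel_vol = config.voxel_nm[0] * config.voxel_nm[1] * config.voxel_nm[2]
    return ChromosomeSolid(
        voxels=vox,
        d_norm=d_norm,
        bbox=bbox,
        skeleton_nm=geom.centerline + config.center_nm,
        centromere_arc_nm=geom.s_c,
        p_len_nm=geom.p_len_nm,
        q_len_nm=geom.q_len_nm,
        ci_percent=geom.ci_percent,
        volume_nm3=float(solid.sum()) * voxel_vol,
        target_volume_nm3=geom.target_volume_nm3,
        chromatid_radius_nm=geom.R,
    )


# ---------------------------------------------------------------------------
# whole-nucleus generation
# ---------------------------------------------------------------------------


def _fft_place(
    sizing: _Sizing,
    config: PhantomConfig,
    rng: np.random.Generator,
    forbidden: np.ndarray,
    nucleus_dist2: np.ndarray,
    center: np.ndarray,
    g_hat: float,
):
    """Exhaustive collision-free placement of one chromosome.

    Rasterizes the rod (at a random orientation and bend) into a kernel,
    enumerates every integer grid position at which the kernel's solid
    avoids the blocked mask (placed objects with clearance, plus everything
    outside the nuclear sphere) via FFT correlation, and draws one position
    at random — weighted by the radial gene-density bias when active.
    Returns ``((bbox, d_norm, solid, skeleton_nm), geometry)`` or
    ``(None, None)`` if no orientation admits any position.
    """
    from scipy import fft as sfft

    R_nuc = config.nucleus_diameter_nm / 2.0
    sx, sy, sz = config.voxel_nm
    spacing = np.array([sx, sy, sz])
    grid_shape = np.array(forbidden.shape)
    bad = (forbidden | (nucleus_dist2 > R_nuc**2)).astype(np.float32)
    struct = np.ones((3, 3, 3), dtype=bool)

    # orientation-independent kernel box (the rod fits at any rotation),
    # so the blocked-mask FFT is computed once and reused per orientation
    extent = sizing.L + 2 * sizing.R
    pad = config.halo_end_dnorm * sizing.R + spacing.max()
    kdim_xyz = np.ceil((extent + 2 * pad) / spacing).astype(int)
    kdim_xyz += 1 - (kdim_xyz % 2)  # odd dims: unambiguous centre
    kshape = (int(kdim_xyz[2]), int(kdim_xyz[1]), int(kdim_xyz[0]))
    if any(kshape[a] > grid_shape[a] for a in range(3)):
        return None, None
    fshape = [
        sfft.next_fast_len(int(grid_shape[a] + kshape[a] - 1)) for a in range(3)
    ]
    bad_f = sfft.rfftn(bad, fshape)
    same_lo = [(kshape[a] - 1) // 2 for a in range(3)]

    for _ in range(config.fft_orientations):
        geom = _build_geometry(sizing, config, rng)
        rot = Rotation.random(rng=rng)
        pts, rad = geom.chromatid_points()
        pts = rot.apply(pts)

        box_center = kdim_xyz * spacing / 2.0
        shift0 = box_center - (pts.min(axis=0) + pts.max(axis=0)) / 2.0
        kpts = pts + shift0
        res = _rasterize(kpts, rad, config, kshape, config.halo_end_dnorm)
        if res is None:
            continue
        kbox, kdn = res
        d_norm = np.full(kshape, np.inf, dtype=np.float32)
        d_norm[kbox] = kdn
        solid = d_norm <= 1.0
        if not solid.any() or ndimage.label(solid, structure=struct)[1] != 1:
            continue

        kern_f = sfft.rfftn(solid[::-1, ::-1, ::-1].astype(np.float32), fshape)
        full = sfft.irfftn(bad_f * kern_f, fshape)
        overlap = full[
            same_lo[0] : same_lo[0] + int(grid_shape[0]),
            same_lo[1] : same_lo[1] + int(grid_shape[1]),
            same_lo[2] : same_lo[2] + int(grid_shape[2]),
        ]
        feasible = overlap < 0.5
        idxs = np.argwhere(feasible)
        if len(idxs) == 0:
            continue

        if config.radial_bias > 0:
            r_frac = np.sqrt(nucleus_dist2[feasible]) / R_nuc
            logw = -config.radial_bias * (r_frac - (1.0 - g_hat)) ** 2
            w = np.exp(logw - logw.max())  # stable under strong bias
            w = w / w.sum()
            pick = idxs[rng.choice(len(idxs), p=w)]
        else:
            pick = idxs[rng.integers(len(idxs))]

        # the kernel box may poke beyond the grid (the solid never does,
        # since it must stay inside the nuclear sphere): crop the paste
        origin = (np.array(kshape) - 1) // 2
        start = pick - origin
        g_lo = np.maximum(start, 0)
        g_hi = np.minimum(start + np.array(kshape), grid_shape)
        k_lo = g_lo - start
        k_hi = g_hi - start
        bbox = tuple(slice(int(g_lo[a]), int(g_hi[a])) for a in range(3))
        ksl = tuple(slice(int(k_lo[a]), int(k_hi[a])) for a in range(3))
        solid_c = solid[ksl]
        if solid_c.sum() != solid.sum():  # solid clipped: infeasible after all
            continue
        if (forbidden[bbox] & solid_c).any():  # should not happen
            continue
        shift_xyz = np.array([start[2] * sx, start[1] * sy, start[0] * sz])
        skel = rot.apply(geom.centerline) + shift0 + shift_xyz
        return (bbox, d_norm[ksl], solid_c, skel), geom
    return None, None


_TRUTH_COLUMNS = [
    "object_id",
    "chrom_id",
    "homolog",
    "true_volume_nm3",
    "true_p_len_nm",
    "true_q_len_nm",
    "true_ci_percent",
    "centroid_x_nm",
    "centroid_y_nm",
    "centroid_z_nm",
    "true_radius_nm",
]


def generate_phantom(
    config: PhantomConfig, reference: ReferenceKaryotype | None = None
) -> tuple[ImageStack, LabelVolume, pd.DataFrame]:
    """Generate a ground-truthed nucleus phantom.

    Chromosomes are placed largest-first by seeded rejection sampling:
    random position inside the nuclear sphere, random orientation and arm
    curvature per attempt, with a clearance of ``clearance_voxels`` between
    solids so that band segmentation is well posed.  With
    ``radial_bias`` > 0 an extra acceptance test
    ``exp(-beta * g_hat * (r / R)^2)`` (g_hat the min-max normalized gene
    density) pulls gene-rich chromosomes toward the nuclear interior.

    Returns ``(stack, labels, truth)`` — the rendered 16-bit intensity
    stack, the ground-truth label volume, and one truth row per object.
    """
    if reference is None:
        reference = load_reference()
    rng = np.random.default_rng(config.seed)

    last_err: PlacementError | None = None
    for _ in range(config.placement_restarts + 1):
        try:
            labels, intensity, records = _place_all(config, reference, rng)
            break
        except PlacementError as err:
            last_err = err
    else:
        raise last_err

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, intensity.shape)
    stack_data = np.clip(np.rint(intensity), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(records, columns=_TRUTH_COLUMNS)
    if len(truth):
        truth = truth.sort_values("object_id").reset_index(drop=True)
    return (
        ImageStack(stack_data, config.voxel_nm),
        LabelVolume(labels, config.voxel_nm),
        truth,
    )


def _place_all(
    config: PhantomConfig, reference: ReferenceKaryotype, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """One complete placement pass; raises :class:`PlacementError` on jam."""
    grid_shape = config.grid_shape
    sx, sy, sz = config.voxel_nm
    spacing = np.array([sx, sy, sz])
    voxel_vol = sx * sy * sz
    center = config.center_nm
    R_nuc = config.nucleus_diameter_nm / 2.0

    labels = np.zeros(grid_shape, dtype=np.int32)
    intensity = np.full(grid_shape, float(config.background_level), dtype=np.float32)
    forbidden = np.zeros(grid_shape, dtype=bool)

    chrom_ids = config.chrom_ids()
    # largest first; homolog 'a' precedes 'b'
    order = sorted(
        range(len(chrom_ids)), key=lambda i: (-reference.mbp(chrom_ids[i]), i)
    )
    seen: dict[str, int] = {}
    g = reference.table["gene_density"]
    g_lo, g_span = float(g.min()), float(g.max() - g.min())

    records: list[dict] = []
    struct = np.ones((3, 3, 3), dtype=bool)
    xy_struct = np.zeros((1, 3, 3), dtype=bool)
    xy_struct[0] = True
    half_diag = 0.5 * math.sqrt(sx * sx + sy * sy + sz * sz)

    # squared distance of each voxel centre from the nucleus centre
    nz, ny, nx = grid_shape
    zz = ((np.arange(nz) + 0.5) * sz - center[2]) ** 2
    yy = ((np.arange(ny) + 0.5) * sy - center[1]) ** 2
    xx = ((np.arange(nx) + 0.5) * sx - center[0]) ** 2
    nucleus_dist2 = (
        zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    ).astype(np.float32)

    next_label = 1
    for i in order:
        cid = chrom_ids[i]
        seen[cid] = seen.get(cid, 0) + 1
        homolog = "a" if seen[cid] == 1 else "b"
        entry = reference.entry(cid)
        jitter = 1.0 + rng.uniform(-config.homolog_jitter, config.homolog_jitter)
        g_hat = (reference.gene_density(cid) - g_lo) / g_span if g_span else 0.0
        sizing = _size_chromosome(
            float(entry["mbp"]), float(entry["canonical_ci"]), config, jitter
        )

        # a rod of half-extent h fits (tangentially) only if its centre lies
        # within sqrt(R_eff^2 - h^2) of the nucleus centre; sampling inside
        # that bound avoids hopeless attempts for the long chromosomes
        h = sizing.L / 2.0 + sizing.R
        R_eff = R_nuc - sizing.R - half_diag
        r_max = math.sqrt(max(R_eff**2 - h**2, 0.0)) or 0.25 * R_nuc

        accepted = None  # (bbox, d_norm, solid, skeleton)
        n_fast = min(300, config.max_attempts)
        for _ in range(n_fast):
            geom = _build_geometry(sizing, config, rng)
            rot = Rotation.random(rng=rng)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r_center = r_max * rng.uniform() ** (1.0 / 3.0)
            pos = center + r_center * u

            pts, rad = geom.chromatid_points()
            pts = rot.apply(pts) + pos

            # solid must lie fully inside the nuclear sphere
            d_from_center = np.linalg.norm(pts - center, axis=1)
            if np.any(d_from_center + rad + half_diag > R_nuc):
                continue

            # gene-density-dependent radial placement bias: gene-rich
            # chromosomes prefer the interior (target radius -> 0),
            # gene-poor ones the periphery (target radius -> R)
            if config.radial_bias > 0:
                r_frac = float(np.mean(d_from_center)) / R_nuc
                if rng.uniform() > math.exp(
                    -config.radial_bias * (r_frac - (1.0 - g_hat)) ** 2
                ):
                    continue

            # cheap clearance pre-check on axis samples
            idx = np.floor(pts / spacing).astype(int)
            idx = np.clip(idx, 0, [grid_shape[2] - 1, grid_shape[1] - 1, grid_shape[0] - 1])
            if forbidden[idx[:, 2], idx[:, 1], idx[:, 0]].any():
                continue

            res = _rasterize(pts, rad, config, grid_shape, config.halo_end_dnorm)
            if res is None:
                continue
            bbox, d_norm = res
            solid = d_norm <= 1.0
            if not solid.any() or forbidden[bbox][solid].any():
                continue
            if ndimage.label(solid, structure=struct)[1] != 1:
                continue
            accepted = (bbox, d_norm, solid, rot.apply(geom.centerline) + pos)
            break

        if accepted is None:
            # crowded nucleus: enumerate all collision-free integer
            # placements of a rasterized rod kernel by FFT correlation
            # against the blocked mask and draw one at random
            accepted, geom = _fft_place(
                sizing, config, rng, forbidden, nucleus_dist2, center, g_hat
            )

        if accepted is None:
            raise PlacementError(
                f"could not place chromosome {cid} (homolog {homolog}); "
                "nucleus too crowded"
            )
        bbox, d_norm, solid, skel = accepted

        labels[bbox][solid] = next_label
        halo = d_norm <= config.halo_end_dnorm
        region = intensity[bbox]
        region[halo] = np.maximum(region[halo], _intensity_profile(d_norm[halo], config))
        # clearance shell: full clearance in-plane, ~equal physical
        # clearance axially (sections are ~2-4x thicker than pixels)
        n_full = min(2, config.clearance_voxels)
        grown = ndimage.binary_dilation(solid, structure=struct, iterations=n_full)
        if config.clearance_voxels > n_full:
            grown = ndimage.binary_dilation(
                grown, structure=xy_struct, iterations=config.clearance_voxels - n_full
            )
        forbidden[bbox] |= grown

        vox = np.argwhere(solid) + np.array(
            [bbox[0].start, bbox[1].start, bbox[2].start]
        )
        centroid = ((vox[:, ::-1] + 0.5) * spacing).mean(axis=0)  # zyx -> xyz
        records.append(
            {
                "object_id": next_label,
                "chrom_id": cid,
                "homolog": homolog,
                "true_volume_nm3": float(solid.sum()) * voxel_vol,
                "true_p_len_nm": geom.p_len_nm,
                "true_q_len_nm": geom.q_len_nm,
                "true_ci_percent": geom.ci_percent,
                "centroid_x_nm": centroid[0],
                "centroid_y_nm": centroid[1],
                "centroid_z_nm": centroid[2],
                "true_radius_nm": float(np.linalg.norm(centroid - center)),
            }
        )
        next_label += 1

    return labels, intensity, records
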