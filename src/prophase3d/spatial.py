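"""Radial organization and neighborhood mapping of chromosomes.

Positions every chromosome relative to the nuclear center (the
volume-weighted centroid of all chromosome voxels, unless an explicit
center is supplied), bins the radii into five equal-width radial regions
from center to periphery, regresses radius on chromosome volume and on
gene density — lymphocyte nuclei classically show gene-density-dependent
radial organization — and builds a symmetric chromosome neighborhood
matrix from 3D proximity of the segmented objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import linregress

from .containers import LabelVolume

__all__ = [
    "RADIAL_REGIONS",
    "SpatialReport",
    "nucleus_center_and_radii",
    "radial_bins",
    "radial_regression",
    "neighbor_map",
    "build_spatial_report",
    "plot_neighbor_heatmap",
]

#: region labels ordered center -> periphery (bin 0 .. bin 4)
RADIAL_REGIONS = (
    "center",
    "center-intermediate",
    "intermediate",
    "periphery-intermediate",
    "periphery",
)

#: default surface proximity cutoff for calling two chromosomes neighbors
DEFAULT_NEIGHBOR_CUTOFF_NM = 250.0


def nucleus_center_and_radii(
    labels: LabelVolume,
    center_nm: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Nucleus center and per-object radial distance.

    The center defaults to the volume-weighted centroid of all chromosome
    voxels (every voxel weighs the same, so this is the chromatin center
    of mass); each object's radius is the distance of its own centroid
    from that center.  All coordinates in physical (x, y, z) nm.
    """
    ids = labels.object_ids()
    if len(ids) == 0:
        raise ValueError("label volume contains no objects")
    sx, sy, sz = labels.voxel_nm
    spacing = np.array([sx, sy, sz])

    centroids = {}
    for oid in ids:
        vox = np.argwhere(labels.data == oid)
        centroids[int(oid)] = ((vox[:, ::-1] + 0.5) * spacing).mean(axis=0)
    counts = {int(oid): int((labels.data == oid).sum()) for oid in ids}

    if center_nm is None:
        total = sum(counts.values())
        center_nm = sum(counts[o] * c for o, c in centroids.items()) / total
    center_nm = np.asarray(center_nm, float)

    radii = pd.Series(
        {o: float(np.linalg.norm(c - center_nm)) for o, c in centroids.items()},
        name="radius_nm",
    )
    radii.index.name = "object_id"
    return center_nm, radii.sort_index()


def radial_bins(radii, n_bins: int = 5) -> pd.Series:
    """Equal-width radial region labels from center to periphery.

    Bin edges are ``k * max(radius) / n_bins``; bins are half-open
    ``[lo, hi)`` except the outermost, which includes the maximum radius.
    If all radii are zero every object is labeled ``center``.
    """
    radii = pd.Series(radii, dtype=float)
    if (radii < 0).any():
        raise ValueError("radii must be non-negative")
    if n_bins != len(RADIAL_REGIONS):
        names = [f"bin{i}" for i in range(n_bins)]
    else:
        names = list(RADIAL_REGIONS)
    rmax = radii.max()
    if rmax == 0:
        return pd.Series([names[0]] * len(radii), index=radii.index, name="radial_region")
    idx = np.minimum((radii / rmax * n_bins).astype(int), n_bins - 1)
    return pd.Series(
        [names[i] for i in idx], index=radii.index, name="radial_region"
    )


def radial_regression(x, y) -> tuple[float, float, float]:
    """OLS of radius on a per-chromosome covariate: (slope, intercept, R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("constant covariate: regression undefined")
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 0.0
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def neighbor_map(
    labels: LabelVolume,
    cutoff_nm: float = DEFAULT_NEIGHBOR_CUTOFF_NM,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Symmetric boolean neighbor matrix of the labeled objects.

    Two objects are neighbors when their minimum voxel-centre separation
    is at most ``cutoff_nm`` plus one voxel diagonal — i.e. their surfaces
    approach within the cutoff at voxel resolution, so 26-adjacent
    (touching) objects are neighbors even at cutoff 0.  Implemented with
    one anisotropic Euclidean distance transform per object.

    ``names`` relabels rows/columns (e.g. object id -> "1a"); ordering
    follows sorted object ids, or karyotype order of the names if all ids
    are named.
    """
    if cutoff_nm < 0:
        raise ValueError("cutoff must be >= 0")
    ids = [int(i) for i in labels.object_ids()]
    n = len(ids)
    spacing = labels.spacing_zyx
    diag = float(np.linalg.norm(spacing))
    eff = cutoff_nm + diag

    mat = np.zeros((n, n), dtype=bool)
    for a, oid in enumerate(ids):
        dist = ndimage.distance_transform_edt(labels.data != oid, sampling=spacing)
        for b, other in enumerate(ids):
            if b <= a:
                continue
            dmin = float(dist[labels.data == other].min())
            if dmin <= eff:
                mat[a, b] = mat[b, a] = True

    index = [names.get(i, str(i)) if names else i for i in ids]
    df = pd.DataFrame(mat, index=index, columns=index)
    if names and all(i in names for i in ids):
        order = sorted(index, key=_karyotype_sort_key)
        df = df.loc[order, order]
    return df


def _karyotype_sort_key(name: str):
    base = name.rstrip("ab")
    hom = name[len(base) :] or "a"
    order = {str(i): i for i in range(1, 23)}
    order.update({"X": 23, "Y": 24})
    return (order.get(base, 99), hom)


@dataclass
class SpatialReport:
    nucleus_center_nm: np.ndarray
    per_chromosome: pd.DataFrame  # object_id, name, radius_nm, radial_region
    volume_regression: tuple[float, float, float]  # slope, intercept, r^2
    gene_density_regression: tuple[float, float, float]
    neighbor_matrix: pd.DataFrame
    neighbor_cutoff_nm: float
    neighbor_lists: dict[str, list[str]] = field(default_factory=dict)


def build_spatial_report(
    labels: LabelVolume,
    morphometries: pd.DataFrame,
    assignment=None,
    reference=None,
    cutoff_nm: float = DEFAULT_NEIGHBOR_CUTOFF_NM,
    center_nm: np.ndarray | None = None,
) -> SpatialReport:
    """Full spatial analysis of one nucleus.

    With an assignment and reference table the report keys chromosomes by
    karyotype name (1a..Y), regresses radius on measured volume and on
    reference gene density, and orders the neighbor matrix in karyotype
    order; without them, objects are keyed by id and the gene-density
    regression is skipped.
    """
    center, radii = nucleus_center_and_radii(labels, center_nm=center_nm)
    regions = radial_bins(radii)

    names = None
    gene_density = None
    if assignment is not None:
        names = {
            int(r["object_id"]): f"{r['chrom_id']}{r['homolog']}"
            for _, r in assignment.table.iterrows()
        }
        if reference is not None:
            gene_density = {
                int(r["object_id"]): reference.gene_density(r["chrom_id"])
                for _, r in assignment.table.iterrows()
            }

    per = pd.DataFrame(
        {
            "object_id": radii.index,
            "name": [names.get(i, str(i)) if names else str(i) for i in radii.index],
            "radius_nm": radii.to_numpy(),
            "radial_region": regions.to_numpy(),
        }
    )

    vols = morphometries.set_index("object_id")["volume_nm3"]
    vol_fit = radial_regression(vols.loc[per["object_id"]].to_numpy(), per["radius_nm"])
    gd_fit = (float("nan"),) * 3
    if gene_density is not None:
        gd = np.array([gene_density[i] for i in per["object_id"]])
        gd_fit = radial_regression(gd, per["radius_nm"].to_numpy())

    nmat = neighbor_map(labels, cutoff_nm=cutoff_nm, names=names)
    lists = {
        str(r): [str(c) for c in nmat.columns[nmat.loc[r].to_numpy()]]
        for r in nmat.index
    }
    return SpatialReport(
        nucleus_center_nm=center,
        per_chromosome=per,
        volume_regression=vol_fit,
        gene_density_regression=gd_fit,
        neighbor_matrix=nmat,
        neighbor_cutoff_nm=cutoff_nm,
        neighbor_lists=lists,
    )


def plot_neighbor_heatmap(report: SpatialReport, path: str) -> None:
    """Save the neighbor matrix as a heat map image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = report.neighbor_matrix
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(mat.to_numpy(dtype=int), cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
    ax.set_title(
        f"Chromosome neighbors (cutoff {report.neighbor_cutoff_nm:.0f} nm)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
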