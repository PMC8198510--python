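"""Karyotype assignment: matching measured objects to chromosome identities.

Chromosome identification from morphometry alone is a template-matching
problem: every measured object must be assigned to one of the 46 slots of a
diploid karyotype (two per autosome, one each for X and Y in a male cell).
Classically this is done by eye on volume-vs-centromere-index and
length-vs-centromere-index scatter plots; here the same information is cast
as a linear assignment problem — the cost of pairing an object with a slot
combines its genome-volume share, genome-length share and centromere index
against the reference expectations, and the globally optimal one-to-one
matching is found with the Hungarian algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from .reference import ReferenceKaryotype, group_of

__all__ = [
    "KaryotypeAssignment",
    "ValidationReport",
    "assign_karyotype",
    "validate_assignment",
    "DEFAULT_WEIGHTS",
]

#: cost weights for (volume share, length share, centromere index); the
#: centromere index is down-weighted because its measurement is noisier
DEFAULT_WEIGHTS = (1.0, 1.0, 0.5)


@dataclass
class KaryotypeAssignment:
    """Optimal object -> karyotype-slot assignment."""

    table: pd.DataFrame  # object_id, chrom_id, homolog, group, assignment_cost
    total_cost: float
    is_complete: bool
    template: str = "XY"

    def chrom_of(self, object_id: int) -> str:
        row = self.table.loc[self.table["object_id"] == object_id]
        if row.empty:
            raise KeyError(f"object {object_id} not assigned")
        return str(row["chrom_id"].iloc[0])

    @property
    def groups_present(self) -> set[str]:
        return set(self.table["group"])


@dataclass
class ValidationReport:
    slope: float  # nm^3 per Mbp
    intercept: float
    r_squared: float
    relative_volume_error: dict[str, float]  # keyed by e.g. "1a"
    outliers: list[str] = field(default_factory=list)
    outlier_threshold: float = 0.25


def _slots(reference: ReferenceKaryotype, template: str) -> pd.DataFrame:
    ids = reference.karyotype_chrom_ids(template)
    seen: dict[str, int] = {}
    rows = []
    for cid in ids:
        seen[cid] = seen.get(cid, 0) + 1
        rows.append(
            {
                "chrom_id": cid,
                "slot_homolog": "a" if seen[cid] == 1 else "b",
                "mbp": reference.mbp(cid),
                "canonical_ci": reference.canonical_ci(cid),
                "group": group_of(cid),
            }
        )
    slots = pd.DataFrame(rows)
    total = slots["mbp"].sum()
    # the reference carries no independent length scale: arm length is taken
    # proportional to DNA content, so both shares are Mbp fractions
    slots["vol_percent"] = 100.0 * slots["mbp"] / total
    slots["len_percent"] = 100.0 * slots["mbp"] / total
    return slots


def assign_karyotype(
    morphometries: pd.DataFrame,
    reference: ReferenceKaryotype,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    template: str = "XY",
    allow_partial: bool = False,
) -> KaryotypeAssignment:
    """Optimally assign measured objects to karyotype slots.

    Cost of pairing object *i* with slot *j*:

    ``w_v |vol%_i - vol%_j| + w_l |len%_i - len%_j| + w_c |ci_i - ci_j|``

    with each feature standardized by its standard deviation over the
    reference slots, so the weights compare like with like.  Requires
    exactly 46 records for a diploid template unless ``allow_partial``;
    ties are broken deterministically (objects and slots in table order).
    Within each assigned pair the object with the larger measured volume is
    homolog 'a' (tie: lower object id).
    """
    slots = _slots(reference, template)
    n_slots = len(slots)
    n_obj = len(morphometries)
    if n_obj != n_slots and not allow_partial:
        raise ValueError(
            f"expected {n_slots} measured objects for a 46,{template} template, "
            f"got {n_obj} (pass allow_partial=True for a partial assignment)"
        )
    if n_obj == 0:
        raise ValueError("no morphometry records")

    need = ["object_id", "vol_percent_of_genome", "len_percent_of_genome", "ci_len_percent"]
    missing = [c for c in need if c not in morphometries.columns]
    if missing:
        raise ValueError(f"morphometry table lacks columns {missing}")
    morph = morphometries.sort_values("object_id").reset_index(drop=True)

    feats_obj = morph[
        ["vol_percent_of_genome", "len_percent_of_genome", "ci_len_percent"]
    ].to_numpy(float)
    feats_ref = slots[["vol_percent", "len_percent", "canonical_ci"]].to_numpy(float)
    scale = feats_ref.std(axis=0)
    scale[scale == 0] = 1.0

    w = np.asarray(weights, float)
    diff = np.abs(feats_obj[:, None, :] - feats_ref[None, :, :]) / scale
    cost = (diff * w).sum(axis=2)

    rows, cols = linear_sum_assignment(cost)
    out = []
    for i, j in zip(rows, cols):
        out.append(
            {
                "object_id": int(morph["object_id"].iloc[i]),
                "chrom_id": slots["chrom_id"].iloc[j],
                "group": slots["group"].iloc[j],
                "assignment_cost": float(cost[i, j]),
                "volume_nm3": float(morph["volume_nm3"].iloc[i])
                if "volume_nm3" in morph
                else float("nan"),
            }
        )
    table = pd.DataFrame(out)

    # homolog naming: larger measured volume -> 'a'
    homologs = []
    for _, sub in table.groupby("chrom_id", sort=False):
        order = sub.sort_values(
            ["volume_nm3", "object_id"], ascending=[False, True]
        ).index
        for rank, idx in enumerate(order):
            homologs.append((idx, "a" if rank == 0 else "b"))
    hmap = dict(homologs)
    table["homolog"] = [hmap[i] for i in table.index]
    table = table.sort_values("object_id").reset_index(drop=True)
    table = table[
        ["object_id", "chrom_id", "homolog", "group", "assignment_cost", "volume_nm3"]
    ]

    counts = table["chrom_id"].value_counts()
    expected = pd.Series(reference.karyotype_chrom_ids(template)).value_counts()
    complete = counts.sort_index().equals(expected.sort_index())
    return KaryotypeAssignment(
        table=table,
        total_cost=float(cost[rows, cols].sum()),
        is_complete=bool(complete),
        template=template,
    )


def validate_assignment(
    assignment: KaryotypeAssignment,
    morphometries: pd.DataFrame,
    reference: ReferenceKaryotype,
    outlier_threshold: float = 0.25,
) -> ValidationReport:
    """Regress measured volume on reference DNA content.

    A faithful segmentation should show measured volume growing linearly
    with reference Mbp with slope ~5.80e6 nm^3/Mbp.  The per-chromosome
    relative volume error is computed against the DNA-implied volume
    (mbp x 5.80e6 nm^3); chromosomes beyond ``outlier_threshold`` are
    flagged.
    """
    if not assignment.is_complete:
        raise ValueError("validation requires a complete karyotype assignment")
    merged = assignment.table.merge(
        morphometries[["object_id", "volume_nm3"]], on="object_id", suffixes=("_t", "")
    )
    mbp = merged["chrom_id"].map(reference.mbp).to_numpy(float)
    vol = merged["volume_nm3"].to_numpy(float)
    if np.allclose(mbp, mbp[0]):
        raise ValueError("degenerate reference: all Mbp values equal")

    fit = linregress(mbp, vol)
    rel_err = {}
    outliers = []
    for _, row in merged.iterrows():
        key = f"{row['chrom_id']}{row['homolog']}"
        expected = reference.expected_volume_nm3(row["chrom_id"])
        err = (row["volume_nm3"] - expected) / expected
        rel_err[key] = float(err)
        if abs(err) > outlier_threshold:
            outliers.append(key)
    return ValidationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        relative_volume_error=rel_err,
        outliers=outliers,
        outlier_threshold=outlier_threshold,
    )
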