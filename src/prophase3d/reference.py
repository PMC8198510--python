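"""Reference human karyotype table.

Packaged per-chromosome template used both as the identification target and
as ground-truth sizing for the synthetic nucleus generator:

* ``mbp`` — DNA content in mega base pairs (GRCh38 sequence lengths; e.g.
  chromosome 1 is the largest at 248.9 Mbp and chromosome 21 the smallest
  autosome at 46.7 Mbp).
* ``gene_density`` — protein-coding genes per Mbp; chromosome 19 is the most
  gene-rich, 18 and Y are gene-poor.
* ``canonical_ci`` — centromere index, the short (p) arm as a percentage of
  total arm length; metacentric chromosomes approach 50, acrocentric ones
  (13, 14, 15, 21, 22, Y) are well below 20.  Used only as a soft prior
  during identification.
* ``group`` — classical cytogenetic group: A (1-3), B (4-5), C (6-12),
  D (13-15), E (16-18), F (19-20), G (21-22), plus H for the sex
  chromosomes X and Y.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
import pandas as pd

__all__ = [
    "AUTOSOMES",
    "CHROMOSOMES",
    "GROUPS",
    "NM3_PER_BP",
    "ReferenceKaryotype",
    "load_reference",
    "group_of",
]

#: Volume of the chromosomal protein-DNA complex per base pair.
NM3_PER_BP = 5.80

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

GROUPS: dict[str, str] = {
    **{str(i): "A" for i in (1, 2, 3)},
    **{str(i): "B" for i in (4, 5)},
    **{str(i): "C" for i in range(6, 13)},
    **{str(i): "D" for i in (13, 14, 15)},
    **{str(i): "E" for i in (16, 17, 18)},
    **{str(i): "F" for i in (19, 20)},
    **{str(i): "G" for i in (21, 22)},
    "X": "H",
    "Y": "H",
}

ACROCENTRIC: frozenset[str] = frozenset({"13", "14", "15", "21", "22", "Y"})

_COLUMNS = ["chrom_id", "mbp", "gene_density", "canonical_ci", "group"]


class ReferenceValidationError(ValueError):
    """Raised when a reference karyotype table violates an invariant."""


def group_of(chrom_id: str | int) -> str:
    """Cytogenetic group (A-H) of a chromosome name in {1..22, X, Y}."""
    key = str(chrom_id)
    try:
        return GROUPS[key]
    except KeyError:
        raise KeyError(f"unknown chromosome name: {chrom_id!r}") from None


class ReferenceKaryotype:
    """Validated per-chromosome reference table (24 rows, one per type)."""

    def __init__(self, table: pd.DataFrame):
        self.table = self._validate(table)
        self._by_chrom = self.table.set_index("chrom_id")

    @staticmethod
    def _validate(table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise ReferenceValidationError(f"missing columns: {missing}")
        table = table[_COLUMNS].copy()
        table["chrom_id"] = table["chrom_id"].astype(str)

        dup = table["chrom_id"][table["chrom_id"].duplicated()]
        if len(dup):
            raise ReferenceValidationError(
                f"duplicate chromosome rows: {sorted(set(dup))}"
            )
        absent = set(CHROMOSOMES) - set(table["chrom_id"])
        if absent:
            raise ReferenceValidationError(f"missing chromosomes: {sorted(absent)}")
        extra = set(table["chrom_id"]) - set(CHROMOSOMES)
        if extra:
            raise ReferenceValidationError(f"unknown chromosomes: {sorted(extra)}")

        # canonical karyotype ordering 1..22, X, Y
        order = {c: i for i, c in enumerate(CHROMOSOMES)}
        table = table.sort_values("chrom_id", key=lambda s: s.map(order))
        table = table.reset_index(drop=True)

        for col in ("mbp", "gene_density", "canonical_ci"):
            vals = pd.to_numeric(table[col], errors="coerce")
            if vals.isna().any():
                bad = table.loc[vals.isna(), "chrom_id"].tolist()
                raise ReferenceValidationError(f"non-numeric {col} for {bad}")
            if (vals <= 0).any():
                bad = table.loc[vals <= 0, "chrom_id"].tolist()
                raise ReferenceValidationError(f"non-positive {col} for {bad}")
            table[col] = vals.astype(float)

        if (table["canonical_ci"] > 50).any():
            bad = table.loc[table["canonical_ci"] > 50, "chrom_id"].tolist()
            raise ReferenceValidationError(f"canonical_ci > 50 for {bad}")
        acro = table[table["chrom_id"].isin(ACROCENTRIC)]
        if (acro["canonical_ci"] >= 20).any():
            bad = acro.loc[acro["canonical_ci"] >= 20, "chrom_id"].tolist()
            raise ReferenceValidationError(
                f"acrocentric chromosomes must have canonical_ci < 20: {bad}"
            )

        by = table.set_index("chrom_id")["mbp"]
        if by.idxmax() != "1":
            raise ReferenceValidationError("chromosome 1 must have the maximum Mbp")
        if by.idxmin() != "21":
            raise ReferenceValidationError("chromosome 21 must have the minimum Mbp")

        mism = table.loc[
            table["chrom_id"].map(GROUPS) != table["group"], "chrom_id"
        ].tolist()
        if mism:
            raise ReferenceValidationError(f"group labels inconsistent for {mism}")
        return table

    # -- lookups -----------------------------------------------------------

    def entry(self, chrom_id: str | int) -> pd.Series:
        key = str(chrom_id)
        if key not in self._by_chrom.index:
            raise KeyError(f"unknown chromosome name: {chrom_id!r}")
        return self._by_chrom.loc[key]

    def mbp(self, chrom_id: str | int) -> float:
        return float(self.entry(chrom_id)["mbp"])

    def gene_density(self, chrom_id: str | int) -> float:
        return float(self.entry(chrom_id)["gene_density"])

    def canonical_ci(self, chrom_id: str | int) -> float:
        return float(self.entry(chrom_id)["canonical_ci"])

    def group_of(self, chrom_id: str | int) -> str:
        return group_of(chrom_id)

    # -- karyotype helpers -------------------------------------------------

    @staticmethod
    def karyotype_chrom_ids(template: str = "XY") -> list[str]:
        """Chromosome ids (with multiplicity) of a diploid 46,XY or 46,XX set."""
        if template not in ("XY", "XX"):
            raise ValueError("karyotype template must be 'XY' or 'XX'")
        ids = [c for c in AUTOSOMES for _ in range(2)]
        ids += ["X", "Y"] if template == "XY" else ["X", "X"]
        return ids

    def diploid_mbp(self, template: str = "XY") -> float:
        return float(sum(self.mbp(c) for c in self.karyotype_chrom_ids(template)))

    def expected_volume_nm3(self, chrom_id: str | int) -> float:
        """Reference chromosome volume implied by the 5.80 nm^3/bp conversion."""
        return self.mbp(chrom_id) * 1e6 * NM3_PER_BP


def load_reference(path: str | Path | None = None) -> ReferenceKaryotype:
    """Load and validate a reference karyotype table.

    With no ``path`` the packaged default table is used.  A user-supplied CSV
    must carry the columns ``chrom_id,mbp,gene_density,canonical_ci,group``.
    """
    if path is None:
        source = resources.files("prophase3d.data") / "reference_karyotype.csv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        try:
            table = pd.read_csv(path)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ReferenceValidationError(
                f"cannot read reference CSV {path}: {exc}"
            ) from exc
    return ReferenceKaryotype(table)
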