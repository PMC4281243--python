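"""Immunohistochemistry (IHC) annotation integration.

Antibody stainings of tissue-microarray cores are coded by pathologists on two
ordinal scales: the fraction of positive cells (0 = 0-1%, 1 = 2-25%,
2 = 26-75%, 3 = >75%) and the staining intensity (0 = negative, 1 = weak,
2 = moderate, 3 = strong).  This module validates such coded records, answers
the restricted-expression database query (stained in the target tissue and in
at most N other tissues at no higher level), assigns kidney proteins to a
unique nephron/collecting-duct compartment when their staining is confined to
one, and tallies concordance between RNA-derived and IHC-derived gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AnnotationError, DataError, MissingFileError
from .specificity_classifier import (
    ELEVATED_CATEGORIES,
    Category,
    GeneClassification,
)

__all__ = [
    "KIDNEY_COMPARTMENTS",
    "KIDNEY_CELL_TYPES",
    "IHCAnnotation",
    "CompartmentCall",
    "ConcordanceReport",
    "fraction_to_score",
    "load_ihc_annotations",
    "write_ihc_annotations",
    "restricted_expression_query",
    "assign_unique_compartment",
    "rna_ihc_concordance",
    "compare_to_reference_sets",
    "load_reference_list",
]

#: Nephron/collecting-duct compartments eligible for unique-localisation calls.
KIDNEY_COMPARTMENTS = (
    "glomeruli",
    "proximal_tubule",
    "distal_tubule",
    "collecting_duct",
)

#: Controlled cell-type vocabulary for kidney annotations.  The intercalated
#: subset of the collecting duct is kept distinct so intercalated-only
#: expression can be flagged; "other" covers vessels/interstitium.
KIDNEY_CELL_TYPES = frozenset(
    KIDNEY_COMPARTMENTS + ("collecting_duct_intercalated", "other")
)


@dataclass(frozen=True)
class IHCAnnotation:
    """One gene x tissue x cell-type staining record."""

    gene_id: str
    antibody_id: str
    tissue: str
    cell_type: str
    fraction_score: int
    intensity_score: int
    subcellular: str = ""

    def __post_init__(self) -> None:
        for name in ("fraction_score", "intensity_score"):
            score = getattr(self, name)
            if not (0 <= int(score) <= 3) or int(score) != score:
                raise AnnotationError(f"{self.gene_id}: {name}={score!r} outside 0-3")
        if self.tissue == "kidney" and self.cell_type not in KIDNEY_CELL_TYPES:
            raise AnnotationError(
                f"{self.gene_id}: unknown kidney cell_type {self.cell_type!r} "
                f"(expected one of {sorted(KIDNEY_CELL_TYPES)})"
            )

    @property
    def positive(self) -> bool:
        """Stained at all: some positive cells with at least weak intensity."""
        return self.fraction_score >= 1 and self.intensity_score >= 1

    @property
    def compartment(self) -> str | None:
        """Compartment this kidney record belongs to (intercalated -> collecting duct)."""
        if self.cell_type in KIDNEY_COMPARTMENTS:
            return self.cell_type
        if self.cell_type == "collecting_duct_intercalated":
            return "collecting_duct"
        return None


@dataclass(frozen=True)
class CompartmentCall:
    """Unique-compartment assignment of one gene within the kidney."""

    gene_id: str
    compartment: str
    intercalated_only: bool = False
    evidence: tuple[IHCAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.compartment not in KIDNEY_COMPARTMENTS:
            raise AnnotationError(f"unknown compartment {self.compartment!r}")
        if self.intercalated_only and self.compartment != "collecting_duct":
            raise AnnotationError("intercalated_only applies to collecting duct only")


@dataclass(frozen=True)
class ConcordanceReport:
    """Overlap between an IHC-derived gene set and the RNA-elevated gene set."""

    total_overlap: int
    by_category: Mapping[Category, int]

    def __post_init__(self) -> None:
        if sum(self.by_category.values()) != self.total_overlap:
            raise DataError("concordance breakdown does not sum to the overlap")

    def to_series(self) -> pd.Series:
        out = {cat.value: self.by_category.get(cat, 0) for cat in ELEVATED_CATEGORIES}
        out["total_overlap"] = self.total_overlap
        return pd.Series(out, name="n_genes")


def fraction_to_score(percent_positive: float) -> int:
    """Bin a percentage of positive cells into the coded 0-3 fraction score.

    Bins: <=1% -> 0, (1, 25]% -> 1, (25, 75]% -> 2, >75% -> 3.  Percentages
    between the integer anchors fall in the higher bin so the bins partition
    [0, 100].
    """
    if not (0 <= percent_positive <= 100):
        raise AnnotationError(f"percentage {percent_positive!r} outside [0, 100]")
    if percent_positive <= 1:
        return 0
    if percent_positive <= 25:
        return 1
    if percent_positive <= 75:
        return 2
    return 3


_IHC_COLUMNS = [
    "gene_id",
    "antibody_id",
    "tissue",
    "cell_type",
    "fraction_score",
    "intensity_score",
    "subcellular",
]


def load_ihc_annotations(path: str | Path) -> list[IHCAnnotation]:
    """Read and validate an IHC annotation TSV."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"IHC annotation table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_IHC_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise AnnotationError(f"IHC table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples():
        try:
            fraction = int(row.fraction_score)
            intensity = int(row.intensity_score)
        except ValueError as exc:
            raise AnnotationError(f"non-integer IHC score in row {row.Index}: {exc}") from exc
        records.append(
            IHCAnnotation(
                gene_id=row.gene_id,
                antibody_id=row.antibody_id,
                tissue=row.tissue,
                cell_type=row.cell_type,
                fraction_score=fraction,
                intensity_score=intensity,
                subcellular=getattr(row, "subcellular", ""),
            )
        )
    return records


def write_ihc_annotations(annotations: Sequence[IHCAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "antibody_id": a.antibody_id,
                "tissue": a.tissue,
                "cell_type": a.cell_type,
                "fraction_score": a.fraction_score,
                "intensity_score": a.intensity_score,
                "subcellular": a.subcellular,
            }
            for a in annotations
        ],
        columns=_IHC_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def _tissue_levels(
    annotations: Iterable[IHCAnnotation], level: str
) -> dict[str, dict[str, tuple[int, int]]]:
    """Per gene, per tissue: the maximum staining level over antibodies/cell types.

    The level of a record is (intensity, fraction) compared lexicographically
    (``level="intensity_fraction"``), or intensity alone (``level="intensity"``).
    Only positive records (fraction >= 1 and intensity >= 1) count as expression.
    """
    levels: dict[str, dict[str, tuple[int, int]]] = {}
    for a in annotations:
        if not a.positive:
            continue
        key = (a.intensity_score, a.fraction_score) if level == "intensity_fraction" else (
            a.intensity_score,
            0,
        )
        per_gene = levels.setdefault(a.gene_id, {})
        if a.tissue not in per_gene or key > per_gene[a.tissue]:
            per_gene[a.tissue] = key
    return levels


def restricted_expression_query(
    annotations: Sequence[IHCAnnotation],
    target: str = "kidney",
    max_other_tissues: int = 6,
    level: str = "intensity_fraction",
) -> set[str]:
    """Genes stained in the target tissue and nearly nowhere else.

    A gene qualifies when it is positive in the target and positive in at most
    *max_other_tissues* other tissues, each at a staining level lower than or
    equal to the target's.  With ``max_other_tissues=0`` this returns exactly
    the uniquely-stained genes.
    """
    if target not in {a.tissue for a in annotations}:
        raise DataError(f"no annotations for target tissue {target!r}")
    levels = _tissue_levels(annotations, level)
    result = set()
    for gene, per_tissue in levels.items():
        if target not in per_tissue:
            continue
        target_level = per_tissue[target]
        others = {t: lv for t, lv in per_tissue.items() if t != target}
        if len(others) > max_other_tissues:
            continue
        if any(lv > target_level for lv in others.values()):
            continue
        result.add(gene)
    return result


def assign_unique_compartment(
    annotations: Sequence[IHCAnnotation],
    genes: Iterable[str] | None = None,
) -> list[CompartmentCall]:
    """Call genes whose positive kidney staining is confined to one compartment.

    A gene gets a call iff every positive kidney annotation falls in exactly
    one of the four compartments; positive staining in "other" kidney
    structures blocks the call.  Collecting-duct calls flag
    ``intercalated_only`` when every positive annotation sits in intercalated
    cells.  Gene order of the calls is sorted for determinism.
    """
    universe = set(genes) if genes is not None else {a.gene_id for a in annotations}
    per_gene: dict[str, list[IHCAnnotation]] = {}
    for a in annotations:
        if a.tissue == "kidney" and a.positive and a.gene_id in universe:
            per_gene.setdefault(a.gene_id, []).append(a)
    calls = []
    for gene in sorted(per_gene):
        records = per_gene[gene]
        compartments = {a.compartment for a in records}
        if None in compartments or len(compartments) != 1:
            continue  # stained in "other" structures or in several compartments
        (compartment,) = compartments
        intercalated_only = compartment == "collecting_duct" and all(
            a.cell_type == "collecting_duct_intercalated" for a in records
        )
        calls.append(
            CompartmentCall(
                gene_id=gene,
                compartment=compartment,
                intercalated_only=intercalated_only,
                evidence=tuple(records),
            )
        )
    return calls


def rna_ihc_concordance(
    classifications: Sequence[GeneClassification],
    ihc_genes: Iterable[str],
) -> ConcordanceReport:
    """Overlap of an IHC-derived gene set with the RNA-elevated genes, per category."""
    ihc_set = set(ihc_genes)
    by_category: dict[Category, int] = {}
    total = 0
    for c in classifications:
        if c.category in ELEVATED_CATEGORIES and c.gene_id in ihc_set:
            by_category[c.category] = by_category.get(c.category, 0) + 1
            total += 1
    return ConcordanceReport(total_overlap=total, by_category=by_category)


def load_reference_list(path: str | Path) -> set[str]:
    """Read a plain gene-ID-per-line reference list (e.g. a published proteome)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"reference list not found: {path}")
    return {line.strip() for line in path.read_text().splitlines() if line.strip()}


def compare_to_reference_sets(
    calls: Sequence[CompartmentCall],
    reference_lists: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Overlap of compartment-specific genes with named reference gene sets.

    Returns one row per reference list with present/absent counts, plus an
    ``absent_from_all`` row counting genes covered by none of the lists.
    """
    if not reference_lists:
        raise DataError("no reference lists given")
    gene_ids = [c.gene_id for c in calls]
    rows = []
    covered: set[str] = set()
    for name in sorted(reference_lists):
        ref = set(reference_lists[name])
        present = sum(1 for g in gene_ids if g in ref)
        rows.append({"reference": name, "present": present, "absent": len(gene_ids) - present})
        covered |= ref
    absent_all = sum(1 for g in gene_ids if g not in covered)
    rows.append(
        {"reference": "absent_from_all", "present": len(gene_ids) - absent_all, "absent": absent_all}
    )
    return pd.DataFrame(rows, columns=["reference", "present", "absent"])
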