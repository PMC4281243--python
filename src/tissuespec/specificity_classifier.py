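"""Seven-category tissue-specificity classification of a multi-tissue compendium.

Every protein-coding gene is assigned, for a chosen target tissue, exactly one
of seven categories from its tissue-level mean FPKM profile:

``NOT_DETECTED``
    below the detection limit (1 FPKM) in the target tissue.
``HIGHLY_ENRICHED``
    tissue-specificity (TS) score >= 50, where TS = target mean FPKM divided by
    the maximum mean FPKM over all other tissues.
``MODERATELY_ENRICHED``
    TS >= 5.
``GROUP_ENRICHED``
    a group of 2-7 tissues including the target whose mean FPKM is >= 5-fold
    the expression of every tissue outside the group.
``ENHANCED``
    target FPKM >= 5-fold the average FPKM over all tissues (target included).
``EXPRESSED_IN_ALL``
    detected (>= 1 FPKM) in every analysed tissue.
``MIXED``
    detected in at least the target but in neither of the above patterns.

The rules are applied in that order of precedence, which makes the categories
a partition.  The union of the enriched, group-enriched and enhanced categories
is referred to as the *elevated* gene set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, DataError, NegativeValueError
from .expression_io import TissueProfile

__all__ = [
    "Category",
    "Thresholds",
    "GeneClassification",
    "CategoryTally",
    "PoolFractions",
    "ELEVATED_CATEGORIES",
    "is_detected",
    "tissue_specificity_score",
    "find_enriched_group",
    "classify_gene",
    "classify_profile",
    "mrna_pool_fractions",
    "top_expressed",
    "classifications_to_frame",
    "write_classification_table",
]


class Category(str, enum.Enum):
    """Specificity category of one gene with respect to the target tissue."""

    NOT_DETECTED = "not_detected"
    HIGHLY_ENRICHED = "highly_enriched"
    MODERATELY_ENRICHED = "moderately_enriched"
    GROUP_ENRICHED = "group_enriched"
    ENHANCED = "enhanced"
    EXPRESSED_IN_ALL = "expressed_in_all"
    MIXED = "mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories whose union forms the "elevated" gene set.
ELEVATED_CATEGORIES = frozenset(
    {
        Category.HIGHLY_ENRICHED,
        Category.MODERATELY_ENRICHED,
        Category.GROUP_ENRICHED,
        Category.ENHANCED,
    }
)

#: Top-level four-way partition used for mRNA-pool accounting.
TOP_LEVEL_GROUPS = ("not_detected", "elevated", "mixed", "expressed_in_all")


def _top_level_group(category: Category) -> str:
    if category in ELEVATED_CATEGORIES:
        return "elevated"
    if category is Category.NOT_DETECTED:
        return "not_detected"
    if category is Category.EXPRESSED_IN_ALL:
        return "expressed_in_all"
    return "mixed"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds.

    Parameters
    ----------
    detection_limit
        FPKM below which a gene counts as not expressed in a tissue (default 1).
    high_enrichment_fold, enrichment_fold
        TS-score cutoffs for highly (50) and moderately (5) enriched.
    group_fold
        Fold requirement of the group mean over every outside tissue (5).
    group_min_size, group_max_size
        Allowed group sizes, target included (2-7).
    enhanced_fold
        Fold of target over the all-tissue average (5).
    ts_denominator_floor
        Small positive floor (0.01 FPKM) guarding division by zero when no
        other tissue expresses the gene at all.  Deliberately far below the
        detection limit so that near-zero competitors enter the TS denominator
        as measured.
    group_comparator
        ``"max"`` (default) compares the group mean against the maximum outside
        tissue; ``"mean"`` against the outside average (strictly weaker).
    """

    detection_limit: float = 1.0
    high_enrichment_fold: float = 50.0
    enrichment_fold: float = 5.0
    group_fold: float = 5.0
    group_min_size: int = 2
    group_max_size: int = 7
    enhanced_fold: float = 5.0
    ts_denominator_floor: float = 0.01
    group_comparator: str = "max"

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ConfigError("detection_limit must be > 0")
        if not (self.high_enrichment_fold >= self.enrichment_fold > 1):
            raise ConfigError("need high_enrichment_fold >= enrichment_fold > 1")
        if not (2 <= self.group_min_size <= self.group_max_size):
            raise ConfigError("need 2 <= group_min_size <= group_max_size")
        if self.ts_denominator_floor <= 0:
            raise ConfigError("ts_denominator_floor must be > 0")
        if self.group_comparator not in ("max", "mean"):
            raise ConfigError("group_comparator must be 'max' or 'mean'")


@dataclass(frozen=True)
class GeneClassification:
    """Classification outcome for one gene against one target tissue."""

    gene_id: str
    category: Category
    ts_score: float
    target_fpkm: float
    max_other_fpkm: float
    second_tissue: str
    enriched_group: frozenset[str] = frozenset()
    n_detected_tissues: int = 0

    def __post_init__(self) -> None:
        if (self.category is Category.GROUP_ENRICHED) != bool(self.enriched_group):
            raise ConsistencyError(
                f"{self.gene_id}: enriched_group must be non-empty iff GROUP_ENRICHED"
            )


@dataclass
class CategoryTally:
    """Counts of genes per category, with derived sums."""

    counts: dict[Category, int]

    def __post_init__(self) -> None:
        self.counts = {cat: int(self.counts.get(cat, 0)) for cat in Category}
        if any(v < 0 for v in self.counts.values()):
            raise ConsistencyError("category counts must be non-negative")

    @classmethod
    def from_classifications(cls, classifications: Iterable[GeneClassification]) -> "CategoryTally":
        counts: dict[Category, int] = {}
        for c in classifications:
            counts[c.category] = counts.get(c.category, 0) + 1
        return cls(counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def elevated_count(self) -> int:
        return sum(self.counts[cat] for cat in ELEVATED_CATEGORIES)

    @property
    def top_level_counts(self) -> dict[str, int]:
        out = {g: 0 for g in TOP_LEVEL_GROUPS}
        for cat, n in self.counts.items():
            out[_top_level_group(cat)] += n
        return out

    def to_series(self) -> pd.Series:
        return pd.Series({cat.value: self.counts[cat] for cat in Category}, name="n_genes")


@dataclass(frozen=True)
class PoolFractions:
    """Fraction of the target tissue's total mRNA pool (sum of FPKM) per group."""

    fractions: Mapping[str, float]
    total_fpkm: float

    def __post_init__(self) -> None:
        if self.total_fpkm <= 0:
            raise DataError("total FPKM must be positive for pool fractions")
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ConsistencyError(f"pool fractions sum to {s}, expected 1")


def is_detected(fpkm: float, limit: float = 1.0) -> bool:
    """True iff *fpkm* reaches the detection limit (detected means fpkm >= limit)."""
    if fpkm < 0:
        raise NegativeValueError("FPKM must be non-negative")
    return fpkm >= limit


def _as_profile_series(gene_profile) -> pd.Series:
    series = pd.Series(gene_profile, dtype=float)
    if (series < 0).any() or not np.isfinite(series.to_numpy()).all():
        raise DataError("gene profile must be finite and non-negative")
    return series


def tissue_specificity_score(
    gene_profile, target: str, thresholds: Thresholds = Thresholds()
) -> float:
    """TS score: target mean FPKM / max mean FPKM over all other tissues.

    The denominator is floored at ``ts_denominator_floor`` so a gene silent in
    every other tissue gets a large but finite score.
    """
    series = _as_profile_series(gene_profile)
    if target not in series.index:
        raise DataError(f"target tissue {target!r} not in profile")
    if len(series) < 2:
        raise DataError("TS score needs >= 2 tissues")
    others = series.drop(target)
    denom = max(float(others.max()), thresholds.ts_denominator_floor)
    return float(series[target]) / denom


def _ranked_other_tissues(series: pd.Series, target: str) -> list[str]:
    # descending FPKM, ties broken lexicographically by tissue name
    others = series.drop(target)
    return sorted(others.index, key=lambda t: (-others[t], t))


def find_enriched_group(
    gene_profile, target: str, thresholds: Thresholds = Thresholds()
) -> frozenset[str] | None:
    """Smallest qualifying enriched group containing the target, or ``None``.

    A group G qualifies when ``group_min_size <= |G| <= group_max_size`` and
    mean FPKM over G >= ``group_fold`` x the outside level (maximum outside
    tissue by default).  For the max-outside comparator the best group of a
    given size is always the target plus the highest-expressed other tissues,
    so scanning sorted prefixes is exhaustive.
    """
    series = _as_profile_series(gene_profile)
    if target not in series.index:
        raise DataError(f"target tissue {target!r} not in profile")
    if thresholds.group_max_size >= len(series):
        raise ConfigError(
            "group_max_size must be smaller than the number of tissues "
            "(otherwise no outside tissue remains)"
        )
    ranked = _ranked_other_tissues(series, target)
    values = series.to_dict()
    group = [target]
    group_sum = values[target]
    for size in range(2, thresholds.group_max_size + 1):
        nxt = ranked[size - 2]
        group.append(nxt)
        group_sum += values[nxt]
        if size < thresholds.group_min_size:
            continue
        outside = [values[t] for t in ranked[size - 1 :]]
        if thresholds.group_comparator == "max":
            level = max(outside)
        else:
            level = sum(outside) / len(outside)
        level = max(level, thresholds.ts_denominator_floor)
        if group_sum / size >= thresholds.group_fold * level:
            return frozenset(group)
    return None


def classify_gene(
    gene_profile,
    target: str,
    thresholds: Thresholds = Thresholds(),
    gene_id: str = "",
) -> GeneClassification:
    """Classify one gene's tissue profile against the target tissue.

    Rules are applied in precedence order (detection gate, highly enriched,
    moderately enriched, group enriched, enhanced, expressed in all, mixed);
    the first rule that fires decides the category.
    """
    series = _as_profile_series(gene_profile)
    if target not in series.index:
        raise DataError(f"target tissue {target!r} not in profile")
    if len(series) < 2:
        raise DataError("classification needs >= 2 tissues")

    target_fpkm = float(series[target])
    others = series.drop(target)
    max_other = float(others.max())
    second_tissue = min(t for t in others.index if others[t] == max_other)
    ts = target_fpkm / max(max_other, thresholds.ts_denominator_floor)
    n_detected = int((series >= thresholds.detection_limit).sum())

    def build(category: Category, group: frozenset[str] = frozenset()) -> GeneClassification:
        return GeneClassification(
            gene_id=gene_id,
            category=category,
            ts_score=ts,
            target_fpkm=target_fpkm,
            max_other_fpkm=max_other,
            second_tissue=second_tissue,
            enriched_group=group,
            n_detected_tissues=n_detected,
        )

    if target_fpkm < thresholds.detection_limit:
        return build(Category.NOT_DETECTED)
    if ts >= thresholds.high_enrichment_fold:
        return build(Category.HIGHLY_ENRICHED)
    if ts >= thresholds.enrichment_fold:
        return build(Category.MODERATELY_ENRICHED)
    group = find_enriched_group(series, target, thresholds)
    if group is not None:
        return build(Category.GROUP_ENRICHED, group)
    if target_fpkm >= thresholds.enhanced_fold * float(series.mean()):
        return build(Category.ENHANCED)
    if n_detected == len(series):
        return build(Category.EXPRESSED_IN_ALL)
    return build(Category.MIXED)


def classify_profile(
    profile: TissueProfile, target: str, thresholds: Thresholds = Thresholds()
) -> tuple[list[GeneClassification], CategoryTally]:
    """Classify every gene of a tissue profile; returns (classifications, tally).

    Gene order of the input is preserved.
    """
    if target not in profile.tissues:
        raise DataError(f"target tissue {target!r} not in profile")
    classifications = [
        classify_gene(profile.mean_fpkm.loc[gene], target, thresholds, gene_id=gene)
        for gene in profile.gene_ids
    ]
    return classifications, CategoryTally.from_classifications(classifications)


def mrna_pool_fractions(
    profile: TissueProfile,
    classifications: Sequence[GeneClassification],
    target: str,
) -> PoolFractions:
    """Share of the target tissue's total mRNA pool per top-level category group.

    The pool of a group is the sum of the target-tissue FPKM of its genes; the
    fractions are normalised by the total FPKM over all genes.
    """
    classified = {c.gene_id for c in classifications}
    missing = set(profile.gene_ids) - classified
    if missing:
        raise DataError(f"classifications missing for genes: {sorted(missing)[:5]}...")
    target_fpkm = profile.mean_fpkm[target]
    total = float(target_fpkm.sum())
    if total <= 0:
        raise DataError("total target-tissue FPKM is zero; pool fractions undefined")
    sums = {g: 0.0 for g in TOP_LEVEL_GROUPS}
    for c in classifications:
        sums[_top_level_group(c.category)] += float(target_fpkm[c.gene_id])
    return PoolFractions(
        fractions={g: sums[g] / total for g in TOP_LEVEL_GROUPS}, total_fpkm=total
    )


def top_expressed(
    profile: TissueProfile,
    target: str,
    classifications: Sequence[GeneClassification],
    n: int = 30,
) -> pd.DataFrame:
    """The *n* genes with the highest target-tissue FPKM, annotated with category.

    Ties are broken lexicographically by gene ID; asking for more genes than
    exist returns all of them.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    by_gene = {c.gene_id: c for c in classifications}
    target_fpkm = profile.mean_fpkm[target]
    order = sorted(profile.gene_ids, key=lambda g: (-target_fpkm[g], g))[:n]
    return pd.DataFrame(
        {
            "gene_id": order,
            "target_fpkm": [float(target_fpkm[g]) for g in order],
            "category": [by_gene[g].category.value if g in by_gene else "" for g in order],
        }
    )


def classifications_to_frame(
    classifications: Sequence[GeneClassification],
) -> pd.DataFrame:
    """Tabulate classifications (one row per gene) for reporting."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "category": [c.category.value for c in classifications],
            "ts_score": [c.ts_score for c in classifications],
            "target_fpkm": [c.target_fpkm for c in classifications],
            "max_other_fpkm": [c.max_other_fpkm for c in classifications],
            "second_tissue_name": [c.second_tissue for c in classifications],
            "enriched_group": [";".join(sorted(c.enriched_group)) for c in classifications],
            "n_detected_tissues": [c.n_detected_tissues for c in classifications],
        }
    )


def write_classification_table(
    classifications: Sequence[GeneClassification], path: str | Path
) -> None:
    classifications_to_frame(classifications).to_csv(path, sep="\t", index=False)
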