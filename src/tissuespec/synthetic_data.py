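"""Synthetic multi-tissue expression studies with planted ground truth.

Emulates a 27-tissue bulk RNA-seq compendium (four replicate samples per
tissue, log-normal replicate noise, detection floor at 1 FPKM) in which every
gene is planted to belong to a known specificity category, and a matching
coded-IHC annotation table in which a subset of the elevated genes is planted
with a unique nephron/collecting-duct compartment.  Because the planted
tissue-level means classify exactly as planted before noise is added, the
generator doubles as a noiseless oracle for the classifier.

Plant geometry (all folds are safely away from every category boundary so that
replicate noise of sigma(log2) <= 0.2 cannot flip a label):

* highly enriched: target = 100x the runner-up tissue (threshold 50).
* moderately enriched: target = 10x the runner-up (thresholds 5 and 50).
* group enriched: all group tissues at a common level, 10x the outside
  maximum (threshold 5); TS ~ 1 so the gene is never called enriched.
* enhanced: target = 3x a shoulder of seven tissues, remaining tissues near
  zero; this yields an enhanced fold of ~7.4 over the all-tissue mean.  The
  shoulder of seven blocks every allowed group size and keeps TS at 3; a
  full 2x margin over the enhanced threshold is mathematically incompatible
  with staying out of the enriched and group-enriched categories, so the
  geometry maximises margin subject to exclusivity instead.
* expressed in all: every tissue drawn within a narrow band (max/min < 2.7),
  which rules out every fold criterion at once.
* mixed: detected flat in 9-26 tissues including the target, silent in the
  rest; the >= 8 detected non-target tissues block all group sizes.
* not detected: target uniform in [0, 0.5 x detection floor]; the margin to
  the floor absorbs the worst-case replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .expression_io import ExpressionMatrix, SampleRecord
from .ihc_integration import IHCAnnotation, KIDNEY_COMPARTMENTS
from .specificity_classifier import Category, GeneClassification

__all__ = [
    "DEFAULT_TISSUES",
    "SimulationConfig",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_synthetic_study",
    "generate_synthetic_ihc",
    "evaluate_recovery",
]

#: Tissue panel of the emulated compendium (27 major human tissues/organs).
DEFAULT_TISSUES = (
    "adipose_tissue",
    "adrenal_gland",
    "appendix",
    "bone_marrow",
    "cerebral_cortex",
    "colon",
    "duodenum",
    "endometrium",
    "esophagus",
    "gallbladder",
    "heart_muscle",
    "kidney",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "pancreas",
    "placenta",
    "prostate",
    "salivary_gland",
    "skin",
    "small_intestine",
    "spleen",
    "stomach",
    "testis",
    "thyroid_gland",
    "urinary_bladder",
)

#: Gene counts per category matching the partition of a 20,050-gene
#: protein-coding annotation in a kidney-centred compendium.
DEFAULT_GENES_PER_CATEGORY: Mapping[Category, int] = {
    Category.NOT_DETECTED: 6365,
    Category.HIGHLY_ENRICHED: 20,
    Category.MODERATELY_ENRICHED: 44,
    Category.GROUP_ENRICHED: 156,
    Category.ENHANCED: 167,
    Category.EXPRESSED_IN_ALL: 9250,
    Category.MIXED: 4048,
}

#: Compartment plants among the elevated genes (148 in total, of which three
#: collecting-duct genes are confined to intercalated cells).
DEFAULT_COMPARTMENT_COUNTS: Mapping[str, int] = {
    "glomeruli": 11,
    "proximal_tubule": 120,
    "distal_tubule": 9,
    "collecting_duct": 8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic compendium."""

    n_tissues: int = 27
    replicates_per_tissue: int = 4
    target_tissue: str = "kidney"
    n_genes_per_category: Mapping[Category, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CATEGORY)
    )
    highly_enriched_fold: float = 100.0
    enriched_fold: float = 10.0
    group_fold: float = 10.0
    enhanced_shoulder_ratio: float = 3.0
    group_size_range: tuple[int, int] = (2, 7)
    noise_sd_log2: float = 0.2
    detection_floor: float = 1.0
    compartment_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_COUNTS)
    )
    intercalated_count: int = 3
    ihc_distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 10:
            raise ConfigError("need >= 10 tissues to plant every category")
        if self.replicates_per_tissue < 1:
            raise ConfigError("replicates_per_tissue must be >= 1")
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi):
            raise ConfigError("invalid group_size_range")
        if hi >= self.n_tissues:
            raise ConfigError("group sizes must be smaller than the tissue count")
        if any(n < 0 for n in self.n_genes_per_category.values()):
            raise ConfigError("gene counts must be non-negative")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if not (0 <= self.ihc_distractor_rate <= 1):
            raise ConfigError("ihc_distractor_rate must be in [0, 1]")
        unknown = set(self.compartment_counts) - set(KIDNEY_COMPARTMENTS)
        if unknown:
            raise ConfigError(f"unknown compartments: {sorted(unknown)}")
        if self.intercalated_count > self.compartment_counts.get("collecting_duct", 0):
            raise ConfigError("intercalated_count exceeds collecting-duct plants")

    @property
    def tissues(self) -> list[str]:
        names = list(DEFAULT_TISSUES[: self.n_tissues])
        for i in range(len(names), self.n_tissues):
            names.append(f"tissue_{i + 1:02d}")
        if self.target_tissue not in names:
            names[0] = self.target_tissue
        return sorted(names)

    @property
    def n_elevated(self) -> int:
        return sum(
            self.n_genes_per_category.get(cat, 0)
            for cat in (
                Category.HIGHLY_ENRICHED,
                Category.MODERATELY_ENRICHED,
                Category.GROUP_ENRICHED,
                Category.ENHANCED,
            )
        )


def scale_compartment_counts(
    counts: Mapping[str, int], n_elevated: int
) -> dict[str, int]:
    """Shrink compartment plants proportionally to fit a smaller elevated set.

    Keeps the default proportions (glomeruli : proximal : distal : collecting
    duct) while ensuring the total never exceeds *n_elevated*.  Counts are
    returned unchanged when they already fit.
    """
    total = sum(counts.values())
    if total <= n_elevated:
        return dict(counts)
    factor = n_elevated / total
    return {k: int(v * factor) for k, v in counts.items()}


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels for one synthetic gene."""

    gene_id: str
    true_category: Category
    true_group: frozenset[str] = frozenset()
    true_compartment: str | None = None
    intercalated_only: bool = False


def _plant_means(
    category: Category, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, frozenset[str]]:
    """Tissue-level mean FPKM for one gene of the given category.

    Returns the mean vector (aligned with ``config.tissues``) and, for
    group-enriched plants, the planted tissue group.
    """
    tissues = config.tissues
    n = len(tissues)
    target_idx = tissues.index(config.target_tissue)
    other_idx = np.array([i for i in range(n) if i != target_idx])
    means = np.zeros(n)
    group: frozenset[str] = frozenset()
    floor = config.detection_floor

    if category is Category.NOT_DETECTED:
        means[target_idx] = rng.uniform(0.0, 0.5 * floor)
        detected = rng.random(n - 1) < 0.5
        means[other_idx] = np.where(
            detected, 2.0 ** rng.uniform(2, 5, n - 1), rng.uniform(0.0, 0.5 * floor, n - 1)
        )
    elif category in (Category.HIGHLY_ENRICHED, Category.MODERATELY_ENRICHED):
        fold = (
            config.highly_enriched_fold
            if category is Category.HIGHLY_ENRICHED
            else config.enriched_fold
        )
        runner_up = 2.0 ** rng.uniform(1, 4)
        vals = np.empty(n - 1)
        vals[0] = runner_up
        vals[1:] = runner_up * rng.uniform(0.05, 1.0, n - 2)
        rng.shuffle(vals)  # runner-up lands in a random non-target tissue
        means[other_idx] = vals
        means[target_idx] = fold * runner_up
    elif category is Category.GROUP_ENRICHED:
        lo, hi = config.group_size_range
        size = int(rng.integers(lo, hi + 1))
        partners = rng.choice(other_idx, size=size - 1, replace=False)
        level = 2.0 ** rng.uniform(3, 6)
        outside_max = level / config.group_fold
        outside = np.array(sorted(set(other_idx) - set(partners)))
        means[outside] = outside_max * rng.uniform(0.1, 1.0, len(outside))
        means[outside[0]] = outside_max
        means[partners] = level
        means[target_idx] = level
        group = frozenset({config.target_tissue} | {tissues[i] for i in partners})
    elif category is Category.ENHANCED:
        shoulder = 2.0 ** rng.uniform(5, 7) / config.enhanced_shoulder_ratio
        shoulder_tissues = rng.choice(other_idx, size=7, replace=False)
        rest = np.array(sorted(set(other_idx) - set(shoulder_tissues)))
        means[target_idx] = config.enhanced_shoulder_ratio * shoulder
        means[shoulder_tissues] = shoulder
        means[rest] = 0.05 * shoulder * rng.uniform(0.5, 1.0, len(rest))
    elif category is Category.EXPRESSED_IN_ALL:
        # narrow band: max/min < 2.7, which defeats every 5-fold criterion
        means[:] = 2.0 ** rng.uniform(2.8, 4.2, n)
    elif category is Category.MIXED:
        n_detected_others = int(rng.integers(8, n - 1))
        detected = rng.choice(other_idx, size=n_detected_others, replace=False)
        silent = np.array(sorted(set(other_idx) - set(detected)))
        means[target_idx] = 2.0 ** rng.uniform(3.3, 3.7)
        means[detected] = 2.0 ** rng.uniform(3.3, 3.7, len(detected))
        means[silent] = rng.uniform(0.05, 0.2, len(silent))
    else:  # pragma: no cover - exhaustive over Category
        raise ConfigError(f"cannot plant category {category}")
    return means, group


def generate_synthetic_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], list[SyntheticTruth]]:
    """Generate an expression matrix, sample metadata and the planted truth.

    Replicate samples are drawn as ``mean * 2**N(0, noise_sd_log2)``.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tissues = config.tissues

    per_category: list[tuple[Category, np.ndarray, frozenset[str]]] = []
    for category in Category:
        for _ in range(config.n_genes_per_category.get(category, 0)):
            means, group = _plant_means(category, config, rng)
            per_category.append((category, means, group))
    if not per_category:
        raise ConfigError("no genes requested")

    order = rng.permutation(len(per_category))
    width = max(5, len(str(len(per_category))))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(len(per_category))]

    truths: list[SyntheticTruth] = []
    mean_rows = np.empty((len(per_category), len(tissues)))
    for row, src in enumerate(order):
        category, means, group = per_category[src]
        mean_rows[row] = means
        truths.append(
            SyntheticTruth(gene_id=gene_ids[row], true_category=category, true_group=group)
        )
    truths = _plant_compartments(truths, config, rng)

    sample_ids: list[str] = []
    samples: list[SampleRecord] = []
    columns = []
    for tissue in tissues:
        for rep in range(1, config.replicates_per_tissue + 1):
            sample_id = f"{tissue}_s{rep}"
            sample_ids.append(sample_id)
            samples.append(
                SampleRecord(sample_id=sample_id, tissue=tissue, individual=f"ind{rep}")
            )
            columns.append(tissues.index(tissue))

    noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, (len(gene_ids), len(sample_ids)))
    values = mean_rows[:, columns] * noise
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    return matrix, samples, truths


def _plant_compartments(
    truths: list[SyntheticTruth], config: SimulationConfig, rng: np.random.Generator
) -> list[SyntheticTruth]:
    """Assign planted compartments to a subset of the elevated genes."""
    elevated_idx = [
        i
        for i, t in enumerate(truths)
        if t.true_category
        in (
            Category.HIGHLY_ENRICHED,
            Category.MODERATELY_ENRICHED,
            Category.GROUP_ENRICHED,
            Category.ENHANCED,
        )
    ]
    needed = sum(config.compartment_counts.values())
    if needed == 0:
        return truths
    if needed > len(elevated_idx):
        raise ConfigError(
            f"cannot plant {needed} compartment genes among {len(elevated_idx)} elevated genes"
        )
    chosen = rng.choice(np.array(elevated_idx), size=needed, replace=False)
    pos = 0
    out = list(truths)
    for compartment in KIDNEY_COMPARTMENTS:
        count = config.compartment_counts.get(compartment, 0)
        for j in range(count):
            idx = int(chosen[pos])
            intercalated = compartment == "collecting_duct" and j < config.intercalated_count
            t = out[idx]
            out[idx] = SyntheticTruth(
                gene_id=t.gene_id,
                true_category=t.true_category,
                true_group=t.true_group,
                true_compartment=compartment,
                intercalated_only=intercalated,
            )
            pos += 1
    return out


def generate_synthetic_ihc(
    truths: Sequence[SyntheticTruth],
    config: SimulationConfig,
) -> list[IHCAnnotation]:
    """Coded IHC annotations consistent with the planted compartments.

    Genes with a planted compartment receive positive kidney annotations
    confined to that compartment (intercalated-only plants stain intercalated
    cells exclusively).  Elevated genes without a planted compartment stain two
    compartments, so they never yield a unique-compartment call.  With
    ``ihc_distractor_rate`` > 0, compartment genes additionally receive a
    positive annotation in a second compartment with that probability, which
    destroys their call and exercises the exclusivity filter.
    """
    rng = np.random.default_rng(config.seed + 1)
    annotations: list[IHCAnnotation] = []
    compartments = list(KIDNEY_COMPARTMENTS)
    elevated = (
        Category.HIGHLY_ENRICHED,
        Category.MODERATELY_ENRICHED,
        Category.GROUP_ENRICHED,
        Category.ENHANCED,
    )

    def stain(gene: str, antibody: int, cell_type: str) -> IHCAnnotation:
        return IHCAnnotation(
            gene_id=gene,
            antibody_id=f"AB_{gene}_{antibody}",
            tissue="kidney",
            cell_type=cell_type,
            fraction_score=int(rng.integers(2, 4)),
            intensity_score=int(rng.integers(2, 4)),
        )

    for truth in truths:
        if truth.true_compartment is not None:
            cell_type = (
                "collecting_duct_intercalated"
                if truth.intercalated_only
                else truth.true_compartment
            )
            annotations.append(stain(truth.gene_id, 1, cell_type))
            annotations.append(stain(truth.gene_id, 2, cell_type))
            if rng.random() < config.ihc_distractor_rate:
                other = [c for c in compartments if c != truth.true_compartment]
                annotations.append(stain(truth.gene_id, 3, str(rng.choice(other))))
        elif truth.true_category in elevated:
            pair = rng.choice(len(compartments), size=2, replace=False)
            annotations.append(stain(truth.gene_id, 1, compartments[int(pair[0])]))
            annotations.append(stain(truth.gene_id, 2, compartments[int(pair[1])]))
    return annotations


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion counts and per-category recall of planted labels."""

    confusion: pd.DataFrame  # true categories x predicted categories
    recall: pd.Series  # per true category, NaN when no genes planted

    @property
    def overall_accuracy(self) -> float:
        total = float(self.confusion.to_numpy().sum())
        correct = float(np.trace(self.confusion.to_numpy()))
        return correct / total if total else float("nan")

    @property
    def min_recall(self) -> float:
        return float(self.recall.dropna().min())


def evaluate_recovery(
    truths: Sequence[SyntheticTruth],
    predicted: Sequence[GeneClassification],
) -> RecoveryReport:
    """Compare predicted categories with the planted truth, gene by gene."""
    truth_by_gene = {t.gene_id: t for t in truths}
    pred_by_gene = {p.gene_id: p for p in predicted}
    if set(truth_by_gene) != set(pred_by_gene):
        raise DataError("truth and prediction cover different gene sets")
    labels = [c.value for c in Category]
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for gene, truth in truth_by_gene.items():
        confusion.loc[truth.true_category.value, pred_by_gene[gene].category.value] += 1
    planted = confusion.sum(axis=1)
    recall = pd.Series(
        np.where(planted > 0, np.diag(confusion) / planted.replace(0, 1), np.nan),
        index=labels,
        name="recall",
    )
    return RecoveryReport(confusion=confusion, recall=recall)
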