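"""End-to-end orchestration: I/O, averaging, classification, network, IHC, reports.

A run is configured either from real input files (expression TSV, sample
metadata, optional IHC annotations and reference lists) or from a synthetic
study with planted truth; the stages then run in a fixed order and every
report is written as TSV into the output directory.  All summary numbers are
recomputed from row-level data, and a tally that disagrees with the row-level
classifications fails hard — such a mismatch can only be an internal bug.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigError, ConsistencyError, TissuespecError
from .expression_io import (
    TissueProfile,
    average_by_tissue,
    pairwise_sample_correlation,
    read_expression_table,
    read_sample_metadata,
)
from .group_network import SharingNetwork, build_sharing_network, write_network_edgelist
from .ihc_integration import (
    CompartmentCall,
    ConcordanceReport,
    IHCAnnotation,
    assign_unique_compartment,
    compare_to_reference_sets,
    load_ihc_annotations,
    load_reference_list,
    restricted_expression_query,
)
from .specificity_classifier import (
    CategoryTally,
    GeneClassification,
    PoolFractions,
    Thresholds,
    classifications_to_frame,
    classify_profile,
    mrna_pool_fractions,
    top_expressed,
)
from .synthetic_data import (
    RecoveryReport,
    SimulationConfig,
    SyntheticTruth,
    evaluate_recovery,
    generate_synthetic_ihc,
    generate_synthetic_study,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "tally_report"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (one target tissue per run)."""

    target_tissue: str
    out_dir: str | Path = "tissuespec_out"
    expression_path: str | Path | None = None
    metadata_path: str | Path | None = None
    ihc_path: str | Path | None = None
    reference_list_paths: Sequence[str | Path] = ()
    synthetic: SimulationConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    top_n: int = 30
    network_max_partners: int = 3
    ihc_max_other_tissues: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_tissue:
            raise ConfigError("config field 'target_tissue' is required")
        real = self.expression_path is not None or self.metadata_path is not None
        if self.synthetic is not None and real:
            raise ConfigError("give either real input paths or a synthetic config, not both")
        if self.synthetic is None and not real:
            raise ConfigError("config needs expression_path+metadata_path or synthetic settings")
        if real and (self.expression_path is None or self.metadata_path is None):
            raise ConfigError("real-data mode needs both expression_path and metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            if "n_genes_per_category" in syn:
                from .specificity_classifier import Category

                syn["n_genes_per_category"] = {
                    Category(k): int(v) for k, v in syn["n_genes_per_category"].items()
                }
            kwargs["synthetic"] = SimulationConfig(**syn)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid config field: {exc}") from exc


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    classifications: list[GeneClassification]
    tally: CategoryTally
    pool_fractions: PoolFractions
    top_table: pd.DataFrame
    network: SharingNetwork
    profile: TissueProfile
    sample_correlation: pd.DataFrame
    summary: pd.DataFrame
    compartment_calls: list[CompartmentCall] = field(default_factory=list)
    concordance: ConcordanceReport | None = None
    reference_overlap: pd.DataFrame | None = None
    truths: list[SyntheticTruth] = field(default_factory=list)
    recovery: RecoveryReport | None = None
    log_lines: list[str] = field(default_factory=list)


def tally_report(
    tally: CategoryTally,
    calls: Sequence[CompartmentCall] = (),
    classifications: Sequence[GeneClassification] | None = None,
) -> pd.DataFrame:
    """Bookkeeping summary: per-category counts and every derived sum.

    Emits the seven per-category counts, the elevated sum, the four-way
    top-level partition with its total, and per-compartment call counts with
    their sum.  Every sum is recomputed from the addends.  When row-level
    *classifications* are supplied, the tally is cross-checked against them and
    any mismatch raises :class:`ConsistencyError` (an internal bug, never a
    data problem).
    """
    if classifications is not None:
        recomputed = CategoryTally.from_classifications(classifications)
        if recomputed.counts != tally.counts:
            raise ConsistencyError(
                "tally disagrees with row-level classifications: "
                f"{tally.counts} != {recomputed.counts}"
            )
    if calls:
        seen = [c.gene_id for c in calls]
        if len(seen) != len(set(seen)):
            raise ConsistencyError("a gene received more than one compartment call")
        if len(calls) > tally.elevated_count:
            raise ConsistencyError(
                f"{len(calls)} compartment calls exceed {tally.elevated_count} elevated genes"
            )

    rows: list[dict[str, object]] = []
    for cat, n in tally.counts.items():
        rows.append({"section": "category", "name": cat.value, "count": n})
    top = tally.top_level_counts
    rows.append({"section": "top_level", "name": "elevated", "count": tally.elevated_count})
    for group in ("not_detected_top_level", "mixed_top_level", "expressed_in_all_top_level"):
        rows.append({"section": "top_level", "name": group, "count": top[group.replace("_top_level", "")]})
    rows.append({"section": "derived", "name": "total_genes", "count": tally.total})

    per_compartment: dict[str, int] = {}
    intercalated = 0
    for call in calls:
        per_compartment[call.compartment] = per_compartment.get(call.compartment, 0) + 1
        if call.intercalated_only:
            intercalated += 1
    for compartment in sorted(per_compartment):
        rows.append(
            {"section": "compartment", "name": compartment, "count": per_compartment[compartment]}
        )
    if calls:
        rows.append(
            {"section": "derived", "name": "compartment_specific_total", "count": len(calls)}
        )
        rows.append(
            {"section": "derived", "name": "intercalated_only", "count": intercalated}
        )

    frame = pd.DataFrame(rows, columns=["section", "name", "count"])
    _check_summary(frame, tally, calls)
    return frame


def _check_summary(
    frame: pd.DataFrame, tally: CategoryTally, calls: Sequence[CompartmentCall]
) -> None:
    by_name = dict(zip(frame["name"], frame["count"]))
    if by_name["elevated"] != sum(
        by_name[c] for c in ("highly_enriched", "moderately_enriched", "group_enriched", "enhanced")
    ):
        raise ConsistencyError("elevated sum does not match its constituents")
    top = sum(
        by_name[g]
        for g in (
            "not_detected_top_level",
            "elevated",
            "mixed_top_level",
            "expressed_in_all_top_level",
        )
    )
    if top != by_name["total_genes"] or top != tally.total:
        raise ConsistencyError("top-level partition does not sum to the gene total")
    if calls and by_name.get("compartment_specific_total") != len(calls):
        raise ConsistencyError("compartment sum does not match the calls")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name in the message."""

    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TissuespecError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False

    return _StageContext()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write every report under ``config.out_dir``.

    Stage order: input -> averaging -> QC correlation -> classification ->
    pool fractions -> top-N -> network -> IHC integration -> reports.  The run
    is idempotent for fixed inputs and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"target_tissue\t{config.target_tissue}", f"seed\t{config.seed}"]
    log.append(f"thresholds\t{config.thresholds}")

    truths: list[SyntheticTruth] = []
    annotations: list[IHCAnnotation] = []
    with _stage("input"):
        if config.synthetic is not None:
            sim = config.synthetic
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            matrix, samples, truths = generate_synthetic_study(sim)
            annotations = generate_synthetic_ihc(truths, sim)
            log.append(f"input\tsynthetic n_genes={matrix.n_genes} n_samples={matrix.n_samples}")
        else:
            matrix = read_expression_table(config.expression_path)
            samples = read_sample_metadata(config.metadata_path)
            log.append(f"expression_sha256\t{_sha256(config.expression_path)}")
            log.append(f"metadata_sha256\t{_sha256(config.metadata_path)}")
            if config.ihc_path is not None:
                annotations = load_ihc_annotations(config.ihc_path)
                log.append(f"ihc_sha256\t{_sha256(config.ihc_path)}")

    with _stage("averaging"):
        profile = average_by_tissue(matrix, samples)
    with _stage("qc_correlation"):
        correlation = pairwise_sample_correlation(matrix)
    with _stage("classification"):
        classifications, tally = classify_profile(profile, config.target_tissue, config.thresholds)
    with _stage("pool_fractions"):
        pools = mrna_pool_fractions(profile, classifications, config.target_tissue)
    with _stage("top_expressed"):
        top_table = top_expressed(profile, config.target_tissue, classifications, n=config.top_n)
    with _stage("network"):
        network = build_sharing_network(
            classifications, config.target_tissue, max_partners=config.network_max_partners
        )

    calls: list[CompartmentCall] = []
    concordance = None
    overlap = None
    if annotations:
        with _stage("ihc_integration"):
            restricted = restricted_expression_query(
                annotations, config.target_tissue, config.ihc_max_other_tissues
            )
            calls = assign_unique_compartment(annotations)
            concordance = None
            if restricted:
                from .ihc_integration import rna_ihc_concordance

                concordance = rna_ihc_concordance(classifications, restricted)
            if config.reference_list_paths:
                references = {
                    Path(p).stem: load_reference_list(p) for p in config.reference_list_paths
                }
                overlap = compare_to_reference_sets(calls, references)

    recovery = None
    if truths:
        with _stage("recovery"):
            recovery = evaluate_recovery(truths, classifications)

    with _stage("reports"):
        summary = tally_report(tally, calls, classifications=classifications)
        classifications_to_frame(classifications).to_csv(
            out_dir / "classification.tsv", sep="\t", index=False
        )
        tally.to_series().to_csv(out_dir / "category_tally.tsv", sep="\t")
        pd.Series(pools.fractions, name="fraction").to_csv(
            out_dir / "pool_fractions.tsv", sep="\t"
        )
        top_table.to_csv(out_dir / "top_expressed.tsv", sep="\t", index=False)
        correlation.to_csv(out_dir / "sample_correlation.tsv", sep="\t")
        write_network_edgelist(
            network, out_dir / "network_nodes.tsv", out_dir / "network_edges.tsv"
        )
        summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        if calls:
            pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "compartment": c.compartment,
                        "intercalated_only": c.intercalated_only,
                    }
                    for c in calls
                ]
            ).to_csv(out_dir / "compartment_calls.tsv", sep="\t", index=False)
        if concordance is not None:
            concordance.to_series().to_csv(out_dir / "rna_ihc_concordance.tsv", sep="\t")
        if overlap is not None:
            overlap.to_csv(out_dir / "reference_overlap.tsv", sep="\t", index=False)
        if recovery is not None:
            recovery.confusion.to_csv(out_dir / "recovery_confusion.tsv", sep="\t")
            recovery.recall.to_csv(out_dir / "recovery_recall.tsv", sep="\t")
        (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")

    return ReportBundle(
        classifications=classifications,
        tally=tally,
        pool_fractions=pools,
        top_table=top_table,
        network=network,
        profile=profile,
        sample_correlation=correlation,
        summary=summary,
        compartment_calls=calls,
        concordance=concordance,
        reference_overlap=overlap,
        truths=truths,
        recovery=recovery,
        log_lines=log,
    )
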