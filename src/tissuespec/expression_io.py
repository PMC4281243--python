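"""Expression-table I/O, replicate averaging and sample-level QC.

The pipeline starts from a genes x samples table of FPKM values (fragments per
kilobase of exon model per million mapped reads) and a sample metadata table
mapping each sample to a tissue and an individual.  Replicate samples of a
tissue are collapsed by the arithmetic mean on the linear FPKM scale, and
sample quality is assessed with pairwise Spearman rank correlations across all
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DuplicateGeneError,
    MetadataError,
    MissingFileError,
    NegativeValueError,
    NonNumericValueError,
)

__all__ = [
    "SampleRecord",
    "ExpressionMatrix",
    "TissueProfile",
    "read_expression_table",
    "read_sample_metadata",
    "average_by_tissue",
    "pairwise_sample_correlation",
    "log2_with_pseudocount",
]


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: an RNA library from one tissue of one individual."""

    sample_id: str
    tissue: str
    individual: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise MetadataError("sample_id must be non-empty")
        if not self.tissue:
            raise MetadataError(f"sample {self.sample_id!r}: tissue must be non-empty")


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene IDs and
    whose columns hold unique sample IDs; every value is a finite non-negative
    float.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(f"duplicate gene IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MetadataError(f"duplicate sample IDs: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise NonNumericValueError("expression values must be numeric")
        if values.size:
            if not np.isfinite(values).all():
                raise NonNumericValueError("expression values must be finite (no NaN/inf)")
            if (values < 0).any():
                genes = self.data.index[(values < 0).any(axis=1)].tolist()
                raise NegativeValueError(f"negative FPKM for genes: {genes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class TissueProfile:
    """Per-tissue mean FPKM per gene (the object all classification rules read)."""

    mean_fpkm: pd.DataFrame  # genes x tissues
    n_samples_per_tissue: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_fpkm.index.has_duplicates:
            raise DuplicateGeneError("duplicate gene IDs in tissue profile")
        values = self.mean_fpkm.to_numpy()
        if values.size:
            if not np.isfinite(values).all():
                raise NonNumericValueError("tissue means must be finite")
            if (values < 0).any():
                raise NegativeValueError("tissue means must be non-negative")
        if self.n_samples_per_tissue is None:
            self.n_samples_per_tissue = pd.Series(1, index=self.mean_fpkm.columns)
        if (self.n_samples_per_tissue < 1).any():
            raise MetadataError("every tissue must be averaged over >= 1 sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_fpkm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.mean_fpkm.columns)

    def gene_profile(self, gene_id: str) -> pd.Series:
        return self.mean_fpkm.loc[gene_id]

    def to_tsv(self, path: str | Path) -> None:
        self.mean_fpkm.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table (header of sample IDs, first column gene IDs).

    Raises
    ------
    MissingFileError, NonNumericValueError, DuplicateGeneError, NegativeValueError
        Each malformed-input condition raises its own error class.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"expression table not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if frame.isna().any().any():
        raise NonNumericValueError(f"missing/non-numeric cells in {path}")
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return ExpressionMatrix(frame)


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV with columns sample_id, tissue, individual[, notes]."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"sample metadata not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "tissue", "individual"}
    missing = required - set(frame.columns)
    if missing:
        raise MetadataError(f"metadata missing columns: {sorted(missing)}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            tissue=row.tissue,
            individual=row.individual,
            notes=getattr(row, "notes", ""),
        )
        for row in frame.itertuples()
    ]
    ids = [r.sample_id for r in records]
    if len(ids) != len(set(ids)):
        raise MetadataError("duplicate sample_id in metadata")
    return records


def average_by_tissue(
    matrix: ExpressionMatrix, samples: Sequence[SampleRecord]
) -> TissueProfile:
    """Collapse replicate samples to tissue-level means (linear-scale arithmetic mean).

    Tissues are ordered lexicographically in the output.  Every sample column
    of *matrix* must be present in *samples*; metadata rows for samples absent
    from the matrix are ignored.
    """
    by_id: Mapping[str, SampleRecord] = {r.sample_id: r for r in samples}
    unknown = [s for s in matrix.sample_ids if s not in by_id]
    if unknown:
        raise MetadataError(f"samples missing from metadata: {unknown}")
    tissue_of = {s: by_id[s].tissue for s in matrix.sample_ids}
    grouped = matrix.data.T.groupby(matrix.data.columns.map(tissue_of))
    means = grouped.mean().T
    counts = grouped.size()
    order = sorted(means.columns)
    return TissueProfile(mean_fpkm=means[order], n_samples_per_tissue=counts[order])


def pairwise_sample_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Spearman rank correlation between every pair of samples, across all genes.

    Returns a square symmetric DataFrame with unit diagonal.  A constant sample
    (zero rank variance) yields NaN against every other sample rather than a
    silent 0.
    """
    if matrix.n_samples < 2:
        raise MetadataError("need >= 2 samples for pairwise correlation")
    if matrix.n_genes < 2:
        raise MetadataError("need >= 2 genes for pairwise correlation")
    import warnings

    with warnings.catch_warnings():
        # constant samples are reported as NaN entries, not warnings
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(matrix.data.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    else:
        rho = np.asarray(rho)
    np.fill_diagonal(rho, 1.0)
    # spearmanr propagates NaN for zero-variance columns; keep that behaviour
    return pd.DataFrame(rho, index=matrix.sample_ids, columns=matrix.sample_ids)


def log2_with_pseudocount(x, pseudocount: float = 1.0):
    """log2(x + pseudocount); the pseudo-count keeps zero FPKM finite.

    Accepts scalars or arrays; rejects negative input.
    """
    if pseudocount <= 0:
        raise NegativeValueError("pseudocount must be positive")
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise NegativeValueError("expression values must be non-negative")
    out = np.log2(arr + pseudocount)
    if np.isscalar(x) or (isinstance(x, (int, float)) and not isinstance(x, bool)):
        return float(out)
    return out
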