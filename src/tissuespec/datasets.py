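"""Bundled reference tables.

Ships the reference table of the 20 most highly kidney-enriched protein-coding
genes (ranked by tissue-specificity score), with their mean kidney FPKM, TS
score, main subcellular localisation and whether antibody-based profiling data
were available for the encoded protein.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_highly_enriched_reference",
    "count_slc_family",
    "count_antibody_available",
]


def load_highly_enriched_reference() -> pd.DataFrame:
    """The 20 most highly kidney-enriched genes, sorted by descending TS score."""
    ref = resources.files("tissuespec.data") / "highly_enriched_kidney_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def count_slc_family(table: pd.DataFrame) -> int:
    """Number of solute-carrier (SLC) family genes in a gene table."""
    return int(table["gene_name"].str.match(r"SLC\d").sum())


def count_antibody_available(table: pd.DataFrame) -> int:
    """Number of genes with antibody-based profiling data available."""
    return int((table["hpa_available"].str.lower() == "yes").sum())
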