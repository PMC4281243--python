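import pandas as pd
import pytest

from tissuespec.expression_io import ExpressionMatrix, SampleRecord, TissueProfile
from tissuespec.specificity_classifier import Category
from tissuespec.synthetic_data import SimulationConfig, generate_synthetic_study


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples (two kidney, one liver, one lung)."""
    frame = pd.DataFrame(
        {
            "kidney_s1": [4.0, 0.5, 100.0],
            "kidney_s2": [6.0, 0.7, 80.0],
            "liver_s1": [5.0, 2.0, 1.0],
            "lung_s1": [5.5, 3.0, 0.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def small_samples() -> list[SampleRecord]:
    return [
        SampleRecord("kidney_s1", "kidney", "ind1"),
        SampleRecord("kidney_s2", "kidney", "ind2"),
        SampleRecord("liver_s1", "liver", "ind1"),
        SampleRecord("lung_s1", "lung", "ind2"),
    ]


def make_profile(rows: dict[str, dict[str, float]]) -> TissueProfile:
    """Build a TissueProfile from {gene: {tissue: mean FPKM}}."""
    return TissueProfile(pd.DataFrame(rows).T)


@pytest.fixture(scope="session")
def planted_study():
    """A small noisy 27-tissue study with 15 genes per category (fixed seed)."""
    config = SimulationConfig(
        n_genes_per_category={c: 15 for c in Category},
        compartment_counts={"glomeruli": 3, "proximal_tubule": 10, "distal_tubule": 2, "collecting_duct": 2},
        intercalated_count=1,
        seed=42,
    )
    matrix, samples, truths = generate_synthetic_study(config)
    return config, matrix, samples, truths
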