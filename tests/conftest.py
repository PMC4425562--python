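import numpy as np
import pytest

from siderosig import (
    CohortDesign,
    ExpressionCohort,
    TranscriptModel,
    generate_expression_cohort,
)


@pytest.fixture
def tiny_cohort() -> ExpressionCohort:
    """3 genes x 6 samples, two groups of three, deterministic values."""
    rng = np.random.default_rng(42)
    values = rng.normal(7.0, 1.0, size=(3, 6))
    samples = [f"S{i}" for i in range(6)]
    groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(samples)}
    return ExpressionCohort(
        genes=["g1", "g2", "g3"], samples=samples, values=values, groups=groups
    )


@pytest.fixture
def null_cohort():
    """2000-gene two-group cohort with no planted effect."""
    design = CohortDesign(
        group_sizes={"RARS": 30, "CTRL": 31},
        n_genes=2000,
        n_planted=0,
        effect_log2=0.0,
        noise_sd=0.7,
        seed=11,
    )
    cohort, truth = generate_expression_cohort(design)
    return cohort, truth


@pytest.fixture
def planted_cohort():
    """100 genes shifted by 2 log2 units in the RARS group (30 vs 31)."""
    design = CohortDesign(
        group_sizes={"RARS": 30, "CTRL": 31},
        n_genes=2000,
        n_planted=100,
        effect_log2=2.0,
        noise_sd=0.7,
        seed=12,
        planted_group="RARS",
    )
    cohort, truth = generate_expression_cohort(design)
    return cohort, truth


@pytest.fixture
def toy_model() -> TranscriptModel:
    """Met-Val-Arg-stop CDS on a single forward-strand exon at 101..112."""
    return TranscriptModel(
        gene="TOY",
        chrom="chrT",
        strand="+",
        cds_intervals=[(101, 112)],
        cds_sequence="ATGGTTCGTTAA",
    )


@pytest.fixture
def toy_model_minus() -> TranscriptModel:
    """The same CDS placed on the minus strand (genomic seq is its revcomp)."""
    return TranscriptModel(
        gene="TOYM",
        chrom="chrM",
        strand="-",
        cds_intervals=[(201, 212)],
        cds_sequence="ATGGTTCGTTAA",
    )
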