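import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from l1scope import (
    CompositionProfile,
    CodingCategory,
    analyze_reads,
    build_toy_consensus,
    build_toy_genome,
    simulate_library,
)


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_consensus(scale=0.25, seed=1)


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome(seed=2)


@pytest.fixture(scope="session")
def balanced_profile():
    """Profile with every category well represented, for round-trip tests."""
    return CompositionProfile(
        category_fractions={
            CodingCategory.ORF1_ONLY: 15.0,
            CodingCategory.ORF2_ONLY: 10.0,
            CodingCategory.ORF2P_ONLY: 10.0,
            CodingCategory.ORF1_ORF2P: 10.0,
            CodingCategory.ORF1_ORF2: 10.0,
            CodingCategory.NONCODING: 45.0,
        },
        sense_pct=70.0,
        utr5_pct=40.0,
        yy1_pct=20.0,
        flank_pcts={"INTRAGENIC": 40.0, "INTERGENIC": 10.0, "NONE_OR_UNMAPPED": 50.0},
    )


@pytest.fixture(scope="session")
def balanced_library(toy_model, toy_genome, balanced_profile):
    return simulate_library(toy_model, toy_genome, profile=balanced_profile, n=400, seed=3, error_rate=0.0)


@pytest.fixture(scope="session")
def balanced_result(toy_model, toy_genome, balanced_library):
    return analyze_reads(balanced_library.reads, toy_model, toy_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
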