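import numpy as np
import pytest

from plastidrive import PlastomeAlignment
from plastidrive.simulate import PlastomeSimConfig, simulate_plastome_set


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


@pytest.fixture
def toy_alignment():
    """Hand-built alignment: reference plus three samples with known
    substitutions, deletions and insertions."""
    #           1234 567 890  (reference positions; '-' = ref gap)
    ref = "ACGT-ACG-TAC"
    s1 = "ACGTAACGGTAC"  # insertions after pos 4 and pos 7
    s2 = "TCGT-A-G-TAC"  # sub at pos 1, deletion at pos 6
    s3 = "ACGT-ACG-TAC"  # identical to reference
    return PlastomeAlignment(
        sample_ids=["ref", "s1", "s2", "s3"],
        rows=[ref, s1, s2, s3],
        reference_id="ref",
        annotations=[("geneA", 2, 5, "+"), ("geneB", 8, 10, "-")],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One seeded plastome simulation shared across read-only tests."""
    return simulate_plastome_set(PlastomeSimConfig(seed=42))
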