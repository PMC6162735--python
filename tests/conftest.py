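import numpy as np
import pytest

from retroquant.synthcohort import (CohortConfig, RepeatFamilySpec,
                                    simulate_cohort)


def small_specs(n_families: int = 6, consensus_length: int = 500,
                n_contigs: int = 2) -> list[RepeatFamilySpec]:
    lineages = ["Chromovirus", "Athila", "AleII", "Angela", "Maximus/SIRE",
                "TAR/Tork"]
    return [RepeatFamilySpec(f"FAM{i + 1:02d}", lineages[i % len(lineages)],
                             consensus_length=consensus_length,
                             n_contigs=n_contigs)
            for i in range(n_families)]


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete cohort shared by read-level tests."""
    cfg = CohortConfig(
        n_wild=3, n_cultivated=3,
        families=small_specs(5),
        base_copy_number=30,
        fold_change={"FAM01": 2.5, "FAM02": 0.4},
        gene_adjacent_fraction=0.2,
        n_genes=60, coverage=3000,
        background_length=120_000, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
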