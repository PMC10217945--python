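import numpy as np
import pandas as pd
import pytest

from cubkit.genetic_code import AA_TO_CODONS, CODONS, DEGENERATE_AA
from cubkit.sequence_io import CodonSeq
from cubkit.synthetic_data import SimulationConfig, simulate_cds


def random_count_table(rng: np.random.Generator, mean_total: int = 300) -> pd.Series:
    """Random 64-codon count vector (Poisson per codon, stops sparse)."""
    counts = rng.poisson(mean_total / 64, size=64)
    return pd.Series(counts, index=list(CODONS))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest default-condition synthetic panel shared across tests."""
    cfg = SimulationConfig(n_genes=120, seed=11)
    return simulate_cds(cfg)


@pytest.fixture(scope="session")
def uniform_codon_seq():
    """Every synonymous codon exactly 10 times (maximally even usage)."""
    from cubkit.genetic_code import SYNONYMOUS_CODONS

    return CodonSeq("uniform", tuple(SYNONYMOUS_CODONS) * 10)


@pytest.fixture(scope="session")
def one_codon_per_aa_seq():
    """One fixed codon per degenerate amino acid, five times each."""
    codons = tuple(
        AA_TO_CODONS[aa][0] for aa in DEGENERATE_AA for _ in range(5)
    )
    return CodonSeq("maxbias", codons)
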