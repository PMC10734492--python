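import numpy as np
import pandas as pd
import pytest

from micronet.preprocess import CountTable
from micronet.synthetic_data import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One full-size synthetic cohort shared across read-only tests."""
    return generate_study(SyntheticConfig(seed=11))


@pytest.fixture()
def toy_table():
    """4 samples x 3 taxa toy table with hand-set counts."""
    counts = pd.DataFrame(
        [[5, 0, 3], [2, 0, 0], [7, 0, 1], [1, 0, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C"],
    )
    lineages = pd.Series(
        {
            "A": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Blautia; s__",
            "B": "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__Roseburia; s__",
            "C": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Rikenellaceae; g__; s__",
        }
    )
    return CountTable(counts, lineages)


@pytest.fixture()
def cluster_counts():
    """6-taxon counts with 3 nearly proportional taxa: small subsamples of
    this table frequently drive the exclusion loop into a singular basis
    system (used to exercise the redraw logic)."""
    rng = np.random.default_rng(0)
    n = 24
    base = np.exp(rng.normal(4, 1.2, n))
    counts = np.empty((n, 6))
    for j in range(3):
        counts[:, j] = base * np.exp(rng.normal(0, 0.3, n))
    for j in range(3, 6):
        counts[:, j] = np.exp(rng.normal(4, 1.2, n))
    return np.round(counts * 50).astype(np.int64) + 1
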