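import numpy as np
import pandas as pd
import pytest

from indelssr import SimConfig, simulate_cohort, simulate_genome, simulate_traits
from indelssr.band_matrix import BandMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """40 individuals, 30 markers: enough structure for diversity tests."""
    cfg = SimConfig(seed=11, n_individuals=40, n_markers=30, missing_rate=0.0)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_genome_sim():
    cfg = SimConfig(seed=13, n_chromosomes=2, chrom_len=30_000,
                    n_indels_per_chromosome=12)
    return cfg, simulate_genome(cfg)


@pytest.fixture()
def toy_band_matrix():
    """10 individuals, 1 biallelic marker: 4x(b1,b1), 4x(b1,b2), 2x(b2,b2).

    Hand-derivable: p = (0.6, 0.4), Ho = 0.4, He = 0.48, PIC = 0.3648.
    """
    inds = [f"i{k}" for k in range(10)]
    b1 = [1, 1, 1, 1, 1, 1, 1, 1, 0, 0]
    b2 = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
    scores = pd.DataFrame(
        np.array([b1, b2], dtype=float),
        index=pd.MultiIndex.from_tuples(
            [("m1", "b1"), ("m1", "b2")], names=["marker_id", "band_id"]
        ),
        columns=inds,
    )
    return BandMatrix(scores=scores)
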