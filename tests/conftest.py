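import numpy as np
import pandas as pd
import pytest

import strandtools as st


@pytest.fixture(scope="session")
def small_lengths():
    return {"chr1": 5_000_000, "chr2": 4_000_000, "chr3": 3_000_000}


@pytest.fixture(scope="session")
def clean_config(small_lengths):
    """Noiseless three-chromosome experiment, no planted features."""
    return st.SimConfig(chrom_lengths=small_lengths, n_libraries=6,
                        mean_reads=12_000, background=0.0, seed=101)


@pytest.fixture(scope="session")
def clean_library(clean_config):
    reads, truth = st.simulate_library(clean_config, 0)
    return reads, truth


def make_counts(per_chrom, bin_size=200_000, library_id="libT"):
    """Build a BinnedCounts directly from {chrom: (W array, C array)}."""
    watson = {c: np.asarray(w, dtype=np.int64) for c, (w, _) in per_chrom.items()}
    crick = {c: np.asarray(cc, dtype=np.int64) for c, (_, cc) in per_chrom.items()}
    lengths = {c: len(w) * bin_size for c, w in watson.items()}
    return st.BinnedCounts(bin_size=bin_size, watson=watson, crick=crick,
                           chrom_lengths=lengths, library_id=library_id)
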