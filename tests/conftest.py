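import numpy as np
import pandas as pd
import pytest

from hiftargets import (
    AnalysisConfig,
    DifferentialComparison,
    GeneModel,
    Genome,
    Peak,
    SimulationParams,
)


@pytest.fixture
def genome():
    return Genome((("chrI", 1000), ("chrII", 2000)))


@pytest.fixture
def gene():
    return GeneModel("g1", "chrI", "+", 100)


@pytest.fixture
def config():
    return AnalysisConfig(seed=0)


@pytest.fixture
def small_params():
    """A reduced regulome used by tests that only need structure, not power."""
    return SimulationParams(
        n_chromosomes=3,
        chromosome_length_bp=500_000,
        n_genes=200,
        n_direct_targets=5,
        n_decoy_peaks=20,
        n_hot_loci=5,
        n_tfs=18,
        tf_peaks_per_tf=40,
        seed=11,
    )


def make_comparison(label, gene_ids, raw_p, log2fc=None, fdr=None):
    """Build a DifferentialComparison from plain lists."""
    from hiftargets.loa import benjamini_hochberg

    raw_p = np.asarray(raw_p, dtype=float)
    if log2fc is None:
        log2fc = np.ones_like(raw_p)
    if fdr is None:
        fdr = benjamini_hochberg(raw_p)
    df = pd.DataFrame(
        {"gene_id": list(gene_ids), "log2fc": np.asarray(log2fc, dtype=float),
         "raw_p": raw_p, "fdr": np.asarray(fdr, dtype=float)}
    )
    return DifferentialComparison(label, df)
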