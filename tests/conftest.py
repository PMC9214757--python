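import numpy as np
import pandas as pd
import pytest

from hicogeny.core import BinTable, ContactMatrix
from hicogeny import matrixio, simdata


def make_bins(n_bins, bin_size=40_000, chroms=("chr1",)):
    """Equal-sized chromosomes of n_bins bins each."""
    return BinTable.from_chrom_lengths(
        [(c, n_bins * bin_size) for c in chroms], bin_size
    )


def symmetric_matrix(values, bins=None, kind="raw", **kw):
    v = np.asarray(values)
    if bins is None:
        bins = make_bins(v.shape[0])
    return ContactMatrix(bins, v, kind=kind, **kw)


@pytest.fixture(scope="session")
def biased_sim():
    """500-bin single-chromosome map with planted biases, no structure."""
    cfg = simdata.SimulationConfig(
        chrom_lengths=[("chr1", 500 * 40_000)], bias_log_sd=0.3, seed=11
    )
    return simdata.simulate_contact_map(cfg)


@pytest.fixture(scope="session")
def checkerboard_sim():
    """500-bin map with a planted g = ln 2 checkerboard in 10-bin blocks."""
    cfg = simdata.SimulationConfig(
        chrom_lengths=[("chr1", 500 * 40_000)],
        compartment_contrast=1.0,
        compartment_track="auto-blocks",
        block_size_bins=10,
        seed=7,
    )
    return simdata.simulate_contact_map(cfg)


@pytest.fixture(scope="session")
def tad_sim():
    """500-bin map with planted 20-bin TADs (tau = 3) separated by gaps."""
    tad_list = [("chr1", s, s + 20) for s in range(5, 475, 25)]
    cfg = simdata.SimulationConfig(
        chrom_lengths=[("chr1", 500 * 40_000)],
        tad_intervals=tad_list,
        tad_enrichment=3.0,
        seed=5,
    )
    return simdata.simulate_contact_map(cfg)


@pytest.fixture(scope="session")
def balanced_tad_sim(tad_sim):
    m, bins, truth = tad_sim
    balanced, biases = matrixio.ice_normalize(m)
    return balanced, bins, truth
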