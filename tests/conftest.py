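"""Shared fixtures: one small synthetic cohort reused across test modules."""

import numpy as np
import pytest

from gcovpipe import compute_grm, simulate_annotation, simulate_genotypes
from gcovpipe.datatypes import GenotypePanel
from gcovpipe.synthetic_data import default_spec, simulate_longitudinal_traits


@pytest.fixture(scope="session")
def small_panel():
    return simulate_genotypes(300, 800, 0.05, 0.5, seed=11)


@pytest.fixture(scope="session")
def annotation(small_panel):
    # long genes so that +/-50 kb windows catch a workable share of the panel
    return simulate_annotation(small_panel, 60, 2_000_000, seed=12)


@pytest.fixture(scope="session")
def cohort(small_panel, annotation):
    spec = default_spec(seed=13, n_causal=200)
    table, truth = simulate_longitudinal_traits(small_panel, spec, annotation,
                                                return_truth=True)
    return spec, table, truth


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return compute_grm(small_panel)


def make_panel(dosages, positions=None, chrom=None, freqs=None):
    """Hand-built panel for boundary-arithmetic tests."""
    import pandas as pd

    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 1000
    chrom = chrom if chrom is not None else np.ones(m, int)
    freqs = freqs if freqs is not None else np.full(m, 0.5)
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": chrom,
        "pos": positions,
        "allele_ref": "A",
        "allele_alt": "G",
        "allele_freq": freqs,
    })
    return GenotypePanel([f"i{j}" for j in range(n)], snps, dosages)
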