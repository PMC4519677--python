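"""Shared fixtures: a small simulated species panel and helpers."""

import pytest

from barcodekit.alignment import progressive_msa
from barcodekit.synthetic_data import SimParams, simulate_species_set


@pytest.fixture(scope="session")
def panel():
    """Seven species x three genotypes, the default study regime."""
    return simulate_species_set(SimParams(seed=2024))


@pytest.fixture(scope="session")
def small_panel():
    """Four species x two genotypes over 300 bp: fast alignment tests."""
    return simulate_species_set(SimParams(
        n_species=4, n_per_species=2, seq_length=300,
        d_inter=0.02, d_intra=0.0, n_planted_diagnostic=2, seed=7))


@pytest.fixture(scope="session")
def small_alignment(small_panel):
    return progressive_msa(small_panel.sequences, small_panel.species_of)
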