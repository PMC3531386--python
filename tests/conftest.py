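import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/helpers.py

import svmix


@pytest.fixture(scope="session")
def small_sim():
    """A mid-size simulated dataset shared by end-to-end tests: 4 Mb with
    the default event density scaled down proportionally."""
    cfg = svmix.SimConfig(
        genome_length=4_000_000,
        n_deletions=40, n_hom_del=20, n_het_del=20,
        n_inversions=40,
        n_decoy_deletions=15, n_decoy_inversions=16,
        seed=5,
    )
    truth, pairs = svmix.simulate(cfg)
    return cfg, truth, pairs


@pytest.fixture(scope="session")
def no_event_sim():
    """Variant-free emulated alignments (pure insert-size behavior)."""
    cfg = svmix.SimConfig(
        genome_length=600_000,
        n_deletions=0, n_hom_del=0, n_het_del=0, n_inversions=0,
        n_decoy_deletions=0, n_decoy_inversions=0,
        seed=7,
    )
    truth, pairs = svmix.simulate(cfg)
    assert truth == []
    return cfg, pairs
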