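"""Shared fixtures: one small simulated dataset reused across modules."""

import pytest

from retroepi import simdata


@pytest.fixture(scope="session")
def small_sim():
    """30 full-length L1s on two chromosomes, decoys, one in-frame chimera."""
    cfg = simdata.SimConfig(seed=11, n_l1=30, n_escapees=5)
    return simdata.build_genome(cfg)


@pytest.fixture(scope="session")
def frameshift_sim():
    """Same layout with the 4 bp deletion in the chimera's unique cassette."""
    cfg = simdata.SimConfig(seed=11, n_l1=6, n_escapees=0,
                            chimera_in_frame=False)
    return simdata.build_genome(cfg)
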