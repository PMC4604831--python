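"""Shared fixtures: small demographies and deterministic study fixtures."""

import numpy as np
import pytest

from quartetcoal.demography import (Demography, SampleDesign, Outgroup,
                                    flycatcher_demography)


@pytest.fixture(scope="session")
def mle_demography():
    """Flycatcher preset at the published composite-likelihood estimates."""
    return flycatcher_demography("PA_C_S", "mle")


@pytest.fixture(scope="session")
def mle_demography_no_og():
    return flycatcher_demography("PA_C_S", "mle", outgroups=())


@pytest.fixture(scope="session")
def strong_signal_demography():
    """Deep splits, no migration: topology recovery is easy (low ILS)."""
    ne = {sp: 100_000 for sp in "CPAS"}
    pa = frozenset("PA")
    pac = frozenset("PAC")
    root = frozenset("CPAS")
    return Demography(
        topology=((("P", "A"), "C"), "S"),
        ne_current=ne,
        ne_ancestral={pa: 100_000, pac: 100_000, root: 100_000},
        split_times={pa: 1_000_000, pac: 2_000_000, root: 3_000_000},
        migration={},
        mu=2.5e-9,
        outgroups=(Outgroup("O1", 5_000_000, 200_000),
                   Outgroup("O2", 6_000_000, 200_000)),
    )


@pytest.fixture(scope="session")
def tiny_study(mle_demography):
    """A small complete synthetic study used across popgen tests."""
    from quartetcoal import simulate
    design = SampleDesign(haplotypes_per_species=6, n_loci=5,
                          locus_length=2000, include_outgroups=True, seed=11)
    return simulate.emit_study(mle_demography, design)
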