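"""Shared fixtures: one mid-sized simulated community reused across tests.

Simulation sizes here are chosen so the whole suite stays within a few
minutes on one CPU while keeping per-member coverage deep enough (>= 25x
for the rarest member) for consensus accuracy.
"""

from __future__ import annotations

import pytest
from Bio.Seq import Seq

from otuasm import (OlcParams, PrimerSpec, ReadSimConfig, ReferenceSet,
                    generate_community, olc_assemble, simulate_reads,
                    trim_reads)
from otuasm.simulate import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER


@pytest.fixture(scope="session")
def community():
    """The 20-member validation community analog (seed 1)."""
    return generate_community(n=20, length_nt=552, identity_min=60.0,
                              identity_max=96.0, synonymous_pair=True, seed=1)


@pytest.fixture(scope="session")
def community_refs(community):
    return ReferenceSet(records=list(community.members), alphabet="nt")


@pytest.fixture(scope="session")
def community_prot_refs(community):
    return ReferenceSet(
        records=[(n, str(Seq(s).translate())) for n, s in community.members],
        alphabet="aa")


@pytest.fixture(scope="session")
def primer_spec():
    return PrimerSpec(DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER)


@pytest.fixture(scope="session")
def simulated(community, primer_spec):
    """2000 reads at 0.5% substitution error, primer-trimmed, with truth."""
    cfg = ReadSimConfig(n_reads=2000, sub_rate=0.005, seed=5)
    reads, truth = simulate_reads(community, cfg, ["libA"])
    trimmed, _ = trim_reads(reads, primer_spec)
    return trimmed, truth


@pytest.fixture(scope="session")
def assembled(simulated):
    """OLC assembly of the shared simulated read set at default parameters."""
    trimmed, truth = simulated
    otus, unassembled = olc_assemble(trimmed, OlcParams())
    return otus, unassembled, trimmed, truth
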