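"""Assemble simulated reads into OTUs with the greedy OLC engine.

Every read is either tracked into exactly one OTU or reported unassembled;
each OTU consensus should match one community member at ~100% identity.
"""

from otuasm import (OlcParams, PrimerSpec, ReadSimConfig, generate_community,
                    olc_assemble, pairwise_identity, simulate_reads,
                    trim_reads)
from otuasm import revcomp
from otuasm.simulate import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER

community = generate_community(n=20, length_nt=552, identity_min=60.0,
                               identity_max=96.0, synonymous_pair=True,
                               seed=1)
reads, truth = simulate_reads(
    community, ReadSimConfig(n_reads=2000, sub_rate=0.005, seed=1), ["libA"])
trimmed, _ = trim_reads(reads, PrimerSpec(DEFAULT_FWD_PRIMER,
                                          DEFAULT_REV_PRIMER))

otus, unassembled = olc_assemble(
    trimmed, OlcParams(min_overlap_len=100, min_overlap_identity=90.0))
print(f"{len(otus)} OTUs, {len(unassembled)} unassembled reads "
      f"of {len(trimmed)}")

members = dict(community.members)
for otu in otus[:5]:
    best = max(members, key=lambda n: max(
        pairwise_identity(otu.consensus, members[n]),
        pairwise_identity(revcomp(otu.consensus), members[n])))
    ident = max(pairwise_identity(otu.consensus, members[best]),
                pairwise_identity(revcomp(otu.consensus), members[best]))
    print(f"  {otu.id}: {len(otu.consensus)} nt, {len(otu.tracked_reads)} "
          f"reads, best match {best} at {ident:.1f}%")
# 20 OTUs at ~100% identity means the assembler resolved every member,
# including the 96%-identical pair, from reads alone.
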