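"""Sweep the de Bruijn graph k-mer length and count members recovered.

Longer k-mers disentangle similar templates: member recovery rises with k,
but the DBG engine cannot track reads, so abundance must come from mapping.
"""

from otuasm import (DbgParams, PrimerSpec, ReadSimConfig, ReferenceSet,
                    dbg_assemble, generate_community, simulate_reads,
                    trim_reads, watered_blast_identity)
from otuasm.simulate import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER

community = generate_community(n=20, length_nt=552, identity_min=60.0,
                               identity_max=96.0, synonymous_pair=True,
                               seed=1)
reads, _ = simulate_reads(
    community, ReadSimConfig(n_reads=2000, sub_rate=0.005, seed=1), ["libA"])
trimmed, _ = trim_reads(reads, PrimerSpec(DEFAULT_FWD_PRIMER,
                                          DEFAULT_REV_PRIMER))
refs = ReferenceSet(records=list(community.members), alphabet="nt")

print("k    contigs  members recovered (of 20)")
for k in (10, 15, 21, 27, 31):
    contigs = dbg_assemble(trimmed, DbgParams(k=k))
    recovered = set()
    for c in contigs:
        for h in watered_blast_identity(c.seq, refs):
            if h.identity >= 97.0:
                recovered.add(h.ref_id)
    print(f"{k:<5}{len(contigs):<9}{len(recovered)}")
# Short k-mers are shared between similar members and tangle the graph;
# recovery approaches (but here does not reach) the OLC engine's 20.
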