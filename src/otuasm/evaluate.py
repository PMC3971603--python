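"""Assembly and tracking quality assessment.

watered_blast_identity is a fast identity screen in the WateredBLAST mould:
candidate references are short-listed by shared k-mer counts, then scored by
exact Smith-Waterman; identity is matches / alignment columns over the
optimal local alignment.  The profile comparison reports total variation
distance (half the L1 distance) between estimated and true compositions,
member recovery at a 97% identity threshold, and the unmapped fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._align import (KmerIndex, alignment_identity, alignment_target_span,
                     local_aligner, revcomp)
from .io import ReferenceSet
from .mapping import AbundanceTable, Assignment
from .simulate import CommunityTruth

RECOVERY_IDENTITY = 97.0


@dataclass
class WateredBlastHit:
    ref_id: str
    identity: float
    strand: str
    ref_start: int
    ref_end: int


@dataclass
class OtuQuality:
    otu_id: str
    nearest_ref: str | None
    nearest_identity: float
    sensitivity: float | None  # None = undefined (zero denominator)
    specificity: float | None


@dataclass
class ProfileComparison:
    l1_error: float  # total variation distance in [0, 1]
    members_recovered: int
    unmapped_fraction: float
    member_estimates: dict[str, float]
    otu_to_member: dict[str, str]


_LOCAL = local_aligner(gap=-2.0)


def watered_blast_identity(query: str, refs: ReferenceSet, k: int = 8,
                           top: int = 20, min_columns: int | None = None
                           ) -> list[WateredBlastHit]:
    """Best local-alignment identity of query against a reference set.

    Returns every reference attaining the maximum identity (ties kept,
    ranked by alignment length), with strand and the aligned span on the
    reference.  Alignments shorter than min_columns (default: half the
    query) are ignored so that a tiny perfect match can never outrank a
    long, slightly imperfect one.  Queries with no k-mer candidates (e.g.
    all-N) return an empty list with a warning.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    if min_columns is None:
        min_columns = max(1, len(query) // 2)
    seqs = [s for _, s in refs.records]
    ids = [r for r, _ in refs.records]
    index = KmerIndex(seqs, k)
    cands: list[tuple[int, int, str]] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        for idx, cnt in index.candidate_counts(q).items():
            cands.append((cnt, idx, strand))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    cands = cands[:top]
    if not cands:
        warnings.warn("query shares no k-mers with any reference; no hits",
                      stacklevel=2)
        return []
    hits: list[tuple[WateredBlastHit, int]] = []
    for _, idx, strand in cands:
        q = query if strand == "+" else revcomp(query)
        aln = _LOCAL.align(seqs[idx], q)[0]
        ident, columns, _ = alignment_identity(aln)
        if columns < min_columns:
            continue
        start, end = alignment_target_span(aln)
        hits.append((WateredBlastHit(ids[idx], ident, strand, start, end),
                     columns))
    if not hits:
        return []
    best = max(h.identity for h, _ in hits)
    out = [(h, c) for h, c in hits if abs(h.identity - best) < 1e-9]
    # one hit per reference id (longest alignment, then '+' strand first);
    # ties across references ordered by alignment length then id
    out.sort(key=lambda t: (-t[1], t[0].ref_id, t[0].strand))
    seen: dict[str, WateredBlastHit] = {}
    for h, _ in out:
        seen.setdefault(h.ref_id, h)
    return list(seen.values())


def nearest_reference(query: str, refs: ReferenceSet) -> tuple[str | None, float]:
    hits = watered_blast_identity(query, refs)
    if not hits:
        return None, 0.0
    return hits[0].ref_id, hits[0].identity


def otu_sn_sp(otu_id: str, source: str | None,
              assignments: list[Assignment],
              read_sources: dict[str, str],
              nearest_identity: float = 100.0) -> OtuQuality:
    """Per-OTU sensitivity and specificity against per-read truth labels.

    With t the OTU's source: Sn = reads from t in this OTU / all reads from
    t; Sp = reads from t in this OTU / all reads in this OTU.  Zero
    denominators yield None, never a division error.
    """
    in_otu = [a for a in assignments if a.otu_id == otu_id]
    from_t_total = sum(1 for s in read_sources.values() if s == source)
    from_t_in_otu = sum(1 for a in in_otu
                        if read_sources.get(a.read_id) == source)
    sn = from_t_in_otu / from_t_total if from_t_total else None
    sp = from_t_in_otu / len(in_otu) if in_otu else None
    return OtuQuality(otu_id=otu_id, nearest_ref=source,
                      nearest_identity=nearest_identity,
                      sensitivity=sn, specificity=sp)


def evaluate_otus(otus: list[tuple[str, str]], assignments: list[Assignment],
                  truth: CommunityTruth) -> list[OtuQuality]:
    """Sn/Sp for every OTU, sources inferred by nearest reference."""
    refs = ReferenceSet(records=list(truth.community.members), alphabet="nt")
    out = []
    for otu_id, consensus in sorted(otus):
        src, ident = nearest_reference(consensus, refs)
        out.append(otu_sn_sp(otu_id, src, assignments, truth.read_sources,
                             nearest_identity=ident))
    return out


def compare_profiles(table: AbundanceTable, otus: list[tuple[str, str]],
                     truth: CommunityTruth,
                     recovery_identity: float = RECOVERY_IDENTITY
                     ) -> ProfileComparison:
    """Compare the mapped abundance profile with the simulator's truth.

    Each OTU is matched to its best member by the watered-BLAST screen (one
    member may receive several OTUs; their counts are summed).  l1_error is
    0.5 * sum |p_hat - p| over members, with p_hat taken over mapped reads
    only and p the realized multinomial proportions.  members_recovered
    counts members matched by at least one OTU at >= recovery_identity.
    """
    refs = ReferenceSet(records=list(truth.community.members), alphabet="nt")
    otu_to_member: dict[str, str] = {}
    recovered: set[str] = set()
    for otu_id, consensus in sorted(otus):
        member, ident = nearest_reference(consensus, refs)
        if member is None:
            continue
        otu_to_member[otu_id] = member
        if ident >= recovery_identity:
            recovered.add(member)

    mapped_per_otu = table.counts.sum(axis=1)
    total_mapped = int(mapped_per_otu.sum())
    est: dict[str, float] = {name: 0.0 for name in truth.community.names}
    if total_mapped:
        for otu_id, n in mapped_per_otu.items():
            member = otu_to_member.get(otu_id)
            if member is not None:
                est[member] = est.get(member, 0.0) + n / total_mapped

    true_p = truth.true_proportions()
    members = sorted(set(est) | set(true_p))
    l1 = 0.5 * sum(abs(est.get(m, 0.0) - true_p.get(m, 0.0)) for m in members)
    total = int(table.total.sum())
    unmapped_fraction = float(table.unmapped.sum()) / total if total else 0.0
    return ProfileComparison(l1_error=l1, members_recovered=len(recovered),
                             unmapped_fraction=unmapped_fraction,
                             member_estimates=est, otu_to_member=otu_to_member)
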