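"""Nucleotide dereplication, reading-frame identification and peptide collapse.

For a protein-coding barcode, the biological unit is the peptide: nucleotide
OTUs are dereplicated at 100% identity (including reverse-complement and
substring containment, CD-hit style), the reading frame of each survivor is
identified by scoring all six conceptual translations against a protein
reference with local BLOSUM62 alignments (the BLASTX role), and identical
peptides are collapsed into peptide OTUs whose per-library abundance is the
sum of their member nucleotide OTUs.  OTUs whose best-frame translation has
an internal stop are excluded from peptide space by default (frameshifted
pseudo-peptides would otherwise inflate peptide richness) but stay in
nucleotide space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from ._align import protein_aligner, revcomp
from .io import ReferenceSet
from .mapping import AbundanceTable

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class FrameResult:
    frame: int
    score: float
    peptide: str
    has_internal_stop: bool
    from_fallback: bool = False


@dataclass
class PeptideOTU:
    id: str
    peptide: str
    member_nt_otus: set[str]
    frames: dict[str, int] = field(default_factory=dict)
    has_internal_stop: bool = False


def _merge_rows(table: AbundanceTable, groups: dict[str, list[str]],
                extra_unmapped=None) -> AbundanceTable:
    """Sum abundance rows into representatives per groups {rep: members}."""
    counts = table.counts
    rows = {}
    for rep, members in groups.items():
        present = [m for m in members if m in counts.index]
        rows[rep] = counts.loc[present].sum(axis=0) if present else 0
    new = pd.DataFrame(rows).T
    new = new.reindex(sorted(new.index))
    new.columns = counts.columns
    unmapped = table.unmapped
    if extra_unmapped is not None:
        unmapped = unmapped + extra_unmapped.astype(int)
    return AbundanceTable(new, unmapped, table.total)


def dereplicate_nt(otus: list[tuple[str, str]], table: AbundanceTable
                   ) -> tuple[list[tuple[str, str]], AbundanceTable,
                              dict[str, list[str]]]:
    """Collapse identical / reverse-complement / contained OTUs.

    The representative is the longest sequence (ties: lexicographically
    smallest id); merged abundances are summed into it.  Returns the reduced
    OTU list, the merged table and the {representative: members} map.
    """
    order = sorted(otus, key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str]] = []
    groups: dict[str, list[str]] = {}
    for oid, seq in order:
        rc = revcomp(seq)
        home = None
        for rid, rseq in reps:
            if seq in rseq or rc in rseq:
                home = rid
                break
        if home is None:
            reps.append((oid, seq))
            groups[oid] = [oid]
        else:
            groups[home].append(oid)
    reps.sort()
    return reps, _merge_rows(table, groups), groups


_PROT = protein_aligner()


def _six_frames(seq: str) -> dict[int, str]:
    out = {}
    rc = revcomp(seq)
    for f in (1, 2, 3):
        for frame, s in ((f, seq), (-f, rc)):
            sub = s[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            out[frame] = str(Seq(sub).translate()) if sub else ""
    return out


def _longest_orf_len(pep: str) -> int:
    return max((len(p) for p in pep.split("*")), default=0)


def find_frame(otu_seq: str, protein_ref: ReferenceSet,
               score_floor: float = 50.0) -> FrameResult:
    """Identify the reading frame by local protein alignment.

    All six conceptual translations are scored (BLOSUM62, gap open -11,
    extend -1) against every reference protein; the maximal score wins, ties
    to the frame listed earlier in (+1,+2,+3,-1,-2,-3).  Below score_floor
    the frame with the longest open reading frame is used instead.
    """
    if len(otu_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if protein_ref is not None and len(protein_ref) == 0:
        raise ValueError("empty protein reference")
    peps = _six_frames(otu_seq)
    best_frame, best_score = None, None
    if protein_ref is not None:
        for frame in FRAMES:
            pep = peps[frame]
            if not pep:
                continue
            score = max((_PROT.score(ref_seq, pep.replace("*", "X"))
                         for _, ref_seq in protein_ref.records), default=0.0)
            if best_score is None or score > best_score:
                best_frame, best_score = frame, score
    if best_score is None or best_score < score_floor:
        # ORF fallback: no (or too weak) protein evidence
        best_frame = max(FRAMES, key=lambda f: (_longest_orf_len(peps[f]),
                                                -FRAMES.index(f)))
        best_score = best_score if best_score is not None else 0.0
        fallback = True
    else:
        fallback = False
    pep = peps[best_frame]
    has_stop = "*" in pep.rstrip("*")
    return FrameResult(frame=best_frame, score=float(best_score), peptide=pep,
                       has_internal_stop=has_stop, from_fallback=fallback)


def collapse_peptides(framed: dict[str, FrameResult], table: AbundanceTable,
                      exclude_internal_stop: bool = True
                      ) -> tuple[list[PeptideOTU], AbundanceTable, list[str]]:
    """Group identical (or contained) peptides into peptide OTUs.

    Peptide abundance per library is the sum of member nucleotide OTU
    abundances.  Returns (peptide OTUs, peptide table, excluded nt OTU ids).
    """
    excluded = [oid for oid, fr in framed.items()
                if exclude_internal_stop and fr.has_internal_stop]
    usable = {oid: fr for oid, fr in framed.items() if oid not in excluded}

    order = sorted(usable.items(),
                   key=lambda kv: (-len(kv[1].peptide.rstrip("*")), kv[0]))
    reps: list[tuple[str, str]] = []  # (first nt otu id, peptide)
    members: dict[str, list[str]] = {}
    for oid, fr in order:
        pep = fr.peptide.rstrip("*")
        home = None
        for rid, rpep in reps:
            if pep in rpep:
                home = rid
                break
        if home is None:
            reps.append((oid, pep))
            members[oid] = [oid]
        else:
            members[home].append(oid)

    peptide_otus: list[PeptideOTU] = []
    groups: dict[str, list[str]] = {}
    ordered = sorted(reps, key=lambda t: (-len(t[1]), t[1]))
    for i, (rid, pep) in enumerate(ordered):
        pid = f"pep_{i + 1:04d}"
        mem = members[rid]
        peptide_otus.append(PeptideOTU(
            id=pid, peptide=pep, member_nt_otus=set(mem),
            frames={m: usable[m].frame for m in mem}))
        groups[pid] = mem
    # counts of excluded internal-stop OTUs move to the unmapped tally so the
    # peptide table still conserves every input read; they stay in nucleotide
    # space and are reported to the caller
    dropped = None
    if excluded:
        dropped = table.counts.reindex(
            [o for o in excluded if o in table.counts.index]).fillna(0).sum(axis=0)
    pep_table = _merge_rows(table, groups, extra_unmapped=dropped)
    return peptide_otus, pep_table, sorted(excluded)
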