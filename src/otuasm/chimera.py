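"""Chimera screening by split end-matching (the C3 strategy).

Both ends of an OTU (default 150 bp) are matched against a nucleotide
reference set; an OTU whose two ends best-match disjoint reference sets, or
whose shared best references disagree in strand or 5'/3' order, is flagged
as a putative chimera.  Ends that match nothing above min_end_identity make
the verdict indeterminate, never chimeric: in novel communities weak
matches must not inflate the false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluate import WateredBlastHit, watered_blast_identity
from .io import ReferenceSet
from .mapping import AbundanceTable


@dataclass
class C3Params:
    reference: ReferenceSet
    end_len: int = 150
    min_end_identity: float = 60.0

    def __post_init__(self):
        if self.end_len < 20:
            raise ValueError("end_len must be >= 20")
        if len(self.reference) == 0:
            raise ValueError("C3 requires a non-empty reference set")


@dataclass
class C3Verdict:
    otu_id: str
    status: str  # 'non-chimeric' | 'chimeric' | 'indeterminate'
    best5: list[WateredBlastHit]
    best3: list[WateredBlastHit]
    note: str = ""


def _consistent(h5: WateredBlastHit, h3: WateredBlastHit) -> bool:
    """Same reference, same strand, 5' end upstream of the 3' end."""
    if h5.ref_id != h3.ref_id or h5.strand != h3.strand:
        return False
    if h5.strand == "+":
        return h5.ref_start < h3.ref_start
    # reverse-complement OTU: its 5' end lies downstream on the reference
    return h5.ref_start > h3.ref_start


def c3_classify(otu_id: str, consensus: str, params: C3Params) -> C3Verdict:
    """Classify one OTU consensus as non-chimeric, chimeric or indeterminate.

    All ties at each end's maximum identity are retained; chimerism requires
    the two tie sets to be disjoint so that near-identical reference entries
    cannot force a false chimera call.
    """
    if len(consensus) < 2 * params.end_len:
        return C3Verdict(otu_id, "indeterminate", [], [],
                         note=f"shorter than 2 x end_len ({params.end_len})")
    end5 = consensus[:params.end_len]
    end3 = consensus[-params.end_len:]
    best5 = [h for h in watered_blast_identity(end5, params.reference)
             if h.identity >= params.min_end_identity]
    best3 = [h for h in watered_blast_identity(end3, params.reference)
             if h.identity >= params.min_end_identity]
    if not best5 or not best3:
        return C3Verdict(otu_id, "indeterminate", best5, best3,
                         note="an end has no reference match above "
                              f"{params.min_end_identity}% identity")
    for h5 in best5:
        for h3 in best3:
            if _consistent(h5, h3):
                return C3Verdict(otu_id, "non-chimeric", best5, best3)
    refs5 = {h.ref_id for h in best5}
    refs3 = {h.ref_id for h in best3}
    if refs5 & refs3:
        # shared best reference but inconsistent orientation/order
        return C3Verdict(otu_id, "chimeric", best5, best3,
                         note="shared best reference in inconsistent "
                              "orientation")
    return C3Verdict(otu_id, "chimeric", best5, best3)


def classify_otus(otus: list[tuple[str, str]], params: C3Params
                  ) -> list[C3Verdict]:
    return [c3_classify(oid, seq, params) for oid, seq in sorted(otus)]


def filter_chimeras(otus: list[tuple[str, str]], table: AbundanceTable,
                    verdicts: list[C3Verdict]
                    ) -> tuple[list[tuple[str, str]], AbundanceTable, dict]:
    """Drop chimeric OTUs; their reads move to the unmapped tally.

    Indeterminate OTUs are retained and listed in the report.  Conservation
    (mapped + unmapped == total per library) is preserved.
    """
    status = {v.otu_id: v.status for v in verdicts}
    missing = [oid for oid, _ in otus if oid not in status]
    if missing:
        raise ValueError(f"verdicts missing for OTUs: {missing}")
    removed = [oid for oid, _ in otus if status[oid] == "chimeric"]
    kept = [(oid, seq) for oid, seq in otus if status[oid] != "chimeric"]
    counts = table.counts.drop(index=[o for o in removed
                                      if o in table.counts.index])
    moved = table.counts.reindex([o for o in removed
                                  if o in table.counts.index]).sum(axis=0)
    unmapped = table.unmapped + moved.astype(int)
    new_table = AbundanceTable(counts, unmapped, table.total)
    report = {
        "removed": removed,
        "flagged_indeterminate": [oid for oid, _ in otus
                                  if status[oid] == "indeterminate"],
        "reads_moved_to_unmapped": int(moved.sum()),
    }
    return kept, new_table, report


def write_verdicts(verdicts: list[C3Verdict], path) -> None:
    rows = []
    for v in verdicts:
        def fmt(hits):
            return ";".join(f"{h.ref_id}:{h.identity:.1f}:{h.strand}:"
                            f"{h.ref_start}" for h in hits) or "."
        rows.append((v.otu_id, v.status, fmt(v.best5), fmt(v.best3), v.note))
    pd.DataFrame(rows, columns=["otu", "status", "best5", "best3", "note"]
                 ).to_csv(path, sep="\t", index=False)
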