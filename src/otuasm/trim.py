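"""PCR primer removal from amplicon read ends.

Primer search is anchored to a terminal window (primer length plus 3 bases
of slack) rather than a global scan: amplicon primers sit at read ends, and
global scans create false internal trims.  IUPAC degeneracies in the primer
match any compatible read base.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import revcomp
from .io import Read
from .simulate import IUPAC

TERMINAL_SLACK = 3


@dataclass
class PrimerSpec:
    forward: str
    reverse: str
    max_mismatch: int = 2
    min_retained_length: int = 50

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatch >= min(len(self.forward), len(self.reverse)):
            raise ValueError("max_mismatch must be smaller than the primer length")


@dataclass
class TrimReport:
    read_id: str
    trimmed_5: int
    trimmed_3: int
    kept: bool
    note: str


def _mismatches(primer: str, window: str) -> int:
    return sum(1 for p, b in zip(primer, window) if b not in IUPAC.get(p, p))


def _best_terminal_hit(seq: str, primers: list[str], max_mismatch: int,
                       end: str) -> int:
    """Bases to remove from the given end (0 if no primer found).

    Tries each primer at offsets 0..TERMINAL_SLACK from the terminus and
    keeps the hit with fewest mismatches, then the longest removal.
    """
    best = None  # (mismatches, -removed, removed)
    for primer in primers:
        plen = len(primer)
        for off in range(TERMINAL_SLACK + 1):
            if off + plen > len(seq):
                continue
            window = (seq[off:off + plen] if end == "5"
                      else seq[len(seq) - off - plen:len(seq) - off])
            mm = _mismatches(primer if end == "5" else revcomp(primer), window)
            if mm <= max_mismatch:
                removed = off + plen
                key = (mm, -removed)
                if best is None or key < best[0]:
                    best = (key, removed)
    return best[1] if best else 0


def trim_primers(read: Read, spec: PrimerSpec) -> tuple[Read, TrimReport]:
    """Remove primer sequence from the 5' and 3' termini of a read.

    Both the forward and reverse primer are tried at either end (a 3'-end
    amplicon read starts with the reverse primer), in the orientation that
    end implies.  Non-matching reads pass through unmodified.
    """
    seq = read.seq
    primers = [spec.forward.upper(), spec.reverse.upper()]
    cut5 = _best_terminal_hit(seq, primers, spec.max_mismatch, end="5")
    cut3 = _best_terminal_hit(seq[cut5:], primers, spec.max_mismatch, end="3")
    trimmed_seq = seq[cut5:len(seq) - cut3] if cut3 else seq[cut5:]
    notes = []
    if cut5 == 0 and cut3 == 0:
        notes.append("no primer found")
    kept = len(trimmed_seq) >= spec.min_retained_length
    if not kept:
        notes.append("discard: shorter than min_retained_length")
    qual = read.qual[cut5:len(seq) - cut3] if read.qual is not None else None
    out = Read(id=read.id, seq=trimmed_seq if trimmed_seq else seq,
               qual=qual if trimmed_seq else read.qual,
               library=read.library, truth_source=read.truth_source)
    if not trimmed_seq:  # pathological: primer consumed everything
        kept = False
    report = TrimReport(read_id=read.id, trimmed_5=cut5, trimmed_3=cut3,
                        kept=kept, note="; ".join(notes))
    return out, report


def trim_reads(reads: list[Read], spec: PrimerSpec
               ) -> tuple[list[Read], list[TrimReport]]:
    """Trim a read set; returns kept reads and a report for every input read."""
    kept: list[Read] = []
    reports: list[TrimReport] = []
    for r in reads:
        t, rep = trim_primers(r, spec)
        reports.append(rep)
        if rep.kept:
            kept.append(t)
    return kept, reports


def write_trim_report(reports: list[TrimReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\ttrimmed_5\ttrimmed_3\tstatus\tnote\n")
        for r in reports:
            fh.write(f"{r.read_id}\t{r.trimmed_5}\t{r.trimmed_3}\t"
                     f"{'kept' if r.kept else 'discarded'}\t{r.note}\n")
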