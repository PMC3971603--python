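"""Read-to-OTU mapping and per-library abundance accounting.

Each read is aligned semi-globally (read end-to-end, free gaps on the OTU)
against the OTU consensuses on both strands; the best hit by (identity,
aligned length, lexicographic OTU id) wins, and falls to unmapped below the
identity/length gates.  Candidate OTUs are short-listed by shared k-mers and
re-scored by exact alignment; when the OTU set is small (<= 8) every OTU is
aligned, so the short list can never change the answer where exhaustive
search is affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import (KmerIndex, alignment_identity, gapless_overlap, revcomp,
                     semiglobal_aligner, seq_to_array)
from .io import Read, SampleMap


@dataclass
class MappingParams:
    min_identity: float = 90.0
    min_aligned_len: int = 50
    shortlist_k: int = 11
    shortlist_size: int = 4
    gapless_accept: float = 97.0

    def __post_init__(self):
        if self.min_identity <= 0 or self.min_aligned_len <= 0:
            raise ValueError("mapping thresholds must be positive")


@dataclass
class Assignment:
    read_id: str
    library: str
    otu_id: str | None  # None = unmapped
    identity: float
    aligned_len: int
    strand: str


class AbundanceTable:
    """OTU x library count matrix with explicit unmapped accounting.

    Invariant: for every library, column sum + unmapped == total.
    """

    def __init__(self, counts: pd.DataFrame, unmapped: pd.Series,
                 total: pd.Series | None = None):
        self.counts = counts.astype(int)
        self.unmapped = unmapped.astype(int)
        if total is None:
            total = self.counts.sum(axis=0) + self.unmapped
        self.total = total.astype(int)
        self.validate()

    def validate(self) -> None:
        if (self.counts.values < 0).any() or (self.unmapped < 0).any():
            raise ValueError("negative counts")
        implied = self.counts.sum(axis=0) + self.unmapped
        if not implied.equals(self.total):
            raise ValueError("conservation violated: mapped + unmapped != total")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def mapped_fraction(self) -> pd.Series:
        return 1.0 - self.unmapped / self.total.replace(0, 1)

    def to_tsv(self, path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            fh.write("otu\t" + "\t".join(self.libraries) + "\n")
            for otu in self.otu_ids:
                row = "\t".join(str(int(v)) for v in self.counts.loc[otu])
                fh.write(f"{otu}\t{row}\n")
            fh.write("UNMAPPED\t"
                     + "\t".join(str(int(self.unmapped[l]))
                                 for l in self.libraries) + "\n")


class ReadMapper:
    """Maps reads onto a fixed OTU set (index built once).

    For each candidate (OTU, strand) a gapless placement is first evaluated
    on the k-mer-voted diagonal; when its identity clears a safety band
    (params.gapless_accept) the ungapped alignment is provably score-optimal
    for substitution-only divergence and is used directly.  Otherwise the
    exact semi-global dynamic program decides.
    """

    def __init__(self, otus: list[tuple[str, str]],
                 params: MappingParams | None = None):
        if not otus:
            raise ValueError("cannot map against an empty OTU set")
        self.params = params or MappingParams()
        self.otus = sorted(otus)  # (id, consensus), lexicographic id order
        self.seqs = [s for _, s in self.otus]
        self.ids = [i for i, _ in self.otus]
        self.arrs = [seq_to_array(s) for s in self.seqs]
        k = self.params.shortlist_k
        self.index = KmerIndex(self.seqs, k)
        self.kpos: list[dict[str, int]] = []
        for s in self.seqs:
            pos: dict[str, int] = {}
            for i in range(len(s) - k + 1):
                pos.setdefault(s[i:i + k], i)
            self.kpos.append(pos)
        self.aligner = semiglobal_aligner()

    def _candidates(self, read_seq: str) -> list[tuple[int, str]]:
        """(otu index, strand) candidates, ranked by shared k-mers."""
        if len(self.otus) <= 8:
            return [(i, s) for i in range(len(self.otus)) for s in "+-"]
        out = []
        for strand in "+-":
            q = read_seq if strand == "+" else revcomp(read_seq)
            hits = self.index.candidate_counts(q, stride=2)
            out.extend((cnt, i, strand) for i, cnt in hits.items())
        out.sort(key=lambda t: (-t[0], t[1], t[2]))
        return [(i, s) for _, i, s in out[:self.params.shortlist_size]]

    def _gapless(self, i: int, q: str, qarr: np.ndarray
                 ) -> tuple[float, int] | None:
        """(identity, columns) of the best diagonal placement, if any."""
        k = self.params.shortlist_k
        votes: dict[int, int] = {}
        pos = self.kpos[i]
        for j in range(0, len(q) - k + 1, 2):
            t = pos.get(q[j:j + k])
            if t is not None:
                off = t - j
                votes[off] = votes.get(off, 0) + 1
        if not votes:
            return None
        best = None
        for off, _ in sorted(votes.items(),
                             key=lambda kv: (-kv[1], kv[0]))[:2]:
            length, matches = gapless_overlap(self.arrs[i], qarr, off)
            # the read must lie end-to-end inside the OTU for the ungapped
            # placement to be a complete semi-global alignment
            if length != len(qarr):
                continue
            ident = 100.0 * matches / length
            if best is None or ident > best[0]:
                best = (ident, length)
        return best

    def map_read(self, read: Read) -> Assignment:
        p = self.params
        evaluated = []  # (identity, columns, otu index, strand)
        dp_pending = []  # (i, strand, q)
        for i, strand in self._candidates(read.seq):
            q = read.seq if strand == "+" else revcomp(read.seq)
            qarr = seq_to_array(q)
            fast = self._gapless(i, q, qarr)
            if fast is not None and fast[0] >= p.gapless_accept:
                evaluated.append((fast[0], fast[1], i, strand))
            else:
                dp_pending.append((i, strand, q))
        # an accepted ungapped placement cannot be overtaken by a candidate
        # whose own diagonal placement is below the band unless indels add
        # identity, which the band excludes; DP decides sub-band cases only
        if dp_pending and not evaluated:
            scored = sorted(
                ((self.aligner.score(self.seqs[i], q), i, strand, q)
                 for i, strand, q in dp_pending),
                key=lambda t: (-t[0], t[1], t[2]))
            # candidates within a small score margin of the leader can still
            # win on the identity tie-break; align those exactly
            top = scored[0][0]
            for score, i, strand, q in scored[:3]:
                if score < top - 4:
                    break
                aln = self.aligner.align(self.seqs[i], q)[0]
                ident, columns, _ = alignment_identity(aln)
                evaluated.append((ident, columns, i, strand))
        best = None
        for ident, columns, i, strand in evaluated:
            # best = max identity, then max aligned length, then smallest
            # otu id, then '+' strand
            key = (-ident, -columns, self.ids[i], strand)
            if best is None or key < best[0]:
                best = (key, i, strand, ident, columns)
        if best is None:
            return Assignment(read.id, read.library, None, 0.0, 0, ".")
        _, i, strand, ident, columns = best
        if ident < p.min_identity or columns < p.min_aligned_len:
            return Assignment(read.id, read.library, None, ident, columns, ".")
        return Assignment(read.id, read.library, self.ids[i], ident, columns,
                          strand)


def map_read(read: Read, otus: list[tuple[str, str]],
             params: MappingParams | None = None) -> Assignment:
    """Map one read; builds a fresh index (use ReadMapper for batches)."""
    return ReadMapper(otus, params).map_read(read)


def map_reads(reads: list[Read], otus: list[tuple[str, str]],
              params: MappingParams | None = None) -> list[Assignment]:
    mapper = ReadMapper(otus, params)
    return [mapper.map_read(r) for r in reads]


def count_abundance(assignments: list[Assignment],
                    sample_map: SampleMap | list[str],
                    otu_ids: list[str] | None = None) -> AbundanceTable:
    """Aggregate assignments into an OTU x library table."""
    libraries = (sample_map.libraries if isinstance(sample_map, SampleMap)
                 else list(sample_map))
    known = set(libraries)
    if otu_ids is None:
        otu_ids = sorted({a.otu_id for a in assignments if a.otu_id})
    counts = pd.DataFrame(0, index=list(otu_ids), columns=libraries, dtype=int)
    unmapped = pd.Series(0, index=libraries, dtype=int)
    for a in assignments:
        if a.library not in known:
            raise ValueError(f"read {a.read_id}: unknown library {a.library!r}")
        if a.otu_id is None:
            unmapped[a.library] += 1
        else:
            counts.loc[a.otu_id, a.library] += 1
    return AbundanceTable(counts, unmapped)


def downsample(assignments: list[Assignment],
               sample_map: SampleMap | list[str], seed: int,
               otu_ids: list[str] | None = None
               ) -> tuple[AbundanceTable, list[Assignment]]:
    """Subsample each library's mapped reads to the smallest library depth.

    Sampling is without replacement and deterministic under seed.  Raises on
    a library with zero mapped reads (exclude it first).
    """
    libraries = (sample_map.libraries if isinstance(sample_map, SampleMap)
                 else list(sample_map))
    mapped = {lib: [a for a in assignments
                    if a.library == lib and a.otu_id is not None]
              for lib in libraries}
    depths = {lib: len(v) for lib, v in mapped.items()}
    zero = [lib for lib, d in depths.items() if d == 0]
    if zero:
        raise ValueError(
            f"libraries with zero mapped reads: {zero}; exclude them before "
            f"down-sampling")
    floor = min(depths.values())
    rng = np.random.default_rng(seed)
    kept: list[Assignment] = []
    for lib in libraries:
        pool = sorted(mapped[lib], key=lambda a: a.read_id)
        sel = rng.choice(len(pool), size=floor, replace=False)
        kept.extend(pool[i] for i in sorted(sel))
    return count_abundance(kept, libraries, otu_ids=otu_ids), kept


def write_assignments(assignments: list[Assignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tlibrary\totu\tidentity\taligned_len\tstrand\n")
        for a in assignments:
            fh.write(f"{a.read_id}\t{a.library}\t{a.otu_id or 'unmapped'}\t"
                     f"{a.identity:.2f}\t{a.aligned_len}\t{a.strand}\n")
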