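"""Greedy overlap-layout-consensus assembly with exact internal read tracking.

Every OTU is a per-column weighted-majority consensus over the reads placed
in it, and every input read ends up either in exactly one OTU's tracked set
or in the unassembled list.  The overlap model is ungapped (dovetail or
containment placements scored as matches / overlap columns), which is exact
for substitution-only divergence; overlaps below min_overlap_len or
min_overlap_identity never join reads.

Scalability: rather than materialising all O(n^2) read-pair overlaps, reads
are processed longest-first and greedily joined to the best-scoring draft
(score = overlap length x identity, the same objective a global greedy edge
ordering maximises at each step), followed by a greedy draft-merge phase
under the same score.  Candidate drafts are short-listed by shared k-mers
and every candidate placement is verified by exact comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import gapless_overlap, revcomp, seq_to_array
from .io import Read

_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of a 0..3-encoded array (255 = N preserved)."""
    out = arr[::-1].copy()
    m = out < 4
    out[m] = 3 - out[m]
    return out


@dataclass
class OlcParams:
    """Overlap-layout-consensus parameters.

    strong_join_identity is the identity band above which a read joins a
    draft immediately; placements between min_overlap_identity and this band
    are honoured only after every strong join has been made.  This emulates
    a global greedy edge ordering (highest-identity overlaps merge first) at
    linear cost, and is what keeps a 96%-identical template pair from being
    absorbed into a single consensus when min_overlap_identity is 90.
    """

    min_overlap_len: int = 100
    min_overlap_identity: float = 90.0
    min_reads_per_otu: int = 2
    strong_join_identity: float = 98.0
    shortlist_k: int = 15
    shortlist_size: int = 4

    @property
    def strong_band(self) -> float:
        return max(self.strong_join_identity, self.min_overlap_identity)

    def __post_init__(self):
        if self.min_overlap_len < 1:
            raise ValueError("min_overlap_len must be >= 1")
        if not 0 < self.min_overlap_identity <= 100:
            raise ValueError("min_overlap_identity must be in (0, 100]")


@dataclass
class OTU:
    """An assembled consensus with the reads that built it."""

    id: str
    consensus: str
    tracked_reads: set[str]
    per_column_depth: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Overlap:
    a_id: str
    b_id: str
    orientation: str  # '+' if b overlaps a on the same strand, '-' otherwise
    length: int
    identity: float
    kind: str  # 'dovetail' or 'containment'
    offset: int  # position of b[0] (oriented) in a's coordinates


def find_overlaps(reads: list[Read], params: OlcParams) -> list[Overlap]:
    """All qualifying pairwise overlaps (exhaustive all-offset scan).

    An edge exists iff some ungapped dovetail or containment placement, on
    either strand, reaches min_overlap_len columns at min_overlap_identity;
    the best-scoring placement per (pair, orientation) is reported.
    Quadratic in the number of reads; intended for modest read sets.
    """
    arrs = {r.id: seq_to_array(r.seq) for r in reads}
    edges: list[Overlap] = []
    ordered = sorted(reads, key=lambda r: r.id)
    for i, ra in enumerate(ordered):
        a = arrs[ra.id]
        for rb in ordered[i + 1:]:
            for orient in "+-":
                b = arrs[rb.id] if orient == "+" else _rc_arr(arrs[rb.id])
                best = None
                for off in range(-(len(b) - params.min_overlap_len),
                                 len(a) - params.min_overlap_len + 1):
                    length, matches = gapless_overlap(a, b, off)
                    if length < params.min_overlap_len:
                        continue
                    ident = 100.0 * matches / length
                    if ident < params.min_overlap_identity:
                        continue
                    score = length * ident
                    if best is None or score > best[0]:
                        contained = (off >= 0 and off + len(b) <= len(a)) or \
                                    (off <= 0 and off + len(b) >= len(a))
                        best = (score, off, length, ident, contained)
                if best:
                    _, off, length, ident, contained = best
                    edges.append(Overlap(
                        a_id=ra.id, b_id=rb.id, orientation=orient,
                        length=length, identity=ident,
                        kind="containment" if contained else "dovetail",
                        offset=off))
    return edges


class _Draft:
    """A growing layout: base-count matrix plus read placements."""

    __slots__ = ("counts", "reads", "_cons", "_kpos", "_kpos_k")

    def __init__(self, read: Read):
        arr = seq_to_array(read.seq)
        self.counts = np.zeros((4, len(arr)), dtype=np.float64)
        w = self._weights(read)
        valid = arr < 4
        self.counts[arr[valid], np.nonzero(valid)[0]] = w[valid]
        # (read_id, offset, strand, oriented uint8 array, weights)
        self.reads: list[tuple[str, int, str, np.ndarray, np.ndarray]] = [
            (read.id, 0, "+", arr, w)]
        self._cons: np.ndarray | None = arr.copy()
        self._kpos: dict[str, int] | None = None
        self._kpos_k = 0

    @staticmethod
    def _weights(read: Read) -> np.ndarray:
        if read.qual is not None:
            return np.asarray(read.qual, dtype=np.float64).clip(min=1.0)
        return np.ones(len(read.seq), dtype=np.float64)

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    def consensus(self) -> np.ndarray:
        if self._cons is None:
            # ties resolved to the lexicographically smallest base: argmax
            # returns the first maximal row and rows are in A,C,G,T order
            self._cons = np.argmax(self.counts, axis=0).astype(np.uint8)
        return self._cons

    def consensus_str(self) -> str:
        return _IDX2BASE[self.consensus()].tobytes().decode("ascii")

    def kmer_positions(self, k: int) -> dict[str, int]:
        """First position of each consensus k-mer (cached until modified)."""
        if self._kpos is None or self._kpos_k != k:
            cons = self.consensus_str()
            pos: dict[str, int] = {}
            for i in range(len(cons) - k + 1):
                pos.setdefault(cons[i:i + k], i)
            self._kpos = pos
            self._kpos_k = k
        return self._kpos

    def add(self, arr: np.ndarray, w: np.ndarray, offset: int,
            read_id: str, strand: str) -> None:
        if offset < 0:
            self.counts = np.pad(self.counts, ((0, 0), (-offset, 0)))
            self.reads = [(rid, off - offset, st, a, ww)
                          for rid, off, st, a, ww in self.reads]
            offset = 0
        if offset + len(arr) > len(self):
            self.counts = np.pad(
                self.counts, ((0, 0), (0, offset + len(arr) - len(self))))
        pos = np.arange(offset, offset + len(arr))
        valid = arr < 4
        np.add.at(self.counts, (arr[valid], pos[valid]), w[valid])
        self.reads.append((read_id, offset, strand, arr, w))
        self._cons = None
        self._kpos = None

    def depth(self) -> np.ndarray:
        d = np.zeros(len(self), dtype=np.int64)
        for _, off, _, a, _ in self.reads:
            d[off:off + len(a)] += 1
        return d


def _best_placement(cons: np.ndarray, arr: np.ndarray, params: OlcParams,
                    offsets) -> tuple[float, int, int, float] | None:
    """(score, offset, length, identity) of the best qualifying placement."""
    best = None
    for off in sorted(set(offsets)):
        length, matches = gapless_overlap(cons, arr, off)
        if length < params.min_overlap_len:
            continue
        ident = 100.0 * matches / length
        if ident < params.min_overlap_identity:
            continue
        score = length * ident
        if best is None or score > best[0]:
            best = (score, off, length, ident)
    return best


def olc_assemble(reads: list[Read], params: OlcParams | None = None
                 ) -> tuple[list[OTU], list[str]]:
    """Assemble reads into consensus OTUs; returns (otus, unassembled ids).

    Deterministic: reads are processed longest-first (ties by id), draft
    candidates are scored by overlap length x identity, consensus ties fall
    to the lexicographically smallest base, and final OTU ids are assigned
    on (read support desc, consensus) order.  Drafts with fewer than
    min_reads_per_otu reads are dissolved to the unassembled list, and
    consensus ends supported by fewer than two reads are trimmed.
    """
    params = params or OlcParams()
    k = params.shortlist_k
    ordered = sorted(reads, key=lambda r: (-len(r.seq), r.id))

    drafts: dict[int, _Draft] = {}
    kmer_map: dict[str, set[int]] = {}
    next_id = 0

    def _index_consensus(did: int, seq: str) -> None:
        for i in range(0, len(seq) - k + 1):
            kmer_map.setdefault(seq[i:i + k], set()).add(did)

    def _candidates(seq: str) -> list[int]:
        hits: dict[int, int] = {}
        for i in range(0, len(seq) - k + 1, 2):
            for did in kmer_map.get(seq[i:i + k], ()):
                if did in drafts:
                    hits[did] = hits.get(did, 0) + 1
        ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
        return [did for did, _ in ranked[:params.shortlist_size]]

    def _diag_offsets(draft: _Draft, seq: str) -> list[int]:
        positions = draft.kmer_positions(k)
        votes: dict[int, int] = {}
        for i in range(0, len(seq) - k + 1):
            j = positions.get(seq[i:i + k])
            if j is not None:
                off = j - i
                votes[off] = votes.get(off, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return [off for off, _ in ranked[:4]]

    def _best_join(read: Read):
        """Best placement over all drafts: (key, did, strand, off, arr, identity)."""
        placed = None
        for strand in "+-":
            seq = read.seq if strand == "+" else revcomp(read.seq)
            arr = seq_to_array(seq)
            for did in _candidates(seq):
                draft = drafts[did]
                offsets = _diag_offsets(draft, seq)
                if not offsets:
                    continue
                hit = _best_placement(draft.consensus(), arr, params, offsets)
                if hit is None:
                    continue
                score, off, _, ident = hit
                key = (score, -did, 0 if strand == "+" else -1)
                if placed is None or key > placed[0]:
                    placed = (key, did, strand, off, arr, ident)
        return placed

    def _join(read: Read, placed) -> None:
        _, did, strand, off, arr, _ = placed
        draft = drafts[did]
        draft.add(arr, _Draft._weights(read), off, read.id, strand)
        _index_consensus(did, draft.consensus_str())

    def _seed(read: Read) -> None:
        nonlocal next_id
        drafts[next_id] = _Draft(read)
        _index_consensus(next_id, read.seq)
        next_id += 1

    # pass 1: strong joins only; reads with weak-only placements wait so a
    # rarer, similar template is not swallowed by an abundant one
    deferred: list[Read] = []
    for read in ordered:
        placed = _best_join(read)
        if placed is not None and placed[5] >= params.strong_band:
            _join(read, placed)
        elif placed is None:
            _seed(read)
        else:
            deferred.append(read)

    # pass 2: deferred reads either join strongly (a matching draft has
    # appeared) or seed their own draft
    for read in deferred:
        placed = _best_join(read)
        if placed is not None and placed[5] >= params.strong_band:
            _join(read, placed)
        else:
            _seed(read)

    _merge_drafts(drafts, params, k)

    # pass 3: reads stranded in under-supported drafts get one weak-band
    # rescue into a surviving draft before dissolution
    by_id = {r.id: r for r in reads}
    small = [did for did, d in drafts.items()
             if d.n_reads < params.min_reads_per_otu]
    rescued: list[Read] = []
    for did in small:
        rescued.extend(by_id[rid] for rid, *_ in drafts[did].reads)
        del drafts[did]
    for read in sorted(rescued, key=lambda r: (-len(r.seq), r.id)):
        placed = _best_join(read)
        if placed is not None:
            _join(read, placed)
        else:
            _seed(read)

    # dissolve small drafts, trim low-depth ends, canonicalise orientation
    otus: list[OTU] = []
    unassembled: list[str] = []
    finished = []
    for did in sorted(drafts):
        draft = drafts[did]
        if draft.n_reads < params.min_reads_per_otu:
            unassembled.extend(rid for rid, *_ in draft.reads)
            continue
        cons = draft.consensus_str()
        depth = draft.depth()
        core = np.nonzero(depth >= 2)[0]
        if core.size == 0 or (core[-1] - core[0] + 1) < params.min_overlap_len:
            unassembled.extend(rid for rid, *_ in draft.reads)
            continue
        cons = cons[core[0]:core[-1] + 1]
        depth_list = depth[core[0]:core[-1] + 1].tolist()
        rc = revcomp(cons)
        if rc < cons:
            cons = rc
            depth_list = depth_list[::-1]
        finished.append((draft, cons, depth_list))

    finished.sort(key=lambda t: (-t[0].n_reads, t[1]))
    for i, (draft, cons, depth_list) in enumerate(finished):
        otus.append(OTU(id=f"otu_{i + 1:04d}", consensus=cons,
                        tracked_reads={rid for rid, *_ in draft.reads},
                        per_column_depth=depth_list))
    return otus, sorted(unassembled)


def _merge_drafts(drafts: dict[int, _Draft], params: OlcParams, k: int) -> None:
    """Greedily merge drafts whose consensuses overlap at the thresholds."""
    while True:
        ids = sorted(drafts)
        best = None  # (key, i, j, strand, offset)
        for ai in range(len(ids)):
            i = ids[ai]
            draft_a = drafts[i]
            pos_a = draft_a.kmer_positions(k)
            cons_a = draft_a.consensus()
            for bj in range(ai + 1, len(ids)):
                j = ids[bj]
                for strand in "+-":
                    s = (drafts[j].consensus_str() if strand == "+"
                         else revcomp(drafts[j].consensus_str()))
                    offs = set()
                    for q in range(len(s) - k + 1):
                        p = pos_a.get(s[q:q + k])
                        if p is not None:
                            offs.add(p - q)
                    if not offs:
                        continue
                    b = seq_to_array(s)
                    hit = _best_placement(cons_a, b, params, offs)
                    # merging repairs fragmentation of one template; joining
                    # distinct near-identical templates is left to mapping
                    if hit is None or hit[3] < params.strong_band:
                        continue
                    score, off, _, _ = hit
                    key = (score, -i, -j)
                    if best is None or key > best[0]:
                        best = (key, i, j, strand, off)
        if best is None:
            return
        _, i, j, strand, off = best
        a, bdraft = drafts[i], drafts[j]
        blen = len(bdraft)
        for rid, roff, rstrand, arr, w in list(bdraft.reads):
            if strand == "+":
                a.add(arr, w, off + roff, rid, rstrand)
            else:
                new_off = off + (blen - (roff + len(arr)))
                flipped = "-" if rstrand == "+" else "+"
                a.add(_rc_arr(arr), w[::-1].copy(), new_off, rid, flipped)
        del drafts[j]
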