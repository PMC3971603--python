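"""Shared alignment primitives: aligner factories, identity bookkeeping, k-mer indexing.

All percent identities in the package are matches / alignment columns * 100,
where the column count excludes terminal unaligned overhangs (relevant for
semi-global and local modes) but includes internal gap columns.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 (anything else 255) as a uint8 vector."""
    return _BASE2IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def global_aligner(match: float = 1.0, mismatch: float = -1.0,
                   gap: float = -2.0) -> Align.PairwiseAligner:
    """Needleman-Wunsch with linear gap penalty (the pairwise-identity scoring)."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def semiglobal_aligner(match: float = 1.0, mismatch: float = -1.0,
                       gap_open: float = -2.0, gap_extend: float = -1.0
                       ) -> Align.PairwiseAligner:
    """Read end-to-end, free end gaps on the reference (target = reference)."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    # call as aligner.align(reference, read): the reference's unaligned
    # flanks appear as end gaps in the read row ("deletions"), made free here
    al.end_deletion_score = 0.0
    return al


def local_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap: float = -2.0) -> Align.PairwiseAligner:
    """Smith-Waterman with linear gap penalty."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def protein_aligner(gap_open: float = -11.0, gap_extend: float = -1.0
                    ) -> Align.PairwiseAligner:
    """Local protein aligner with BLOSUM62 (BLASTP-like scoring)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def alignment_identity(alignment) -> tuple[float, int, int]:
    """(percent identity, columns, matches) for a Bio.Align.Alignment.

    Columns exclude terminal gap columns (unaligned flanks) but include
    internal gaps.
    """
    counts = alignment.counts()
    left = counts.left_insertions + counts.left_deletions
    right = counts.right_insertions + counts.right_deletions
    columns = alignment.shape[1] - left - right
    matches = counts.identities
    if columns == 0:
        return 0.0, 0, 0
    return 100.0 * matches / columns, columns, matches


def alignment_target_span(alignment) -> tuple[int, int]:
    """(start, end) of the aligned region on the target sequence (0-based, half-open)."""
    blocks = alignment.aligned[0]
    if len(blocks) == 0:
        return 0, 0
    return int(blocks[0][0]), int(blocks[-1][1])


def kmers_of(seq: str, k: int, stride: int = 1):
    """Yield (pos, kmer) for k-mers containing only ACGT."""
    for i in range(0, len(seq) - k + 1, stride):
        km = seq[i:i + k]
        if "N" not in km:
            yield i, km


class KmerIndex:
    """k-mer -> list of (record index, position) over a set of sequences.

    Used for candidate short-listing before exact alignment.  Never used to
    decide identity: every candidate is re-scored by alignment.
    """

    def __init__(self, seqs: list[str], k: int):
        self.k = k
        self.n = len(seqs)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(seqs):
            for pos, km in kmers_of(seq, k):
                self.index.setdefault(km, []).append((idx, pos))

    def candidate_counts(self, query: str, stride: int = 1) -> dict[int, int]:
        """Number of shared k-mers between query and each indexed sequence."""
        hits: dict[int, int] = {}
        for _, km in kmers_of(query, self.k, stride):
            for idx, _ in self.index.get(km, ()):
                hits[idx] = hits.get(idx, 0) + 1
        return hits

    def diagonal_votes(self, query: str, idx: int, stride: int = 1) -> dict[int, int]:
        """Offset (target_pos - query_pos) -> vote count against record idx."""
        votes: dict[int, int] = {}
        for qpos, km in kmers_of(query, self.k, stride):
            for j, tpos in self.index.get(km, ()):
                if j == idx:
                    off = tpos - qpos
                    votes[off] = votes.get(off, 0) + 1
        return votes


def gapless_overlap(a: np.ndarray, b: np.ndarray, offset: int
                    ) -> tuple[int, int]:
    """(overlap length, matches) of b placed at `offset` on a, ungapped.

    offset is the position of b[0] in a's coordinates; may be negative.
    """
    start = max(0, offset)
    end = min(len(a), offset + len(b))
    if end <= start:
        return 0, 0
    seg_a = a[start:end]
    seg_b = b[start - offset:end - offset]
    matches = int(np.count_nonzero(seg_a == seg_b))
    return end - start, matches


def best_gapless_overlap(a: np.ndarray, b: np.ndarray, min_len: int,
                         offsets=None) -> tuple[int, int, int] | None:
    """Best ungapped overlap of b against a by matches-maximising score.

    Scans the given offsets (default: all) and returns (offset, length,
    matches) maximising length * identity = matches... ties broken by smaller
    offset.  Returns None when no offset reaches min_len overlap.
    """
    if offsets is None:
        offsets = range(-(len(b) - min_len), len(a) - min_len + 1)
    best = None
    for off in offsets:
        length, matches = gapless_overlap(a, b, off)
        if length < min_len:
            continue
        ident = matches / length
        score = length * ident
        key = (score, -abs(off))
        if best is None or key > best[0]:
            best = (key, off, length, matches)
    if best is None:
        return None
    return best[1], best[2], best[3]
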