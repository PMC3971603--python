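"""De Bruijn graph assembly over canonical k-mers (k in the 10-31 sweep range).

Distilling reads to k-mers forfeits read tracking, so this engine emits
contigs only; abundance for DBG assemblies comes from the mapping module.
Graph cleaning: low-count k-mer removal, short dead-end (tip) clipping, and
popping of simple two-path bubbles whose branches align above a configurable
identity, keeping the higher-coverage branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from ._align import revcomp
from .simulate import pairwise_identity

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class DbgParams:
    k: int = 31
    min_kmer_count: int = 2
    tip_max_len: int | None = None  # default: 2 * k
    bubble_pop_identity: float = 98.0
    min_contig_len: int = 100

    def __post_init__(self):
        if not 10 <= self.k <= 31:
            warnings.warn(f"k={self.k} is outside the supported sweep range "
                          f"[10, 31]", stacklevel=2)
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if self.tip_max_len is None:
            self.tip_max_len = 2 * self.k


@dataclass
class Contig:
    id: str
    seq: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.seq)


def _canon(km: str) -> str:
    rc = revcomp(km)
    return km if km <= rc else rc


def count_kmers(reads, k: int) -> dict[str, int]:
    """Canonical k-mer counts over a read set (k-mers containing N skipped)."""
    counts: dict[str, int] = {}
    skipped = 0
    for read in reads:
        seq = read.seq
        if len(seq) < k:
            skipped += 1
            continue
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            kc = rc[n - k - i:n - i]
            canon = km if km <= kc else kc
            counts[canon] = counts.get(canon, 0) + 1
    if skipped:
        logger.warning("%d reads shorter than k=%d skipped", skipped, k)
    return counts


class _Graph:
    """Bidirected de Bruijn graph over a canonical k-mer count table."""

    def __init__(self, table: dict[str, int], k: int):
        self.table = table
        self.k = k

    def successors(self, km: str) -> list[str]:
        """Oriented k-mers reachable by one-base right extension."""
        stem = km[1:]
        return [stem + b for b in _BASES if _canon(stem + b) in self.table]

    def predecessors(self, km: str) -> list[str]:
        stem = km[:-1]
        return [b + stem for b in _BASES if _canon(b + stem) in self.table]

    def unitigs(self) -> list[tuple[str, list[str]]]:
        """Maximal unbranched paths as (sequence, canonical k-mer list)."""
        visited: set[str] = set()
        out = []
        for start in sorted(self.table):
            if start in visited:
                continue
            visited.add(start)
            path = [start]
            # extend right
            cur = start
            while True:
                nxts = self.successors(cur)
                if len(nxts) != 1:
                    break
                nxt = nxts[0]
                if len(self.predecessors(nxt)) != 1:
                    break
                cn = _canon(nxt)
                if cn in visited:
                    break
                visited.add(cn)
                path.append(nxt)
                cur = nxt
            # extend left
            cur = start
            head: list[str] = []
            while True:
                prvs = self.predecessors(cur)
                if len(prvs) != 1:
                    break
                prv = prvs[0]
                if len(self.successors(prv)) != 1:
                    break
                cp = _canon(prv)
                if cp in visited:
                    break
                visited.add(cp)
                head.append(prv)
                cur = prv
            path = head[::-1] + path
            seq = path[0] + "".join(km[-1] for km in path[1:])
            out.append((seq, [_canon(km) for km in path]))
        return out


def _clip_tips(graph: _Graph, tip_max_len: int) -> bool:
    """Remove short dead-end unitigs hanging off junctions.  True if any."""
    removed = False
    for seq, kms in graph.unitigs():
        if len(seq) >= tip_max_len:
            continue
        first, last = kms[0], kms[-1]
        # orientation of endpoints inside the unitig is lost after
        # canonicalisation; recover degree by checking both orientations
        left_deg = _end_degree(graph, seq[:graph.k], left=True)
        right_deg = _end_degree(graph, seq[-graph.k:], left=False)
        if (left_deg == 0) != (right_deg == 0):
            # dangling on exactly one side: a tip if the attached side
            # meets other sequence (junction)
            for km in kms:
                graph.table.pop(km, None)
            removed = True
    return removed


def _end_degree(graph: _Graph, oriented_km: str, left: bool) -> int:
    return len(graph.predecessors(oriented_km) if left
               else graph.successors(oriented_km))


def _pop_bubbles(graph: _Graph, identity: float) -> bool:
    """Pop simple two-path bubbles, keeping the higher-coverage branch."""
    units = graph.unitigs()
    k = graph.k
    by_ends: dict[frozenset, list[tuple[str, list[str]]]] = {}
    for seq, kms in units:
        left = frozenset(_canon(p) for p in graph.predecessors(seq[:k]))
        right = frozenset(_canon(s) for s in graph.successors(seq[-k:]))
        if not left or not right:
            continue
        key = frozenset((left, right))
        by_ends.setdefault(key, []).append((seq, kms))
    popped = False
    for key in sorted(by_ends, key=lambda fs: sorted(map(sorted, fs))):
        group = by_ends[key]
        if len(group) != 2:
            continue
        (seq_a, kms_a), (seq_b, kms_b) = sorted(group)
        ident = max(pairwise_identity(seq_a, seq_b),
                    pairwise_identity(revcomp(seq_a), seq_b))
        if ident < identity:
            continue
        cov_a = sum(graph.table.get(km, 0) for km in kms_a) / len(kms_a)
        cov_b = sum(graph.table.get(km, 0) for km in kms_b) / len(kms_b)
        loser = kms_b if cov_a >= cov_b else kms_a
        for km in loser:
            graph.table.pop(km, None)
        popped = True
    return popped


def dbg_assemble(reads, params: DbgParams | None = None) -> list[Contig]:
    """Assemble reads into contigs via a canonical de Bruijn graph.

    Deterministic: traversal order is fixed by sorted k-mer keys and contigs
    are emitted in (length desc, sequence) order in canonical (lexicographic
    minimum of forward/reverse-complement) orientation.
    """
    params = params or DbgParams()
    k = params.k
    usable = [r for r in reads if len(r.seq) >= k]
    if not usable:
        raise ValueError(f"no usable reads: every read is shorter than k={k}")
    table = count_kmers(reads, k)
    table = {km: c for km, c in table.items() if c >= params.min_kmer_count}
    graph = _Graph(table, k)

    for _ in range(4):
        changed = _clip_tips(graph, params.tip_max_len)
        changed |= _pop_bubbles(graph, params.bubble_pop_identity)
        if not changed:
            break

    contigs = []
    for seq, kms in graph.unitigs():
        if len(seq) < max(params.min_contig_len, k):
            continue
        cov = sum(graph.table[km] for km in kms) / len(kms)
        rc = revcomp(seq)
        contigs.append((min(seq, rc), cov))
    contigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [Contig(id=f"contig_{i + 1:04d}", seq=s, mean_kmer_coverage=c)
            for i, (s, c) in enumerate(contigs)]
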