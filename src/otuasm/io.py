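"""Reading and writing the pipeline's file formats.

Formats: FASTQ (Sanger/Phred+33), multi-FASTA (via Bio.SeqIO) and the
two-column sample map TSV relating read files to experimental libraries.
Coordinates everywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class Read:
    """A single amplicon sequencing read.

    truth_source is only set by the simulator: the community member (or
    "chimera:A+B") the read was generated from.
    """

    id: str
    seq: str
    qual: list[int] | None = None
    library: str = ""
    truth_source: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSet:
    """An ordered set of uniquely-identified reference sequences."""

    records: list[tuple[str, str]]
    alphabet: str = "nt"  # "nt" or "aa"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        for rid, seq in self.records:
            if rid in seen:
                raise ParseError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if not seq:
                raise ParseError(f"record {rid!r}: empty sequence")
            bad = set(seq) - allowed
            if bad:
                raise ParseError(
                    f"record {rid!r}: characters {sorted(bad)} outside the "
                    f"{self.alphabet} alphabet")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def get(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)


@dataclass
class SampleMap:
    """Mapping from read files to library names."""

    entries: list[tuple[str, str]]

    def __post_init__(self):
        if not self.entries:
            raise ParseError("sample map contains no libraries")
        seen = set()
        for path, lib in self.entries:
            if not lib:
                raise ParseError(f"empty library name for file {path!r}")
            if path in seen:
                raise ParseError(f"file {path!r} listed more than once")
            seen.add(path)

    @property
    def libraries(self) -> list[str]:
        out = []
        for _, lib in self.entries:
            if lib not in out:
                out.append(lib)
        return out


def _check_nt(seq: str, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ParseError(f"{where}: non-nucleotide characters {sorted(bad)}")
    return seq


def read_fastq(path: str | os.PathLike, library: str = "") -> list[Read]:
    """Parse a 4-line-per-record Phred+33 FASTQ file.

    Raises ParseError naming the offending line on malformed records.
    """
    reads: list[Read] = []
    seen_ids = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated record at line {4 * (len(lines) // 4) + 1}")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not header.startswith("@"):
            raise ParseError(f"{path}: line {lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {lineno + 2}: expected '+' separator")
        rid = header[1:].split()[0] if header[1:].strip() else ""
        if not rid:
            raise ParseError(f"{path}: line {lineno}: empty read id")
        if rid in seen_ids:
            raise ParseError(f"{path}: line {lineno}: duplicate read id {rid!r}")
        seen_ids.add(rid)
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}: line {lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(seq)}")
        phred = [ord(c) - 33 for c in qual]
        if any(q < 0 or q > 93 for q in phred):
            raise ParseError(f"{path}: line {lineno + 3}: quality outside Phred+33 range")
        reads.append(Read(id=rid, seq=_check_nt(seq, f"{path}: line {lineno + 1}"),
                          qual=phred, library=library))
    return reads


def write_fastq(reads: list[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else [40] * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n"
                     + "".join(chr(q + 33) for q in qual) + "\n")


def read_fasta(path: str | os.PathLike, alphabet: str = "nt") -> ReferenceSet:
    """Parse a multi-FASTA file into a ReferenceSet.

    Record ids are the header up to the first whitespace; the full header is
    kept as the description.  Duplicate ids raise ParseError.
    """
    records = []
    descriptions = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append((rec.id, seq))
        descriptions[rec.id] = rec.description
    return ReferenceSet(records=records, alphabet=alphabet,
                        descriptions=descriptions)


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    """Write (id, seq) pairs as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def parse_sample_map(path: str | os.PathLike) -> SampleMap:
    """Parse the two-column (read file, library) TSV sample map.

    '#'-prefixed lines are comments.  Relative paths are resolved against
    the map file's directory.  Every referenced file must exist.
    """
    base = Path(path).parent
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}")
            fpath, lib = fields[0].strip(), fields[1].strip()
            resolved = Path(fpath)
            if not resolved.is_absolute():
                resolved = base / resolved
            if not resolved.exists():
                raise ParseError(f"{path}: line {lineno}: file not found: {fpath}")
            entries.append((str(resolved), lib))
    return SampleMap(entries=entries)


def load_reads(sample_map: SampleMap) -> list[Read]:
    """Load every read file in the sample map, labelling reads by library."""
    reads: list[Read] = []
    for fpath, lib in sample_map.entries:
        if fpath.endswith((".fasta", ".fa", ".fna")):
            refset = read_fasta(fpath)
            reads.extend(Read(id=rid, seq=seq, library=lib)
                         for rid, seq in refset.records)
        else:
            reads.extend(read_fastq(fpath, library=lib))
    ids = [r.id for r in reads]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ParseError(f"duplicate read ids across libraries: {dupes}")
    return reads
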