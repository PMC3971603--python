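"""End-to-end orchestration: trim -> assemble -> map -> (chimera) ->
dereplicate -> translate -> down-sample -> export.

The pipeline is a pure function of (input reads, config, seed): every output
file carries the seed in a '#' header where randomness is involved, and the
run manifest records a SHA-256 checksum per artifact so reruns can be
verified byte-identical.  Reference sets are optional: OTU formation and
abundance never depend on them; they power only the chimera screen,
reading-frame identification and evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chimera import C3Params, classify_otus, filter_chimeras, write_verdicts
from .dbg import DbgParams, dbg_assemble
from .io import Read, ReferenceSet, write_fasta
from .mapping import (AbundanceTable, MappingParams, count_abundance,
                      downsample, map_reads, write_assignments)
from .olc import OlcParams, olc_assemble
from .translate import collapse_peptides, dereplicate_nt, find_frame
from .trim import PrimerSpec, trim_reads, write_trim_report

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs up to that stage are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    engine: str = "olc"  # 'olc' | 'dbg'
    primers: PrimerSpec | None = None
    olc: OlcParams = field(default_factory=OlcParams)
    dbg: DbgParams = field(default_factory=DbgParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    c3_end_len: int = 150
    c3_min_end_identity: float = 60.0
    skip_chimera: bool = False
    exclude_internal_stop: bool = True
    seed: int = 0
    outdir: str | Path = "otuasm_out"

    def __post_init__(self):
        if self.engine not in ("olc", "dbg"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class PipelineResult:
    otus: list[tuple[str, str]]
    assignments: list
    table: AbundanceTable
    peptide_otus: list
    peptide_table: AbundanceTable
    downsampled: AbundanceTable | None
    unassembled: list[str]
    verdicts: list
    manifest: dict[str, str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(reads: list[Read], config: PipelineConfig,
                 reference: ReferenceSet | None = None,
                 protein_reference: ReferenceSet | None = None
                 ) -> PipelineResult:
    """Run the full profiling pipeline on labelled reads.

    reference (nucleotide) powers the C3 chimera screen; protein_reference
    powers reading-frame identification (without it the longest-ORF fallback
    is used).  Returns in-memory results plus a manifest of written files.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    libraries = []
    for r in reads:
        if r.library not in libraries:
            libraries.append(r.library)

    def _emit(name: str) -> Path:
        return out / name

    def _record(path: Path) -> None:
        manifest[path.name] = _sha256(path)

    stage = "trim"
    try:
        if config.primers is not None:
            kept, reports = trim_reads(reads, config.primers)
            write_trim_report(reports, _emit("trim_report.tsv"))
            _record(_emit("trim_report.tsv"))
        else:
            kept = reads
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    stage = "assemble"
    try:
        if config.engine == "olc":
            otu_objs, unassembled = olc_assemble(kept, config.olc)
            otus = [(o.id, o.consensus) for o in otu_objs]
        else:
            contigs = dbg_assemble(kept, config.dbg)
            otus = [(c.id, c.seq) for c in contigs]
            unassembled = []
        write_fasta(otus, _emit("otu_nt.fasta"))
        _record(_emit("otu_nt.fasta"))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    stage = "map"
    try:
        assignments = map_reads(kept, otus, config.mapping)
        write_assignments(assignments, _emit("assignments.tsv"))
        _record(_emit("assignments.tsv"))
        table = count_abundance(assignments, libraries,
                                otu_ids=[o for o, _ in otus])
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    verdicts = []
    if not config.skip_chimera and reference is not None:
        stage = "chimera"
        try:
            params = C3Params(reference=reference, end_len=config.c3_end_len,
                              min_end_identity=config.c3_min_end_identity)
            verdicts = classify_otus(otus, params)
            write_verdicts(verdicts, _emit("chimera_verdicts.tsv"))
            _record(_emit("chimera_verdicts.tsv"))
            otus, table, report = filter_chimeras(otus, table, verdicts)
            if not otus:
                logger.warning("all OTUs were flagged chimeric")
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    stage = "dereplicate"
    try:
        otus, table, derep_groups = dereplicate_nt(otus, table)
        table.to_tsv(_emit("otu_abundance.tsv"), seed=config.seed)
        _record(_emit("otu_abundance.tsv"))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    stage = "translate"
    try:
        framed = {oid: find_frame(seq, protein_reference)
                  for oid, seq in otus}
        peptide_otus, peptide_table, excluded = collapse_peptides(
            framed, table, exclude_internal_stop=config.exclude_internal_stop)
        write_fasta([(p.id, p.peptide) for p in peptide_otus],
                    _emit("otu_aa.fasta"))
        _record(_emit("otu_aa.fasta"))
        peptide_table.to_tsv(_emit("peptide_abundance.tsv"), seed=config.seed)
        _record(_emit("peptide_abundance.tsv"))
        with open(_emit("peptide_membership.tsv"), "w") as fh:
            fh.write("# peptide_otu\tnt_otu\tframe\n")
            for p in peptide_otus:
                for m in sorted(p.member_nt_otus):
                    fh.write(f"{p.id}\t{m}\t{p.frames[m]:+d}\n")
        _record(_emit("peptide_membership.tsv"))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    stage = "downsample"
    downsampled = None
    try:
        mapped_depths = table.counts.sum(axis=0)
        if len(libraries) > 1 and (mapped_depths > 0).all():
            downsampled, _ = downsample(assignments, libraries, config.seed,
                                        otu_ids=[o for o, _ in otus])
            downsampled.to_tsv(_emit("otu_abundance_downsampled.tsv"),
                               seed=config.seed)
            _record(_emit("otu_abundance_downsampled.tsv"))
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    stage = "export"
    try:
        export_mothur_shared(table, "nt_otu", _emit("otu.shared"))
        _record(_emit("otu.shared"))
        export_mothur_shared(peptide_table, "aa_otu", _emit("peptide.shared"))
        _record(_emit("peptide.shared"))
        export_alignment_and_tree_inputs(otus,
                                         [(p.id, p.peptide)
                                          for p in peptide_otus], out)
        _record(_emit("alignment_input_nt.fasta"))
        _record(_emit("alignment_input_aa.fasta"))
        with open(_emit("manifest.json"), "w") as fh:
            json.dump({"seed": config.seed, "engine": config.engine,
                       "artifacts": manifest}, fh, indent=2, sort_keys=True)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    return PipelineResult(otus=otus, assignments=assignments, table=table,
                          peptide_otus=peptide_otus,
                          peptide_table=peptide_table,
                          downsampled=downsampled, unassembled=unassembled,
                          verdicts=verdicts, manifest=manifest)


def export_mothur_shared(table: AbundanceTable, label: str, path) -> None:
    """Write a MOTHUR 'shared'-format abundance file.

    Header 'label<TAB>Group<TAB>numOtus<TAB><otu ids...>'; one row per
    library with integer counts in a fixed OTU column order.
    """
    otu_ids = table.otu_ids
    with open(path, "w") as fh:
        fh.write("label\tGroup\tnumOtus\t" + "\t".join(otu_ids) + "\n")
        for lib in table.libraries:
            vals = "\t".join(str(int(table.counts.loc[o, lib]))
                             for o in otu_ids)
            fh.write(f"{label}\t{lib}\t{len(otu_ids)}\t{vals}\n")


def read_mothur_shared(path) -> tuple[str, "AbundanceTable"]:
    """Strict parser for the shared dialect written above (round-trip aid)."""
    import pandas as pd
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["label", "Group", "numOtus"]:
            raise ValueError("not a shared file")
        otu_ids = header[3:]
        rows = {}
        label = ""
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            label, lib, n = fields[0], fields[1], int(fields[2])
            if n != len(otu_ids):
                raise ValueError("numOtus mismatch")
            rows[lib] = [int(v) for v in fields[3:]]
    counts = pd.DataFrame(rows, index=otu_ids)
    unmapped = pd.Series(0, index=counts.columns)
    return label, AbundanceTable(counts, unmapped)


def export_alignment_and_tree_inputs(nt_otus: list[tuple[str, str]],
                                     aa_otus: list[tuple[str, str]],
                                     outdir) -> tuple[Path, Path]:
    """FASTA inputs for external multiple alignment / phylogeny tools.

    Ids match the abundance tables exactly; both nucleotide and peptide
    files are always written (a peptide file may be empty if every OTU was
    excluded, with a warning).
    """
    out = Path(outdir)
    nt_path = out / "alignment_input_nt.fasta"
    aa_path = out / "alignment_input_aa.fasta"
    write_fasta(nt_otus, nt_path)
    if not aa_otus:
        logger.warning("no peptide OTUs to export; writing empty FASTA")
    write_fasta(aa_otus, aa_path)
    return nt_path, aa_path
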