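"""Data model for circular annotated mitochondrial genomes and file I/O.

Coordinates follow the convention of printed mitogenome annotation tables:
1-based, inclusive, on the majority (F/H) strand.  A feature with
``start > end`` wraps the circular origin.  Internal arithmetic converts to
0-based half-open indices at the boundary of each operation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

#: IUPAC nucleotide alphabet (unambiguous + ambiguity codes).
IUPAC_NT = set("ACGTRYSWKMBDHVN")

_ABSENT_CELLS = {"", "-", "–", "—"}  # dash, en dash, em dash

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

ANNOTATION_COLUMNS = [
    "Gene",
    "Direction",
    "Start",
    "End",
    "Size",
    "Anticodon",
    "StartCodon",
    "StopCodon",
    "IntergenicNucleotides",
]


class AnnotationParseError(ValueError):
    """Raised when an annotation table row cannot be interpreted."""


class SequenceUnavailableError(RuntimeError):
    """Raised when a sequence-level operation is attempted in table-only mode."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def infer_feature_class(name: str) -> str:
    lowered = name.lower()
    if lowered.startswith("trn"):
        return "tRNA"
    if lowered.startswith("rrn"):
        return "rRNA"
    if "rich" in lowered or "d-loop" in lowered or "control" in lowered:
        return "control_region"
    return "PCG"


@dataclass
class GeneRecord:
    """One annotated feature on a circular genome.

    ``size_printed`` and ``intergenic_printed`` hold the values exactly as
    printed in the source table; recomputed values never overwrite them.
    """

    name: str
    feature_class: str
    strand: str  # "F" or "R"
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    intergenic_printed: Optional[int] = None
    size_printed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("F", "R"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.name}")

    @property
    def wraps(self) -> bool:
        """True when the feature spans the circular origin."""
        return self.start > self.end


@dataclass
class AnnotatedGenome:
    """Circular genome: ordered gene records plus an optional sequence."""

    identifier: str
    length: int
    records: list[GeneRecord] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None

    def records_of_class(self, feature_class: str) -> list[GeneRecord]:
        return [r for r in self.records if r.feature_class == feature_class]

    def record(self, name: str) -> GeneRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(f"no record named {name!r}")


def gene_length(record: GeneRecord, genome_length: int) -> int:
    """Feature length in bp from circular 1-based inclusive coordinates."""
    for pos in (record.start, record.end):
        if not 1 <= pos <= genome_length:
            raise ValueError(
                f"{record.name}: coordinate {pos} outside [1, {genome_length}]"
            )
    if record.wraps:
        return (genome_length - record.start + 1) + record.end
    return record.end - record.start + 1


def extract_feature_sequence(genome: AnnotatedGenome, record: GeneRecord) -> str:
    """Feature sequence in coding orientation (R-strand features are
    reverse-complemented).  Circular wrap is handled."""
    if genome.sequence is None:
        raise SequenceUnavailableError(
            f"cannot extract {record.name}: genome {genome.identifier} has no sequence"
        )
    seq = genome.sequence
    if record.wraps:
        fragment = seq[record.start - 1 :] + seq[: record.end]
    else:
        fragment = seq[record.start - 1 : record.end]
    if record.strand == "R":
        return reverse_complement(fragment)
    return fragment


def _parse_int(cell: str, column: str, row: int):
    cell = cell.strip()
    if cell in _ABSENT_CELLS:
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise AnnotationParseError(
            f"row {row}: column {column!r} has malformed value {cell!r}"
        ) from exc


def read_annotation_table(path) -> AnnotatedGenome:
    """Read a tab-separated annotation table (table-only mode, no sequence).

    Genome length is set to the maximum end coordinate over all records.
    """
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise AnnotationParseError(f"{path}: empty file, expected a header")
        missing = [c for c in ("Gene", "Direction", "Start", "End") if c not in reader.fieldnames]
        if missing:
            raise AnnotationParseError(f"{path}: missing columns {missing}")
        records: list[GeneRecord] = []
        for i, row in enumerate(reader, start=2):
            name = (row.get("Gene") or "").strip()
            if not name:
                raise AnnotationParseError(f"row {i}: empty gene name")
            direction = (row.get("Direction") or "").strip()
            if direction in _ABSENT_CELLS:
                direction = "F"  # control-region rows print no direction
            if direction not in ("F", "R"):
                raise AnnotationParseError(
                    f"row {i}: unknown strand symbol {direction!r}"
                )
            start = _parse_int(row.get("Start", ""), "Start", i)
            end = _parse_int(row.get("End", ""), "End", i)
            if start is None or end is None:
                raise AnnotationParseError(f"row {i}: missing coordinate")

            def _text(col: str) -> Optional[str]:
                cell = (row.get(col) or "").strip()
                return None if cell in _ABSENT_CELLS else cell

            records.append(
                GeneRecord(
                    name=name,
                    feature_class=infer_feature_class(name),
                    strand=direction,
                    start=start,
                    end=end,
                    anticodon=_text("Anticodon"),
                    start_codon=_text("StartCodon"),
                    stop_codon=_text("StopCodon"),
                    intergenic_printed=_parse_int(
                        row.get("IntergenicNucleotides", ""), "IntergenicNucleotides", i
                    ),
                    size_printed=_parse_int(row.get("Size", ""), "Size", i),
                )
            )
    length = max((r.end for r in records), default=0)
    return AnnotatedGenome(identifier=path.stem, length=length, records=records)


def write_annotation_table(genome: AnnotatedGenome, path) -> None:
    """Write the annotation table TSV; absent cells are written as "-"."""

    def cell(value) -> str:
        return "-" if value is None else str(value)

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for rec in genome.records:
            size = rec.size_printed
            if size is None:
                size = gene_length(rec, genome.length)
            writer.writerow(
                [
                    rec.name,
                    rec.strand,
                    rec.start,
                    rec.end,
                    size,
                    cell(rec.anticodon),
                    cell(rec.start_codon),
                    cell(rec.stop_codon),
                    cell(rec.intergenic_printed),
                ]
            )


def _validate_sequence(seq: str, source: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_NT
    if bad:
        raise ValueError(f"{source}: non-IUPAC characters {sorted(bad)}")
    return seq


def read_fasta(path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (identifier, upper-cased sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return rec.id, _validate_sequence(str(rec.seq), str(path))


def write_fasta(identifier: str, sequence: str, path, width: int = 70) -> None:
    with open(path, "w") as handle:
        handle.write(f">{identifier}\n")
        for i in range(0, len(sequence), width):
            handle.write(sequence[i : i + width] + "\n")


_GENBANK_TYPE = {
    "PCG": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
}
_CLASS_FROM_TYPE = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "control_region",
}


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write a circular GenBank flat file with one feature per record."""
    if genome.sequence is None:
        raise SequenceUnavailableError("GenBank output requires a sequence")
    seqrec = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description="circular mitochondrial genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for rec in genome.records:
        strand = 1 if rec.strand == "F" else -1
        if rec.wraps:
            loc = CompoundLocation(
                [
                    FeatureLocation(rec.start - 1, genome.length, strand),
                    FeatureLocation(0, rec.end, strand),
                ]
            )
        else:
            loc = FeatureLocation(rec.start - 1, rec.end, strand)
        qualifiers = {"gene": [rec.name]}
        if rec.anticodon:
            qualifiers["note"] = [f"anticodon:{rec.anticodon}"]
        seqrec.features.append(
            SeqFeature(loc, type=_GENBANK_TYPE[rec.feature_class], qualifiers=qualifiers)
        )
    SeqIO.write([seqrec], str(path), "genbank")


def read_genbank(path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`."""
    seqrec = SeqIO.read(str(path), "genbank")
    sequence = _validate_sequence(str(seqrec.seq), str(path))
    records: list[GeneRecord] = []
    for feat in seqrec.features:
        if feat.type not in _CLASS_FROM_TYPE:
            continue  # skip source / gene duplicates
        fclass = _CLASS_FROM_TYPE[feat.type]
        name = feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))[0]
        parts = feat.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        strand = "R" if feat.location.strand == -1 else "F"
        anticodon = None
        for note in feat.qualifiers.get("note", []):
            if note.startswith("anticodon:"):
                anticodon = note.split(":", 1)[1]
        records.append(
            GeneRecord(
                name=name,
                feature_class=fclass,
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
            )
        )
    return AnnotatedGenome(
        identifier=seqrec.id,
        length=len(sequence),
        records=records,
        sequence=sequence,
    )


def consistency_report(genome: AnnotatedGenome) -> list[dict]:
    """Flag printed table values that disagree with coordinate arithmetic.

    Printed values are never corrected; each disagreement yields one row with
    the printed and the recomputed value.  Covers the Size column and the
    intergenic-nucleotides column (gap to the next feature in table order).
    """
    issues: list[dict] = []
    for rec in genome.records:
        computed = gene_length(rec, genome.length)
        if rec.size_printed is not None and rec.size_printed != computed:
            issues.append(
                {
                    "record": rec.name,
                    "field": "Size",
                    "printed": rec.size_printed,
                    "computed": computed,
                }
            )
    n = len(genome.records)
    for i, rec in enumerate(genome.records):
        if rec.intergenic_printed is None:
            continue
        nxt = genome.records[(i + 1) % n]
        if i + 1 < n:
            gap = nxt.start - rec.end - 1
        else:
            gap = (nxt.start - 1) + (genome.length - rec.end)
        if gap != rec.intergenic_printed:
            issues.append(
                {
                    "record": f"{rec.name}->{nxt.name}",
                    "field": "IntergenicNucleotides",
                    "printed": rec.intergenic_printed,
                    "computed": gap,
                }
            )
    return issues


def bundled_annotation_path() -> Path:
    """Path of the packaged hawk-moth annotation table fixture."""
    return Path(__file__).parent / "data" / "daphnis_nerii_annotation.tsv"


def bundled_composition_path() -> Path:
    """Path of the packaged lepidopteran composition/skew table fixture."""
    return Path(__file__).parent / "data" / "lepidoptera_composition.tsv"


def load_reference_annotation() -> AnnotatedGenome:
    genome = read_annotation_table(bundled_annotation_path())
    genome.identifier = "D_nerii"
    return genome
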