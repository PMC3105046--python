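"""Sequence and annotation I/O, and the coordinate conventions used throughout.

Internal coordinates are 0-based, half-open everywhere.  User-facing reports
are either 1-based inclusive (printed genomic positions, BED being the
0-based exception the format requires) or signed TSS-relative offsets with no
zero: the transcription start site itself is ``+1`` and the base immediately
upstream is ``-1``, matching the way promoter-element positions such as
``-30`` (a TATA box 30 bp upstream of the initiator) are quoted.

FASTA reading/writing goes through Biopython.  Gene annotations are read
either from a genes-only GFF3 subset (1-based inclusive, converted on load)
or from a simple TSV dialect (``gene_id  chrom  start  end  strand``) that is
already 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _bio_seqio
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "Interval",
    "GeneAnnotation",
    "load_sequences",
    "write_fasta",
    "load_annotations",
    "write_annotations",
    "write_bed",
    "tss_relative",
    "tss_absolute",
    "reverse_complement",
    "inclusive_length",
]

#: Characters accepted in input sequences (DNA plus IUPAC ambiguity codes).
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

STRANDS = frozenset({"+", "-", "."})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def inclusive_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive coordinate pair as printed in reports."""
    return end - start + 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence) or end <= start:
            raise IndexError(
                f"[{start}, {end}) out of bounds for record {self.id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end {self.end} must exceed start {self.start}")
        # Accept the typographic middle dot used in some annotation dumps.
        if self.strand == "·":
            object.__setattr__(self, "strand", ".")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated gene: an id plus a stranded interval."""

    gene_id: str
    interval: Interval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-'"
            )


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

def load_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read sequences from a FASTA file.

    Sequences are uppercased and RNA ``U`` is normalised to ``T``.  Any
    character outside the IUPAC DNA alphabet raises a :class:`ValueError`
    naming the offending record.
    """
    if format != "fasta":
        raise ValueError(f"unsupported sequence format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[SequenceRecord] = []
    for rec in _bio_seqio.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        try:
            records.append(
                SequenceRecord(id=rec.id, sequence=seq, description=rec.description)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    bio_records = [
        _BioSeqRecord(_BioSeq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = _bio_seqio.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _parse_gff3_line(line: str, lineno: int) -> GeneAnnotation | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ValueError(f"line {lineno}: expected 9 tab-separated fields")
    chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
    if ftype != "gene":
        return None
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end1 < start1:
        raise ValueError(f"line {lineno}: end {end1} < start {start1}")
    gene_id = None
    for item in attrs.split(";"):
        key, _, value = item.strip().partition("=")
        if key == "ID":
            gene_id = value
            break
    if gene_id is None:
        gene_id = f"gene_line{lineno}"
    # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
    return GeneAnnotation(
        gene_id, Interval(chrom, start1 - 1, end1, strand=strand)
    )


def _parse_tsv_line(line: str, lineno: int) -> GeneAnnotation:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 5:
        raise ValueError(f"line {lineno}: expected 5 tab-separated fields")
    gene_id, chrom, start_s, end_s, strand = fields
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end < start:
        raise ValueError(f"line {lineno}: end {end} < start {start}")
    return GeneAnnotation(gene_id, Interval(chrom, start, end, strand=strand))


def load_annotations(path: str | Path, format: str = "gff3") -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (genes only) or the TSV dialect.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention on load; the TSV dialect is already internal.
    Malformed rows raise :class:`ValueError` with the line number.
    """
    if format not in ("gff3", "tsv"):
        raise ValueError(f"unsupported annotation format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    genes: list[GeneAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                if format == "gff3":
                    gene = _parse_gff3_line(line, lineno)
                    if gene is None:
                        continue
                else:
                    gene = _parse_tsv_line(line, lineno)
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
            genes.append(gene)
    return genes


def write_annotations(
    genes: Sequence[GeneAnnotation], path: str | Path, format: str = "gff3"
) -> None:
    """Write gene annotations in GFF3 (genes only) or the TSV dialect."""
    if format not in ("gff3", "tsv"):
        raise ValueError(f"unsupported annotation format {format!r}")
    with open(path, "w") as handle:
        if format == "gff3":
            handle.write("##gff-version 3\n")
            for g in genes:
                iv = g.interval
                handle.write(
                    f"{iv.chrom}\t.\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={g.gene_id}\n"
                )
        else:
            for g in genes:
                iv = g.interval
                handle.write(
                    f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n"
                )


def write_bed(
    intervals: Sequence[Interval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open, as the format requires)."""
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals one-to-one")
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region{i + 1}"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# TSS-relative coordinates
# ---------------------------------------------------------------------------

def tss_relative(abs_pos: int, tss: int, strand: str = "+") -> int:
    """Signed TSS-relative offset of an absolute position (no zero).

    The TSS itself maps to ``+1``; the base immediately upstream maps to
    ``-1``.  On the minus strand, upstream means larger absolute coordinates.
    """
    if strand == "+":
        d = abs_pos - tss
    elif strand == "-":
        d = tss - abs_pos
    else:
        raise ValueError("strand must be '+' or '-'")
    return d + 1 if d >= 0 else d


def tss_absolute(rel_pos: int, tss: int, strand: str = "+") -> int:
    """Inverse of :func:`tss_relative`."""
    if rel_pos == 0:
        raise ValueError("TSS-relative coordinates have no zero")
    d = rel_pos - 1 if rel_pos > 0 else rel_pos
    if strand == "+":
        return tss + d
    if strand == "-":
        return tss - d
    raise ValueError("strand must be '+' or '-'")
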