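"""Genome / gene-table input and the 4-level digitization of DNA.

Nucleotides are mapped to integers A->0, G->1, C->2, T->3, turning every
gene into a short integer time series whose long-range correlation can be
quantified by a Hurst exponent.  Coordinates follow the GenBank convention:
1-based, inclusive on both ends; minus-strand genes are reverse-complemented
before digitization so the coding strand is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .exceptions import (
    AmbiguousBaseError,
    DomainError,
    FormatError,
    InputError,
    RangeError,
    RecordError,
    RepliconMismatchError,
)

#: nucleotide -> digit mapping used throughout the package
DIGIT_OF_BASE = {"A": 0, "G": 1, "C": 2, "T": 3}
BASE_OF_DIGIT = "AGCT"

STRANDS = frozenset({"+", "-"})
ESSENTIALITY_LABELS = frozenset({"essential", "nonessential", "unknown"})

#: genes shorter than this are excluded from Hurst estimation (the log-log
#: regressions need several octaves of scales)
MIN_GENE_LENGTH = 64


@dataclass(frozen=True)
class GenomeSequence:
    """One replicon: an id plus its uppercase residue string."""

    replicon_id: str
    residues: str

    def __post_init__(self):
        if not self.replicon_id:
            raise FormatError("replicon_id must be non-empty")
        if not self.residues:
            raise FormatError(f"record {self.replicon_id!r} has zero residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with 1-based inclusive coordinates."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    essentiality: str = "unknown"

    def __post_init__(self):
        if self.start < 1:
            raise RecordError(f"gene {self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise RecordError(
                f"gene {self.gene_id}: start ({self.start}) > end ({self.end})"
            )
        if self.strand not in STRANDS:
            raise RecordError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {sorted(STRANDS)}"
            )
        if self.essentiality not in ESSENTIALITY_LABELS:
            raise RecordError(
                f"gene {self.gene_id}: essentiality {self.essentiality!r} "
                f"not one of {sorted(ESSENTIALITY_LABELS)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DigitizedSequence:
    """Integer series over {0,1,2,3} derived from a nucleotide sequence."""

    source_id: str
    values: np.ndarray = field(compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 1 or values.size < 1:
            raise InputError("digitized series must be a non-empty 1-d array")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into GenomeSequence objects.

    The header token before the first whitespace becomes the replicon id;
    residues are uppercased.  Raises InputError for a missing file and
    FormatError for an empty file or a record with no residues.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = [
        GenomeSequence(replicon_id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


GENE_TABLE_COLUMNS = ("gene_id", "replicon_id", "start", "end", "strand", "essentiality")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the tab-separated gene table.

    Expected header: ``gene_id replicon_id start end strand essentiality``
    (tab separated); ``#``-prefixed lines are ignored.  Invalid rows raise
    RecordError naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene table not found: {path}")
    genes: list[GeneRecord] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != GENE_TABLE_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header "
                        f"{' '.join(GENE_TABLE_COLUMNS)!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise RecordError(
                    f"{path}:{lineno}: expected {len(GENE_TABLE_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            gene_id, replicon_id, start, end, strand, essentiality = fields
            strand = strand.replace("−", "-")  # typographic minus
            try:
                gene = GeneRecord(
                    gene_id=gene_id,
                    replicon_id=replicon_id,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    essentiality=essentiality,
                )
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            except RecordError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    if not header_seen:
        raise FormatError(f"{path}: empty gene table (no header line)")
    return genes


def reverse_complement(sequence: str) -> str:
    """Reverse complement, delegating to Biopython (IUPAC-aware)."""
    return str(Seq(sequence).reverse_complement())


def extract_gene_sequence(genome: GenomeSequence, gene: GeneRecord) -> str:
    """Extract a gene's residues from its replicon.

    Returns the 1-based inclusive slice [start, end]; minus-strand genes are
    returned reverse-complemented (coding strand).
    """
    if gene.replicon_id != genome.replicon_id:
        raise RepliconMismatchError(
            f"gene {gene.gene_id} references replicon {gene.replicon_id!r}, "
            f"genome provides {genome.replicon_id!r}"
        )
    if gene.end > len(genome):
        raise RangeError(
            f"gene {gene.gene_id}: end {gene.end} exceeds replicon length {len(genome)}"
        )
    segment = genome.residues[gene.start - 1 : gene.end]
    if gene.strand == "-":
        segment = reverse_complement(segment)
    return segment


def digitize(sequence: str, source_id: str = "") -> DigitizedSequence:
    """Digitize a nucleotide string: A->0, G->1, C->2, T->3.

    Residues outside {A,C,G,T} are never silently substituted: an
    AmbiguousBaseError identifies the first offending position, and callers
    that batch over genes exclude (and log) the gene instead.
    """
    if not sequence:
        raise InputError("cannot digitize an empty sequence")
    seq = sequence.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for base, digit in DIGIT_OF_BASE.items():
        lut[ord(base)] = digit
    values = lut[codes]
    bad = np.nonzero(values < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise AmbiguousBaseError(seq[pos], pos)
    return DigitizedSequence(source_id=source_id, values=values)


def undigitize(values: Iterable[int]) -> str:
    """Inverse of :func:`digitize`: 0->A, 1->G, 2->C, 3->T."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.size == 0:
        raise InputError("cannot un-digitize an empty series")
    if np.any((arr < 0) | (arr > 3)):
        raise DomainError(f"digits outside 0..3 present: {np.unique(arr)}")
    return "".join(BASE_OF_DIGIT[int(v)] for v in arr)
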