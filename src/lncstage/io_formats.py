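"""Readers, writers and core containers for the formats the pipeline touches.

Conventions fixed here once and tested once:

* every genomic interval is stored 0-based, half-open ``[start, end)``;
  GFF3 (1-based, inclusive) is converted at the boundary;
* nucleotide sequences are uppercase over ``{A, C, G, T, N}``; ``U`` is mapped
  to ``T`` on input and any other ambiguity code is rejected;
* FASTA output is wrapped at 60 columns so round trips are byte-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGTN")

#: GFF3 feature types / BED name tokens treated as protein-coding gene loci.
CODING_FEATURE_TYPES = frozenset(
    {"gene", "mRNA", "CDS", "coding_gene", "protein_coding_gene"}
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: ID, sequence, optional genomic interval and exons.

    ``interval`` is ``(chromosome, start, end, strand)`` with 0-based
    half-open coordinates; ``exons`` are half-open genomic sub-intervals of
    ``interval`` whose total span equals the sequence length.
    """

    transcript_id: str
    sequence: str
    interval: tuple[str, int, int, str] | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for transcript {self.transcript_id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r}: invalid characters {sorted(bad)}; "
                "sequences must be uppercase over A,C,G,T,N"
            )
        if self.interval is not None:
            chrom, start, end, strand = self.interval
            if start >= end:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: interval start {start} >= end {end}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"transcript {self.transcript_id!r}: bad strand {strand!r}")
        if self.exons is not None:
            prev_end = None
            total = 0
            for s, e in self.exons:
                if s >= e:
                    raise ValueError(
                        f"transcript {self.transcript_id!r}: exon start {s} >= end {e}"
                    )
                if prev_end is not None and s < prev_end:
                    raise ValueError(
                        f"transcript {self.transcript_id!r}: exons overlap or are unsorted"
                    )
                prev_end = e
                total += e - s
            if total != len(self.sequence):
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exon span {total} != "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    chromosome: str
    start: int
    end: int
    strand: str
    feature_class: str  # "coding_gene" | "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")
        if self.feature_class not in ("coding_gene", "other"):
            raise ValueError(f"bad feature_class {self.feature_class!r}")


@dataclass
class AnnotationSet:
    """Genomic intervals (0-based half-open) indexable for overlap queries."""

    records: tuple[AnnotationRecord, ...]
    _coding_trees: dict[str, IntervalTree] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.records = tuple(self.records)

    def _trees(self) -> dict[str, IntervalTree]:
        if self._coding_trees is None:
            trees: dict[str, IntervalTree] = {}
            for rec in self.records:
                if rec.feature_class == "coding_gene":
                    trees.setdefault(rec.chromosome, IntervalTree()).addi(
                        rec.start, rec.end, rec
                    )
            self._coding_trees = trees
        return self._coding_trees

    def overlaps_coding(self, chromosome: str, start: int, end: int) -> bool:
        """True when [start, end) overlaps any coding_gene interval (any strand)."""
        tree = self._trees().get(chromosome)
        return bool(tree is not None and tree.overlap(start, end))


class ExpressionMatrix:
    """Transcripts x ordered developmental stages of nonnegative FPKM values."""

    def __init__(self, df: pd.DataFrame) -> None:
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript IDs: {dups}")
        if df.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 stages")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing/non-numeric value at row {df.index[r]!r}, stage {df.columns[c]!r}"
            )
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at row {df.index[r]!r}, stage {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative FPKM at row {df.index[r]!r}, stage {df.columns[c]!r}"
            )
        self._df = df.astype(float)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def row_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def stage_labels(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into validated :class:`TranscriptRecord` objects.

    The transcript ID is the first whitespace-delimited header token.
    Sequences are uppercased and RNA ``U`` is mapped to ``T``; duplicate IDs
    and empty sequences are hard errors.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate ID {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for transcript {rec.id!r}")
        records.append(TranscriptRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns (Biopython default)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a stage x transcript FPKM table.

    First column header must be ``transcript_id``; remaining headers are
    stage labels in developmental order. Negative, missing or non-numeric
    cells are hard errors naming the row and column.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 3:
        raise ValueError("expression table needs transcript_id plus >= 2 stages")
    if raw.columns[0] != "transcript_id":
        raise ValueError(
            f"first column must be 'transcript_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("transcript_id")
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"stage {raw.columns[c]!r}"
        )
    return ExpressionMatrix(parsed)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.df.copy()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation (GFF3 / BED)
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    dialect: str,
    coding_feature_types: frozenset[str] = CODING_FEATURE_TYPES,
) -> AnnotationSet:
    """Read genomic intervals from GFF3 or BED.

    GFF3 starts (1-based inclusive) are converted to 0-based half-open;
    BED is already half-open and passes through unchanged. The feature class
    is taken from the GFF3 type column or the BED name column and mapped to
    ``coding_gene`` when it is in *coding_feature_types*, else ``other``.
    """
    if dialect not in ("GFF3", "BED"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "GFF3":
                cols = line.split("\t")
                if len(cols) < 7:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
                chrom, _, ftype = cols[0], cols[1], cols[2]
                start = int(cols[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(cols[4])
                strand = cols[6]
                token = ftype
            else:
                cols = line.split()
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed BED line")
                chrom = cols[0]
                start = int(cols[1])
                end = int(cols[2])
                token = cols[3] if len(cols) > 3 else "."
                strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            if strand == ".":
                strand = "+"
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end} after normalization"
                )
            fclass = "coding_gene" if token in coding_feature_types else "other"
            records.append(AnnotationRecord(chrom, start, end, strand, fclass))
    return AnnotationSet(tuple(records))


def write_bed(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in annotation.records:
            fh.write(
                f"{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.feature_class}"
                f"\t0\t{rec.strand}\n"
            )


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.records:
            fh.write(
                f"{rec.chromosome}\tlncstage\t{rec.feature_class}\t{rec.start + 1}"
                f"\t{rec.end}\t.\t{rec.strand}\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# plain-text ID lists
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> list[str]:
    """One ID per line; blank lines and '#' comments ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
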