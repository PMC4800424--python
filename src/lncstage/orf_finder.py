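"""Open-reading-frame detection for the maximal-ORF length filter.

An ORF starts at ATG and runs to the first in-frame stop (TAA/TAG/TGA),
giving a *complete* ORF, or to the end of the sequence (3'-partial,
``has_stop=False``). Codons containing N are neither starts nor stops and
terminate a growing ORF. ``aa_length`` counts encoded residues excluding the
stop codon, so the paper-style ">100 amino acids" filter compares against
the residue count of the longest ORF on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """One maximal ORF; ``nt_start`` is a 0-based offset on the reported strand."""

    strand: str  # "+" | "-"
    frame: int  # 0 | 1 | 2
    nt_start: int
    aa_length: int
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if self.aa_length < 1:
            raise ValueError("aa_length must be >= 1")

    @property
    def nt_length(self) -> int:
        """ORF footprint in nucleotides, stop codon included when present."""
        return 3 * self.aa_length + (3 if self.has_stop else 0)


def _scan_forward(seq: str, strand: str, min_aa: int) -> list[OrfHit]:
    hits: list[OrfHit] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    aa = (i - start) // 3
                    if aa >= min_aa:
                        hits.append(OrfHit(strand, frame, start, aa, True, True))
                    start = None
            elif "N" in codon:
                # N codons are non-start, non-stop and non-countable: they
                # end a growing ORF without providing a stop.
                if start is not None:
                    aa = (i - start) // 3
                    if aa >= min_aa:
                        hits.append(OrfHit(strand, frame, start, aa, True, False))
                    start = None
            elif codon == "ATG" and start is None:
                start = i
            i += 3
        if start is not None:
            aa = (i - start) // 3  # i is the end of the last complete codon
            if aa >= min_aa:
                hits.append(OrfHit(strand, frame, start, aa, True, False))
    return hits


def _sequence_of(record: TranscriptRecord | str) -> str:
    return record.sequence if isinstance(record, TranscriptRecord) else record


def find_orfs(
    record: TranscriptRecord | str,
    min_aa: int = 1,
    strand_mode: str = "both",
) -> list[OrfHit]:
    """Every maximal ORF with ``aa_length >= min_aa``.

    Sorted by descending amino-acid length; ties broken by strand ('+'
    first) then by smaller ``nt_start``. With ``strand_mode="both"`` the
    reverse complement is scanned as well and minus-strand coordinates refer
    to the reverse-complemented sequence.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if strand_mode not in ("forward_only", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = _sequence_of(record)
    if not seq:
        raise ValueError("empty sequence")
    hits = _scan_forward(seq, "+", min_aa)
    if strand_mode == "both":
        hits += _scan_forward(revcomp(seq), "-", min_aa)
    hits.sort(key=lambda h: (-h.aa_length, 0 if h.strand == "+" else 1, h.nt_start))
    return hits


def max_orf_aa(record: TranscriptRecord | str, strand_mode: str = "both") -> int:
    """Amino-acid length of the longest ORF, 0 when the sequence has none."""
    hits = find_orfs(record, min_aa=1, strand_mode=strand_mode)
    return hits[0].aa_length if hits else 0


def orf_report_rows(record: TranscriptRecord, strand_mode: str = "both") -> list[dict]:
    """TSV-ready rows: one dict per maximal ORF of *record*."""
    return [
        {
            "transcript_id": record.transcript_id,
            "strand": h.strand,
            "frame": h.frame,
            "nt_start": h.nt_start,
            "aa_length": h.aa_length,
            "has_start": h.has_start,
            "has_stop": h.has_stop,
        }
        for h in find_orfs(record, strand_mode=strand_mode)
    ]
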