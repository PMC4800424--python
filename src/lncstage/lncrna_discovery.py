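"""The lncRNA discovery funnel.

Candidate transcripts pass, in order: a minimum-length filter (>200 bp), a
maximal-ORF filter (removed when the longest ORF encodes >100 amino acids),
the coding-potential classifier (noncoding retained, probability < cutoff),
a CDS-similarity screen against a known coding-sequence set, and finally a
genomic-context classification (intergenic vs genic) when an annotation is
supplied. The per-stage counts form the funnel report.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coding_potential import (
    CodingModel,
    FeatureVector,
    HexamerTable,
    classify_transcript,
    coding_probability,
    extract_features,
)
from .io_formats import AnnotationSet, TranscriptRecord
from .orf_finder import max_orf_aa, revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterStage:
    name: str
    input_count: int
    retained_count: int
    removed_count: int

    def __post_init__(self) -> None:
        if self.retained_count + self.removed_count != self.input_count:
            raise ValueError(f"stage {self.name}: retained + removed != input")


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, input_count: int, retained_count: int) -> None:
        stage = FilterStage(name, input_count, retained_count, input_count - retained_count)
        if self.stages and self.stages[-1].retained_count != input_count:
            raise ValueError(
                f"stage {name}: input {input_count} != previous retained "
                f"{self.stages[-1].retained_count}"
            )
        self.stages.append(stage)

    def rows(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "input": s.input_count,
                "retained": s.retained_count,
                "removed": s.removed_count,
            }
            for s in self.stages
        ]


@dataclass
class CatalogEntry:
    record: TranscriptRecord
    features: FeatureVector
    probability: float
    context: str | None = None  # "intergenic" | "genic" | None
    novelty: str = "novel"  # "annotated" | "novel"


@dataclass
class LncRNACatalog:
    entries: list[CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e.record.transcript_id for e in self.entries]

    def rows(self) -> list[dict]:
        return [
            {
                "transcript_id": e.record.transcript_id,
                "length_bp": len(e.record),
                "orf_size": e.features.orf_size,
                "orf_coverage": e.features.orf_coverage,
                "fickett": e.features.fickett,
                "hexamer": e.features.hexamer,
                "probability": e.probability,
                "context": e.context if e.context is not None else ".",
                "novelty": e.novelty,
            }
            for e in self.entries
        ]


@dataclass(frozen=True)
class StructureStats:
    mean_length: float
    length_histogram: tuple[tuple[str, int], ...]
    mean_exon_count: float | None
    mean_intron_length: float | None


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_min_length(
    transcripts: Sequence[TranscriptRecord], min_bp: int = 200
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Retain transcripts strictly longer than *min_bp* (lncRNA: >200 bp)."""
    retained = [t for t in transcripts if len(t) > min_bp]
    removed = [t for t in transcripts if len(t) <= min_bp]
    return retained, removed


def filter_max_orf(
    transcripts: Sequence[TranscriptRecord],
    max_aa: int = 100,
    strand_mode: str = "both",
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Remove transcripts whose maximal ORF encodes strictly more than *max_aa*."""
    retained, removed = [], []
    for t in transcripts:
        (removed if max_orf_aa(t, strand_mode) > max_aa else retained).append(t)
    return retained, removed


# ---------------------------------------------------------------------------
# CDS similarity screen (seeded, ungapped-extended local matching)
# ---------------------------------------------------------------------------

def _longest_identity_window(match: np.ndarray, min_identity: float) -> int:
    """Length of the longest window whose match fraction is >= min_identity.

    Matches contribute 1 - t and mismatches -t, so a window passes iff its
    transformed sum is nonnegative; the scan finds, for each prefix, the
    earliest prefix not exceeding it.
    """
    if match.size == 0:
        return 0
    w = np.where(match, 1.0 - min_identity, -min_identity)
    prefix = np.concatenate([[0.0], np.cumsum(w)])
    minpre = np.minimum.accumulate(prefix)
    best = 0
    neg = -minpre  # non-decreasing
    for j in range(len(prefix)):
        i = int(np.searchsorted(neg, -(prefix[j] + 1e-12), side="left"))
        if i <= j and j - i > best:
            best = j - i
    return best


def _kmer_index(cds_set: Sequence[TranscriptRecord], kmer: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, cds in enumerate(cds_set):
        s = cds.sequence
        for p in range(len(s) - kmer + 1):
            km = s[p : p + kmer]
            if "N" not in km:
                index.setdefault(km, []).append((ci, p))
    return index


def cds_similarity_screen(
    candidates: Sequence[TranscriptRecord],
    cds_set: Sequence[TranscriptRecord],
    kmer: int = 11,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> tuple[list[TranscriptRecord], list[tuple[TranscriptRecord, str]]]:
    """Screen candidates against a CDS set on both strands.

    A candidate is removed when some CDS shares a k-mer seed lying on a
    diagonal that carries an ungapped match of identity >= *min_identity*
    covering >= *min_coverage* of the candidate. Removals carry the
    best-hit CDS ID (longest qualifying window, ties to the earlier CDS).
    """
    if not cds_set:
        raise ValueError("cds_set must be non-empty")
    if kmer < 8:
        raise ValueError("kmer must be >= 8")
    index = _kmer_index(cds_set, kmer)
    retained: list[TranscriptRecord] = []
    removed: list[tuple[TranscriptRecord, str]] = []
    for cand in candidates:
        best_len = 0
        best_cds: str | None = None
        need = min_coverage * len(cand)
        for seq in (cand.sequence, revcomp(cand.sequence)):
            diagonals: set[tuple[int, int]] = set()
            for q in range(len(seq) - kmer + 1):
                km = seq[q : q + kmer]
                if "N" in km:
                    continue
                for ci, p in index.get(km, ()):
                    diagonals.add((ci, q - p))
            for ci, diag in sorted(diagonals):
                s = cds_set[ci].sequence
                qs = max(0, diag)
                ss = qs - diag
                ovl = min(len(seq) - qs, len(s) - ss)
                if ovl < best_len or ovl < need:
                    continue
                a = np.frombuffer(seq[qs : qs + ovl].encode(), dtype="S1")
                b = np.frombuffer(s[ss : ss + ovl].encode(), dtype="S1")
                wlen = _longest_identity_window(a == b, min_identity)
                if wlen > best_len:
                    best_len = wlen
                    best_cds = cds_set[ci].transcript_id
        if best_cds is not None and best_len >= need:
            removed.append((cand, best_cds))
        else:
            retained.append(cand)
    return retained, removed


def cds_screen_from_hits(
    candidates: Sequence[TranscriptRecord],
    hits: Iterable[tuple[str, str, float, float]],
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> tuple[list[TranscriptRecord], list[tuple[TranscriptRecord, str]]]:
    """External-hit hook: consume (candidate_id, cds_id, identity, coverage) rows
    from an outside alignment tool instead of the built-in screen."""
    best: dict[str, str] = {}
    for cand_id, cds_id, ident, cov in hits:
        if ident >= min_identity and cov >= min_coverage and cand_id not in best:
            best[cand_id] = cds_id
    retained = [c for c in candidates if c.transcript_id not in best]
    removed = [(c, best[c.transcript_id]) for c in candidates if c.transcript_id in best]
    return retained, removed


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------

def classify_context(entries: Sequence[CatalogEntry], annotation: AnnotationSet) -> None:
    """Mark each entry intergenic iff its interval overlaps no coding gene.

    Half-open overlap on either strand; entries without an interval keep
    ``context=None`` with a logged warning.
    """
    for entry in entries:
        if entry.record.interval is None:
            logger.warning(
                "transcript %s has no genomic interval; context unset",
                entry.record.transcript_id,
            )
            continue
        chrom, start, end, _ = entry.record.interval
        entry.context = (
            "genic" if annotation.overlaps_coding(chrom, start, end) else "intergenic"
        )


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

def run_discovery(
    transcripts: Sequence[TranscriptRecord],
    cds_set: Sequence[TranscriptRecord],
    annotation: AnnotationSet | None,
    model: CodingModel,
    table: HexamerTable,
    known_lnc_ids: Iterable[str] = (),
    min_bp: int = 200,
    max_aa: int = 100,
    kmer: int = 11,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    strand_mode: str = "both",
) -> tuple[LncRNACatalog, FilterReport]:
    """Apply the full funnel in its fixed order and report per-stage counts."""
    known = set(known_lnc_ids)
    report = FilterReport()

    after_len, _ = filter_min_length(transcripts, min_bp)
    report.add("min_length", len(transcripts), len(after_len))

    after_orf, _ = filter_max_orf(after_len, max_aa, strand_mode)
    report.add("max_orf", len(after_len), len(after_orf))

    scored: list[tuple[TranscriptRecord, FeatureVector, float]] = []
    for rec in after_orf:
        fv = extract_features(rec, table)
        prob = coding_probability(fv, model)
        if classify_transcript(prob, model.cutoff) == "noncoding":
            scored.append((rec, fv, prob))
    report.add("coding_potential", len(after_orf), len(scored))

    candidates = [rec for rec, _, _ in scored]
    retained_records, _ = cds_similarity_screen(
        candidates, cds_set, kmer, min_identity, min_coverage
    )
    retained_ids = {r.transcript_id for r in retained_records}
    report.add("cds_similarity", len(candidates), len(retained_records))

    entries = [
        CatalogEntry(
            record=rec,
            features=fv,
            probability=prob,
            novelty="annotated" if rec.transcript_id in known else "novel",
        )
        for rec, fv, prob in scored
        if rec.transcript_id in retained_ids
    ]
    if annotation is not None:
        classify_context(entries, annotation)
    return LncRNACatalog(entries), report


# ---------------------------------------------------------------------------
# structure statistics
# ---------------------------------------------------------------------------

def structure_stats(
    catalog: LncRNACatalog, bin_edges: Sequence[int] = (200, 500, 1000, 3000)
) -> StructureStats:
    """Mean length, length histogram and exon/intron means of the catalog.

    Histogram bins are half-open on the left, ``(edge_i, edge_{i+1}]``, with a
    final open-ended ``>last_edge`` bin; defaults follow the 200-500 /
    500-1000 / 1000-3000 / >3000 bp narrative bins.
    """
    if not catalog.entries:
        raise ValueError("empty catalog")
    lengths = [len(e.record) for e in catalog.entries]
    edges = list(bin_edges)
    counts = [0] * len(edges)
    labels = [
        f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)
    ] + [f">{edges[-1]}"]
    for L in lengths:
        # bins are (edges[i], edges[i+1]]; lengths <= edges[0] land in bin 0
        idx = bisect.bisect_left(edges, L) - 1
        counts[max(idx, 0)] += 1
    with_exons = [e for e in catalog.entries if e.record.exons is not None]
    mean_exons: float | None = None
    mean_intron: float | None = None
    if with_exons:
        mean_exons = float(np.mean([len(e.record.exons) for e in with_exons]))
        introns = [
            e.record.exons[i + 1][0] - e.record.exons[i][1]
            for e in with_exons
            for i in range(len(e.record.exons) - 1)
        ]
        if introns:
            mean_intron = float(np.mean(introns))
    return StructureStats(
        mean_length=float(np.mean(lengths)),
        length_histogram=tuple(zip(labels, counts)),
        mean_exon_count=mean_exons,
        mean_intron_length=mean_intron,
    )
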