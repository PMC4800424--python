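"""Synthetic corpora with ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes,
without any external download:

* a transcript pool mixing coding-like sequences (an embedded ATG..stop ORF
  longer than 100 aa covering most of the transcript, codons drawn from a
  biased usage model) and noncoding sequences (i.i.d. background bases,
  chance ORFs capped at 100 aa by rejection);
* stage x transcript FPKM matrices mixing sparse, peaked profiles
  (Dirichlet with concentration < 1, argmax pinned to a designed stage) and
  broad, near-uniform profiles (concentration >= 1), plus all-zero rows;
* a synthetic chromosome on which candidate transcripts are placed either
  inside annotated coding genes or strictly between them.

Every output is a pure function of :class:`SyntheticConfig` (the seed fixes
all draws), and the generated truth labels let tests measure recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AnnotationRecord,
    AnnotationSet,
    ExpressionMatrix,
    TranscriptRecord,
)
from .orf_finder import STOP_CODONS, max_orf_aa

import pandas as pd

_BASES = np.array(list("ACGT"))

#: the 61 sense codons of the standard nuclear code, lexicographic order
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    # sequence corpus
    n_coding: int = 1000
    n_noncoding: int = 1000
    coding_length_range: tuple[int, int] = (450, 3000)
    noncoding_length_range: tuple[int, int] = (250, 1500)
    hexamer_bias_strength: float = 0.5
    max_noncoding_orf_aa: int = 100
    # expression matrix (default 12 stages: embryonic 2 h windows)
    n_stages: int = 12
    n_specific_rows: int = 300
    n_broad_rows: int = 600
    dirichlet_alpha_specific: float = 0.05
    dirichlet_alpha_broad: float = 5.0
    fpkm_lognorm_mu: float = 2.0
    fpkm_lognorm_sigma: float = 1.0
    zero_row_fraction: float = 0.1
    stage_labels: tuple[str, ...] | None = None
    # annotation layout
    n_annotation_genes: int = 100
    n_candidate_intervals: int = 200
    intergenic_fraction: float = 0.5
    chromosome_name: str = "chrSim"
    chromosome_length: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_noncoding", "n_stages", "n_specific_rows",
                     "n_broad_rows", "n_annotation_genes", "n_candidate_intervals"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dirichlet_alpha_specific <= 0 or self.dirichlet_alpha_broad <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")
        if self.hexamer_bias_strength < 0:
            raise ValueError("hexamer_bias_strength must be >= 0")
        if not (0.0 <= self.zero_row_fraction < 1.0):
            raise ValueError("zero_row_fraction must lie in [0, 1)")
        if not (0.0 <= self.intergenic_fraction <= 1.0):
            raise ValueError("intergenic_fraction must lie in [0, 1]")
        for lo, hi in (self.coding_length_range, self.noncoding_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")
        if self.coding_length_range[0] < 3 * (102) + 3:
            raise ValueError(
                "coding_length_range too short to embed an ORF longer than 100 aa"
            )
        if self.stage_labels is not None and len(self.stage_labels) != self.n_stages:
            raise ValueError("stage_labels length must equal n_stages")

    def labels(self) -> list[str]:
        if self.stage_labels is not None:
            return list(self.stage_labels)
        return [f"stage_{i + 1:02d}" for i in range(self.n_stages)]


@dataclass
class SyntheticTruth:
    """Ground truth per generated item."""

    classes: dict[str, str] = field(default_factory=dict)  # id -> coding|noncoding
    designs: dict[str, str] = field(default_factory=dict)  # id -> stage_specific:<s>|broad|zero
    contexts: dict[str, str] = field(default_factory=dict)  # id -> intergenic|genic


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

#: direction of the codon-usage bias: a fixed property of the simulated
#: "species", shared by every corpus regardless of seed so that a model
#: trained on one corpus transfers to another.
_CODON_BIAS_DIRECTION = np.random.default_rng(61).standard_normal(len(SENSE_CODONS))


def _codon_weights(config: SyntheticConfig) -> np.ndarray:
    """Codon-usage weights over the sense codons, w ~ exp(strength * z).

    The direction z is a fixed constant; only the strength is configurable.
    At strength 0 the usage is uniform over the 61 sense codons, which is
    exactly the in-frame codon law of random sequence conditioned on
    containing no stop — so the coding/noncoding hexamer contrast vanishes.
    """
    w = np.exp(config.hexamer_bias_strength * _CODON_BIAS_DIRECTION)
    return w / w.sum()


def generate_sequences(
    config: SyntheticConfig,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Coding + noncoding transcript pool with class truth."""
    rng = _rng(config, 1)
    weights = _codon_weights(config)
    stops = sorted(STOP_CODONS)
    records: list[TranscriptRecord] = []
    truth = SyntheticTruth()

    lo, hi = config.coding_length_range
    for i in range(config.n_coding):
        length = int(rng.integers(lo, hi + 1))
        coverage = rng.uniform(0.65, 0.92)
        aa = max(
            config.max_noncoding_orf_aa + 1,
            int((coverage * length - 3) // 3),
        )
        aa = min(aa, (length - 3) // 3 - 1)
        orf_nt = 3 * aa + 3  # residues plus the stop codon
        utr5 = int(rng.integers(0, length - orf_nt + 1))
        utr3 = length - orf_nt - utr5
        codon_idx = rng.choice(len(SENSE_CODONS), size=aa - 1, p=weights)
        orf = (
            "ATG"
            + "".join(SENSE_CODONS[j] for j in codon_idx)
            + stops[int(rng.integers(0, 3))]
        )
        seq = _random_bases(rng, utr5) + orf + _random_bases(rng, utr3)
        rid = f"coding_{i + 1:05d}"
        records.append(TranscriptRecord(rid, seq))
        truth.classes[rid] = "coding"

    lo, hi = config.noncoding_length_range
    for i in range(config.n_noncoding):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_bases(rng, length)
        while max_orf_aa(seq, "both") > config.max_noncoding_orf_aa:
            seq = _random_bases(rng, length)
        rid = f"noncoding_{i + 1:05d}"
        records.append(TranscriptRecord(rid, seq))
        truth.classes[rid] = "noncoding"

    return records, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _n_zero_rows(config: SyntheticConfig) -> int:
    expressed = config.n_specific_rows + config.n_broad_rows
    if config.zero_row_fraction == 0:
        return 0
    return int(round(config.zero_row_fraction * expressed / (1 - config.zero_row_fraction)))


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Stage x transcript FPKM matrix with per-row design truth.

    Stage-specific rows draw a sparse Dirichlet profile and are relabeled so
    the argmax sits at the designed stage (assigned round-robin); broad rows
    draw a concentrated Dirichlet; both are scaled by log-normal totals.
    """
    if config.n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    rng = _rng(config, 2)
    S = config.n_stages
    labels = config.labels()
    truth = SyntheticTruth()
    rows = []
    ids = []
    counter = 0

    for i in range(config.n_specific_rows):
        stage = i % S
        p = rng.dirichlet(np.full(S, config.dirichlet_alpha_specific))
        peak = int(np.argmax(p))
        p[stage], p[peak] = p[peak], p[stage]
        total = rng.lognormal(config.fpkm_lognorm_mu, config.fpkm_lognorm_sigma)
        counter += 1
        rid = f"tx_{counter:05d}"
        ids.append(rid)
        rows.append(p * total)
        truth.designs[rid] = f"stage_specific:{labels[stage]}"

    for _ in range(config.n_broad_rows):
        p = rng.dirichlet(np.full(S, config.dirichlet_alpha_broad))
        total = rng.lognormal(config.fpkm_lognorm_mu, config.fpkm_lognorm_sigma)
        counter += 1
        rid = f"tx_{counter:05d}"
        ids.append(rid)
        rows.append(p * total)
        truth.designs[rid] = "broad"

    for _ in range(_n_zero_rows(config)):
        counter += 1
        rid = f"tx_{counter:05d}"
        ids.append(rid)
        rows.append(np.zeros(S))
        truth.designs[rid] = "zero"

    df = pd.DataFrame(np.array(rows), index=ids, columns=labels)
    df.index.name = "transcript_id"
    return ExpressionMatrix(df), truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SyntheticConfig,
) -> tuple[AnnotationSet, dict[str, tuple[str, int, int, str]], SyntheticTruth]:
    """Coding-gene intervals plus candidate-transcript intervals with truth.

    Genes are laid out on a regular grid (2 kb genes separated by 3 kb gaps);
    intergenic candidates are placed wholly inside gaps, genic candidates
    start inside a gene, so the construction fixes the truth exactly.
    """
    gene_len, gap = 2000, 3000
    pitch = gene_len + gap
    needed = 1000 + config.n_annotation_genes * pitch
    if needed > config.chromosome_length:
        raise ValueError(
            f"chromosome too short: need {needed} bp for {config.n_annotation_genes} genes"
        )
    if config.n_annotation_genes < 1:
        raise ValueError("need at least one annotated gene")
    rng = _rng(config, 3)
    chrom = config.chromosome_name
    genes = []
    for i in range(config.n_annotation_genes):
        start = 1000 + i * pitch
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append(AnnotationRecord(chrom, start, start + gene_len, strand, "coding_gene"))

    truth = SyntheticTruth()
    intervals: dict[str, tuple[str, int, int, str]] = {}
    n_intergenic = int(round(config.intergenic_fraction * config.n_candidate_intervals))
    for i in range(config.n_candidate_intervals):
        cand_len = int(rng.integers(200, 801))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        rid = f"cand_{i + 1:05d}"
        if i < n_intergenic:
            g = int(rng.integers(0, config.n_annotation_genes))
            gap_start = genes[g].end + 50
            gap_end = genes[g].start + pitch - 50 if g < config.n_annotation_genes - 1 \
                else genes[g].end + gap - 50
            start = int(rng.integers(gap_start, gap_end - cand_len))
            truth.contexts[rid] = "intergenic"
        else:
            g = int(rng.integers(0, config.n_annotation_genes))
            start = int(rng.integers(genes[g].start, genes[g].end - 10))
            truth.contexts[rid] = "genic"
        intervals[rid] = (chrom, start, start + cand_len, strand)

    return AnnotationSet(tuple(genes)), intervals, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: stage-panel presets mirroring the embryonic/larval/pupal layouts
STAGE_PRESETS = {"embryonic": 12, "larval": 6, "pupal": 6}


def preset_config(name: str = "default", seed: int = 0, **overrides) -> SyntheticConfig:
    """Named configurations: 'default'/'embryonic' (12 stages), 'larval', 'pupal',
    and 'small' (a fast corpus for smoke tests)."""
    if name in ("default", "embryonic"):
        params: dict = {}
    elif name in STAGE_PRESETS:
        params = {"n_stages": STAGE_PRESETS[name]}
    elif name == "small":
        params = {
            "n_coding": 60,
            "n_noncoding": 60,
            "n_specific_rows": 60,
            "n_broad_rows": 120,
            "n_candidate_intervals": 60,
        }
    else:
        raise ValueError(f"unknown preset {name!r}")
    params.update(overrides)
    return dataclasses.replace(SyntheticConfig(seed=seed), **params)
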