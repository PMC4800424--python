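"""CPAT-style coding-potential scoring.

Four alignment-free sequence features — maximal-ORF size, ORF coverage,
Fickett TESTCODE statistic and in-frame hexamer usage bias — feed a logistic
regression whose probability is thresholded at the classification cutoff
(default 0.39; a probability strictly below the cutoff labels the transcript
noncoding).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .io_formats import TranscriptRecord
from .orf_finder import OrfHit, find_orfs, revcomp

# ---------------------------------------------------------------------------
# Fickett TESTCODE lookup tables
# ---------------------------------------------------------------------------
# Published TESTCODE constants (position/content probability tables, parameter
# breakpoints and weights) as distributed with the CPAT implementation.
# A parameter value is resolved to the probability of the first breakpoint it
# meets or exceeds, scanning the breakpoints in decreasing order.

FICKETT_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
FICKETT_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

FICKETT_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
FICKETT_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.15, 0.0)

BASES = "ACGT"
FEATURE_NAMES = ("orf_size", "orf_coverage", "fickett", "hexamer")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: All 4096 hexamers in lexicographic (A<C<G<T) order.
HEXAMERS = tuple(
    a + b + c + d + e + f
    for a in BASES for b in BASES for c in BASES
    for d in BASES for e in BASES for f in BASES
)


def hexamer_index(hexamer: str) -> int:
    idx = 0
    for ch in hexamer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def _lookup(value: float, para: Sequence[float], probs: Sequence[float]) -> float:
    for threshold, p in zip(para, probs):
        if value >= threshold:
            return p
    return probs[-1]


def fickett_parameters(sequence: str) -> dict[str, float]:
    """The eight TESTCODE parameters: per-base position asymmetry and content.

    Positions holding N are skipped from all counts. The position parameter
    of base *b* is max over the three codon positions of its count, divided
    by (min over positions + 1); the content parameter is its composition
    fraction.
    """
    seq = sequence.upper()
    pos_counts = {b: [0, 0, 0] for b in BASES}
    total = 0
    for i, ch in enumerate(seq):
        if ch in _BASE_INDEX:
            pos_counts[ch][i % 3] += 1
            total += 1
    if total == 0:
        raise ValueError("sequence has no countable (non-N) positions")
    params: dict[str, float] = {}
    for b in BASES:
        counts = pos_counts[b]
        params[f"{b}_position"] = max(counts) / (min(counts) + 1)
        params[f"{b}_content"] = sum(counts) / total
    return params


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of *sequence* (whole-sequence, frame 0)."""
    if len(sequence) < 2:
        raise ValueError("sequence too short for a Fickett score")
    params = fickett_parameters(sequence)
    score = 0.0
    for b in BASES:
        score += FICKETT_POSITION_WEIGHT[b] * _lookup(
            params[f"{b}_position"], FICKETT_POSITION_PARA, FICKETT_POSITION_PROB[b]
        )
        score += FICKETT_CONTENT_WEIGHT[b] * _lookup(
            params[f"{b}_content"], FICKETT_CONTENT_PARA, FICKETT_CONTENT_PROB[b]
        )
    return score


# ---------------------------------------------------------------------------
# hexamer usage bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HexamerTable:
    """In-frame relative hexamer frequencies for the coding/noncoding classes."""

    f_coding: np.ndarray  # shape (4096,)
    f_noncoding: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        for name in ("f_coding", "f_noncoding"):
            f = getattr(self, name)
            if f.shape != (4096,):
                raise ValueError(f"{name} must have 4096 entries")
            if not (f > 0).all():
                raise ValueError(f"{name} must be strictly positive after pseudocounting")
            if abs(float(f.sum()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    def checksum(self) -> str:
        payload = "\n".join(
            f"{h}\t{fc:.12e}\t{fn:.12e}"
            for h, fc, fn in zip(HEXAMERS, self.f_coding, self.f_noncoding)
        )
        return hashlib.md5(payload.encode()).hexdigest()


def _orf_subsequence(record: TranscriptRecord) -> str | None:
    """Residue codons of the maximal ORF on its own strand (stop excluded).

    The stop codon is left out so that in-frame hexamers are always sense
    codon pairs: with it, every short ORF would carry one stop-containing
    window whose extreme log-ratio dominates the mean for no biological
    reason.
    """
    hits = find_orfs(record, min_aa=1, strand_mode="both")
    if not hits:
        return None
    h: OrfHit = hits[0]
    seq = record.sequence if h.strand == "+" else revcomp(record.sequence)
    return seq[h.nt_start : h.nt_start + 3 * h.aa_length]


def _count_hexamers(subseq: str, counts: np.ndarray) -> None:
    for i in range(0, len(subseq) - 5, 3):
        h = subseq[i : i + 6]
        if "N" not in h:
            counts[hexamer_index(h)] += 1


def train_hexamer_table(
    coding: Sequence[TranscriptRecord],
    noncoding: Sequence[TranscriptRecord],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Tally in-frame hexamers per class and convert to pseudocounted frequencies.

    Coding sequences are counted in the reading frame of their maximal ORF
    (falling back to frame 0 of the whole transcript if no ORF exists);
    noncoding sequences are counted in frame 0. Windows step by 3.
    """
    if not coding or not noncoding:
        raise ValueError("both coding and noncoding training sets must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c_counts = np.zeros(4096)
    n_counts = np.zeros(4096)
    for rec in coding:
        sub = _orf_subsequence(rec) or rec.sequence
        _count_hexamers(sub, c_counts)
    for rec in noncoding:
        _count_hexamers(rec.sequence, n_counts)
    f_c = (c_counts + pseudocount) / (c_counts + pseudocount).sum()
    f_n = (n_counts + pseudocount) / (n_counts + pseudocount).sum()
    return HexamerTable(f_c, f_n, pseudocount)


def hexamer_bias(sequence: str, frame_start: int, table: HexamerTable) -> float:
    """Mean natural-log likelihood ratio of in-frame hexamers (step 3).

    Hexamers containing N are skipped and excluded from the mean; an input
    yielding zero countable hexamers is an error.
    """
    total = 0.0
    m = 0
    for i in range(frame_start, len(sequence) - 5, 3):
        h = sequence[i : i + 6]
        if "N" in h:
            continue
        idx = hexamer_index(h)
        total += math.log(table.f_coding[idx] / table.f_noncoding[idx])
        m += 1
    if m == 0:
        raise ValueError("no countable in-frame hexamers")
    return total / m


# ---------------------------------------------------------------------------
# features and the logistic model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    orf_size: int  # nucleotides of the maximal ORF (stop codon included)
    orf_coverage: float
    fickett: float
    hexamer: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orf_coverage <= 1.0 + 1e-12):
            raise ValueError(f"orf_coverage {self.orf_coverage} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.orf_size, self.orf_coverage, self.fickett, self.hexamer], dtype=float
        )


def extract_features(record: TranscriptRecord, table: HexamerTable) -> FeatureVector:
    """The four coding-potential features of one transcript.

    The Fickett statistic is computed over the whole transcript; the hexamer
    bias over the maximal ORF when one exists (falling back to frame 0 of the
    whole transcript when the ORF is shorter than one hexamer).
    """
    hits = find_orfs(record, min_aa=1, strand_mode="both")
    if hits:
        h = hits[0]
        orf_size = h.nt_length
        sub = _orf_subsequence(record)
    else:
        orf_size = 0
        sub = None
    coverage = orf_size / len(record) if orf_size else 0.0
    fick = fickett_score(record.sequence)
    if sub is not None and len(sub) >= 6:
        try:
            hexamer = hexamer_bias(sub, 0, table)
        except ValueError:
            hexamer = hexamer_bias(record.sequence, 0, table)
    else:
        hexamer = hexamer_bias(record.sequence, 0, table)
    return FeatureVector(orf_size, min(coverage, 1.0), fick, hexamer)


@dataclass(frozen=True)
class CodingModel:
    intercept: float
    coefficients: np.ndarray  # one per FEATURE_NAMES entry
    cutoff: float = 0.39
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if np.asarray(self.coefficients).shape != (len(self.feature_names),):
            raise ValueError("coefficient count must match feature count")


def fit_coding_model(
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    cutoff: float = 0.39,
    ridge: float = 1e-6,
) -> CodingModel:
    """Maximum-likelihood logistic fit (L2-ridged, deterministic).

    *labels* are ``"coding"`` / ``"noncoding"``; the positive class is
    coding. Features are standardized internally and the fit mapped back to
    the raw feature scale, so the returned coefficients apply to raw
    feature values. The small default ridge keeps separable data finite.
    """
    X = np.array([f.as_array() for f in features], dtype=float)
    y = np.array([1 if l == "coding" else 0 for l in labels])
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    design = np.column_stack([np.ones(len(X)), X])
    if ridge == 0 and np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "design matrix is perfectly collinear; refit with a positive ridge"
        )
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Z = (X - mu) / sigma
    C = 1.0 / ridge if ridge > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(Z, y)
    coef_std = clf.coef_[0]
    coef = coef_std / sigma
    intercept = float(clf.intercept_[0] - np.sum(coef_std * mu / sigma))
    return CodingModel(intercept, coef, cutoff)


def coding_probability(fv: FeatureVector | np.ndarray, model: CodingModel) -> float:
    """Logistic coding probability ``1 / (1 + exp(-(b0 + sum(b_i x_i))))``."""
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    z = model.intercept + float(np.dot(model.coefficients, x))
    return float(expit(z))


def classify_transcript(prob: float, cutoff: float = 0.39) -> str:
    """``noncoding`` iff the coding probability is strictly below the cutoff."""
    if not (0.0 <= prob <= 1.0):
        raise ValueError(f"probability {prob} outside [0, 1]")
    return "noncoding" if prob < cutoff else "coding"


def train_model_from_corpus(
    coding: Sequence[TranscriptRecord],
    noncoding: Sequence[TranscriptRecord],
    cutoff: float = 0.39,
    pseudocount: float = 1.0,
    ridge: float = 1e-6,
) -> tuple[CodingModel, HexamerTable]:
    """Train the hexamer table and logistic model from labelled transcripts."""
    table = train_hexamer_table(coding, noncoding, pseudocount)
    feats = [extract_features(r, table) for r in coding] + [
        extract_features(r, table) for r in noncoding
    ]
    labels = ["coding"] * len(coding) + ["noncoding"] * len(noncoding)
    model = fit_coding_model(feats, labels, cutoff=cutoff, ridge=ridge)
    return model, table


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_hexamer_table(table: HexamerTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pseudocount\t{table.pseudocount:.12g}\n")
        fh.write("hexamer\tf_coding\tf_noncoding\n")
        for h, fc, fn in zip(HEXAMERS, table.f_coding, table.f_noncoding):
            fh.write(f"{h}\t{fc:.12e}\t{fn:.12e}\n")


def read_hexamer_table(path: str | Path) -> HexamerTable:
    f_c = np.zeros(4096)
    f_n = np.zeros(4096)
    pseudocount = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
                continue
            if line.startswith("hexamer"):
                continue
            h, fc, fn = line.split("\t")
            idx = hexamer_index(h)
            f_c[idx] = float(fc)
            f_n[idx] = float(fn)
    # re-normalize away round-off from the text representation
    return HexamerTable(f_c / f_c.sum(), f_n / f_n.sum(), pseudocount)


def write_model(model: CodingModel, table: HexamerTable, path: str | Path) -> None:
    """Flat key-value model file; the hexamer table is referenced by checksum."""
    with open(path, "w") as fh:
        fh.write(f"intercept\t{model.intercept:.12e}\n")
        for name, c in zip(model.feature_names, model.coefficients):
            fh.write(f"coef_{name}\t{c:.12e}\n")
        fh.write(f"cutoff\t{model.cutoff:.12g}\n")
        fh.write(f"hexamer_table_md5\t{table.checksum()}\n")


def read_model(path: str | Path, table: HexamerTable) -> CodingModel:
    kv: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            kv[key] = value
    expected = kv.get("hexamer_table_md5")
    if expected is not None and expected != table.checksum():
        raise ValueError("hexamer table checksum does not match the model file")
    coef = np.array([float(kv[f"coef_{n}"]) for n in FEATURE_NAMES])
    return CodingModel(float(kv["intercept"]), coef, float(kv["cutoff"]))


def score_transcripts(
    records: Iterable[TranscriptRecord], model: CodingModel, table: HexamerTable
) -> list[dict]:
    """Feature report rows: one dict per transcript, TSV-ready."""
    rows = []
    for rec in records:
        fv = extract_features(rec, table)
        prob = coding_probability(fv, model)
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "orf_size": fv.orf_size,
                "orf_coverage": fv.orf_coverage,
                "fickett": fv.fickett,
                "hexamer": fv.hexamer,
                "probability": prob,
                "label": classify_transcript(prob, model.cutoff),
            }
        )
    return rows
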