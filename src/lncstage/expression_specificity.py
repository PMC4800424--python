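"""Developmental expression-specificity analysis.

FPKM rows are normalized to relative expression profiles (probability
vectors); a transcript's developmental specificity is the maximal JS
specificity score

    js_max = max_t [ 1 - sqrt( JSD(p, e_t) ) ]

where ``e_t`` is the idealized profile expressed at exactly one stage and
JSD is the Jensen-Shannon divergence with base-2 logarithms, so scores lie
in [0, 1] and a perfectly stage-restricted profile scores exactly 1.
Transcripts are additionally binned into three rank-based expression tiers
(high / moderate / low mean FPKM), and the fraction with extreme specificity
(js_max in [0.9, 1.0]) is compared across groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .io_formats import ExpressionMatrix

_TOL = 1e-9


@dataclass(frozen=True)
class RelativeProfile:
    transcript_id: str
    p: np.ndarray  # nonnegative, sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > _TOL:
            raise ValueError(
                f"profile for {self.transcript_id!r} is not a probability vector"
            )


@dataclass(frozen=True)
class SpecificityResult:
    transcript_id: str
    js_max: float
    peak_stage: str

    def __post_init__(self) -> None:
        if not (-_TOL <= self.js_max <= 1.0 + _TOL):
            raise ValueError(f"js_max {self.js_max} outside [0, 1]")


@dataclass(frozen=True)
class ExpressionTier:
    transcript_id: str
    mean_fpkm: float
    tier: str  # "low" | "moderate" | "high"


def normalize_profile(
    matrix: ExpressionMatrix,
) -> tuple[list[RelativeProfile], list[str]]:
    """Row-sum normalize FPKM rows; all-zero rows are excluded, not profiled."""
    profiles: list[RelativeProfile] = []
    excluded: list[str] = []
    values = matrix.values
    totals = values.sum(axis=1)
    for rid, row, total in zip(matrix.row_ids, values, totals):
        if total > 0:
            profiles.append(RelativeProfile(rid, row / total))
        else:
            excluded.append(rid)
    return profiles, excluded


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy in bits; 0*log(0) := 0. Input must be normalized."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probability vector sums to {p.sum()}, not 1")
    return float(_scipy_entropy(p, base=2))


def js_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon divergence, base 2: H((p+q)/2) - (H(p)+H(q))/2 in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    hp = shannon_entropy(p)
    hq = shannon_entropy(q)
    m = (p + q) / 2.0
    return float(_scipy_entropy(m, base=2) - (hp + hq) / 2.0)


def js_specificity(
    profile: RelativeProfile, stage_labels: Sequence[str]
) -> SpecificityResult:
    """Maximal JS specificity score and the stage achieving it.

    Ties (e.g. a uniform profile) resolve to the earliest stage in
    developmental order, compared with a small tolerance so equal scores do
    not split on floating-point summation order.
    """
    p = np.asarray(profile.p, dtype=float)
    n = len(p)
    if n < 2:
        raise ValueError("at least 2 stages required")
    if len(stage_labels) != n:
        raise ValueError("stage_labels length must match profile length")
    scores = np.empty(n)
    for t in range(n):
        e_t = np.zeros(n)
        e_t[t] = 1.0
        scores[t] = 1.0 - np.sqrt(max(js_divergence(p, e_t), 0.0))
    best = float(scores.max())
    peak = int(np.argmax(scores >= best - 1e-12))
    return SpecificityResult(profile.transcript_id, best, stage_labels[peak])


def specificity_table(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-transcript js_max and peak stage for all rows with positive total.

    Returns a DataFrame indexed by transcript_id with columns
    ``mean_fpkm``, ``js_max``, ``peak_stage``, plus the excluded
    (all-zero) IDs.
    """
    profiles, excluded = normalize_profile(matrix)
    labels = matrix.stage_labels
    means = matrix.df.mean(axis=1)
    rows = []
    for prof in profiles:
        res = js_specificity(prof, labels)
        rows.append(
            {
                "transcript_id": res.transcript_id,
                "mean_fpkm": float(means.loc[res.transcript_id]),
                "js_max": res.js_max,
                "peak_stage": res.peak_stage,
            }
        )
    df = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
        columns=["mean_fpkm", "js_max", "peak_stage"]
    )
    return df, excluded


def assign_tiers(
    matrix: ExpressionMatrix, stage_subset: Sequence[str] | None = None
) -> list[ExpressionTier]:
    """Rank-based tertiles of mean FPKM: high / moderate / low.

    Rows are sorted by (mean descending, transcript_id ascending) and split
    into three contiguous near-equal groups; remainders go to the higher
    tiers (n=10 -> 4/3/3).
    """
    stages = list(stage_subset) if stage_subset is not None else matrix.stage_labels
    if not stages:
        raise ValueError("stage_subset must be non-empty")
    missing = set(stages) - set(matrix.stage_labels)
    if missing:
        raise ValueError(f"unknown stages: {sorted(missing)}")
    means = matrix.df[stages].mean(axis=1)
    if len(means) < 3:
        raise ValueError("at least 3 rows required to form tiers")
    order = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]  # high gets remainder first
    tiers: list[ExpressionTier] = []
    labels = ["high"] * sizes[0] + ["moderate"] * sizes[1] + ["low"] * sizes[2]
    for (rid, mean), tier in zip(order, labels):
        tiers.append(ExpressionTier(rid, float(mean), tier))
    return tiers


def extreme_specificity_proportion(
    results: Sequence[SpecificityResult] | Sequence[float],
    lo: float = 0.9,
    hi: float = 1.0,
) -> float:
    """Fraction of scores inside the closed interval [lo, hi]."""
    if len(results) == 0:
        raise ValueError("no specificity results")
    scores = [
        r.js_max if isinstance(r, SpecificityResult) else float(r) for r in results
    ]
    return sum(lo <= s <= hi for s in scores) / len(scores)


def exclude_ids(matrix: ExpressionMatrix, id_list: Iterable[str]) -> ExpressionMatrix:
    """Drop rows whose ID is listed (e.g. housekeeping transcripts)."""
    drop = set(id_list)
    keep = [rid for rid in matrix.row_ids if rid not in drop]
    return ExpressionMatrix(matrix.df.loc[keep])


def js_histogram(
    scores: Sequence[float], width: float = 0.1, step: float = 0.05
) -> pd.DataFrame:
    """Sliding-window density of JS scores over [0, 1] (window width 0.1).

    Windows are closed intervals [start, start+width] advancing by *step*;
    the returned fractions therefore overlap and need not sum to 1.
    """
    if not scores:
        raise ValueError("no scores")
    starts = np.arange(0.0, 1.0 - width + step / 2, step)
    rows = []
    arr = np.asarray(scores, dtype=float)
    for s in starts:
        frac = float(((arr >= s) & (arr <= s + width)).mean())
        rows.append({"window_start": round(float(s), 6),
                     "window_end": round(float(s + width), 6),
                     "fraction": frac})
    return pd.DataFrame(rows)
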