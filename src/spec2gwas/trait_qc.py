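"""Trait screening: summary statistics, CV flagging, and the normality gate.

A biochemical trait enters index extraction and association testing only if
its distribution passes a normality check; a high coefficient of variation
(CV = SD/mean, flagged at >= 0.15 after display rounding) marks a dispersed
data set but is advisory, not a hard gate.  A trait whose best two-band
index explains less than R^2 = 0.6 of its variance stays at the
correlation-analysis stage and is not scanned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TraitSummary", "summarize_trait", "normality_gate", "eligibility"]

CV_FLAG_THRESHOLD = 0.15
R2_GWAS_MIN = 0.6


@dataclass
class TraitSummary:
    """One summary row for a trait: n, range, moments, CV and its flag."""

    name: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv: float
    cv_display: float
    cv_flag: bool
    normality_p: float | None = None
    verdict: str | None = None  # "accepted" | "rejected-nonnormal"


def summarize_trait(values, name: str = "trait") -> TraitSummary:
    """Compute min/max/mean/SD/CV for one trait vector.

    SD uses the n-1 denominator.  The CV flag applies to the value rounded
    to two decimals (a raw CV of 0.1486 displays as 0.15 and is flagged);
    the full-precision CV is kept alongside.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 values to summarize a trait")
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero-mean trait")
    sd = float(x.std(ddof=1))
    cv = sd / mean
    cv_display = round(cv, 2)
    return TraitSummary(
        name=name,
        n=int(x.size),
        min=float(x.min()),
        max=float(x.max()),
        mean=mean,
        sd=sd,
        cv=cv,
        cv_display=cv_display,
        cv_flag=cv_display >= CV_FLAG_THRESHOLD,
    )


def normality_gate(values, alpha: float = 0.05) -> tuple[float, str]:
    """Shapiro-Wilk normality gate; rejects iff p < alpha.

    Degenerate (constant) vectors are rejected outright.  Returns
    ``(p_value, verdict)`` with verdict ``"accepted"`` or
    ``"rejected-nonnormal"``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 for the normality gate")
    if np.ptp(x) == 0:
        return 0.0, "rejected-nonnormal"
    p = float(stats.shapiro(x).pvalue)
    return p, ("accepted" if p >= alpha else "rejected-nonnormal")


def eligibility(summary: TraitSummary, index_r2: float | None = None) -> str:
    """Classify a trait for the downstream pipeline.

    ``excluded`` if the normality gate rejected it; ``correlation-only`` if
    its best index R^2 falls below 0.6; ``gwas-eligible`` otherwise.  The
    decision depends only on the verdict and R^2, never on trait identity.
    """
    if summary.verdict == "rejected-nonnormal":
        return "excluded"
    if index_r2 is not None and index_r2 < R2_GWAS_MIN:
        return "correlation-only"
    return "gwas-eligible"
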