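"""Cohort-level statistics: coefficient of variation, Pearson correlation
with Cohen strength banding, and distribution summaries.

The correlation of interest is between daily organ-volume change (percent
vs the planning CT) and the corresponding mean-dose deviation, pooled over
all fractions of all supplied course reports.  No clustering correction is
applied for fractions nested in patients; the pooled n is recorded so the
caveat is visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "Strength",
    "CorrelationResult",
    "DistributionSummary",
    "coefficient_of_variation",
    "pearson",
    "volume_dose_correlation",
    "summarize",
]


class Strength(str, Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


def cohen_strength(r: float) -> Strength:
    """Cohen's conventional bands on |r|: <0.3 weak, 0.3-0.5 moderate,
    >0.5 strong.  The printed inequalities are strict on both outer bands,
    so the boundary values 0.3 and 0.5 are classed moderate."""
    a = abs(r)
    if a < 0.3:
        return Strength.WEAK
    if a > 0.5:
        return Strength.STRONG
    return Strength.MODERATE


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    strength: Strength
    sign: str  # "positive" | "negative" | "zero"
    p_value: float | None = None


@dataclass(frozen=True)
class DistributionSummary:
    """Mean/SD and median/IQR always both computed; ``style`` records which
    presentation a skewness rule (|skew| > 1 -> median/IQR) selects."""

    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    n: int
    style: str = "mean_sd"


def coefficient_of_variation(values) -> float:
    """CV = sigma / mu x 100 % with the sample (n-1) standard deviation.

    Requires at least two observations and a positive mean (volumes are
    positive by construction).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"CV needs n >= 2, got {v.size}")
    mu = v.mean()
    if mu <= 0:
        raise DegenerateInputError(f"CV undefined for mean {mu:g} <= 0")
    return float(v.std(ddof=1) / mu * 100.0)


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with Cohen strength banding."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    sign = "zero" if r == 0 else ("positive" if r > 0 else "negative")
    return CorrelationResult(r=r, n=int(x.size), strength=cohen_strength(r),
                             sign=sign, p_value=float(res.pvalue))


def volume_dose_correlation(reports, organ: str) -> CorrelationResult:
    """Pooled Pearson r between per-fraction volume deviation (%) and
    mean-dose deviation (%) for one organ across one or more course reports.

    ``reports`` is a CourseReport or an iterable of them; fractions from all
    reports are pooled (no per-patient clustering adjustment).
    """
    from .accumulation import CourseReport  # local import to avoid a cycle

    if isinstance(reports, CourseReport):
        reports = [reports]
    vols, doses = [], []
    for rep in reports:
        v, d = rep.volume_dose_pairs(organ)
        vols.extend(v)
        doses.extend(d)
    if len(vols) < 3:
        raise InsufficientDataError(
            f"pooled correlation needs >= 3 fractions, got {len(vols)}")
    return pearson(vols, doses)


def summarize(values, style: str = "auto") -> DistributionSummary:
    """Mean±SD and median (IQR) for a series; ``style='auto'`` flags
    median/IQR presentation when the sample skewness exceeds 1 in
    magnitude, mirroring the convention of reporting skewed dosimetric
    variables by median and IQR."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("empty series")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if style == "auto":
        skew = sps.skew(v) if v.size > 2 and sd > 0 else 0.0
        style = "median_iqr" if abs(skew) > 1 else "mean_sd"
    elif style not in ("mean_sd", "median_iqr"):
        raise ValueError(f"unknown style {style!r}")
    return DistributionSummary(mean=float(v.mean()), sd=sd, median=float(med),
                               q25=float(q25), q75=float(q75), n=int(v.size),
                               style=style)
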