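"""Method-comparison statistics: correlation, regression, Bland–Altman,
positivity concordance, and rank-based two-group comparison.

These are the agreement analyses used to validate a chimerism assay
against a comparator (true mixture fractions, or another method's
estimates on the same samples).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    slope: float
    intercept: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclasses.dataclass(frozen=True)
class ConcordanceTable:
    """2×2 cross-tabulation of two methods' positive/negative calls."""

    both_positive: int
    a_only: int  # A positive, B negative
    b_only: int  # A negative, B positive
    both_negative: int
    discordant_ids: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.both_positive + self.a_only + self.b_only + self.both_negative

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.both_positive, self.a_only], [self.b_only, self.both_negative]]
        )


def _paired(x: Sequence[float], y: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; undefined when either input is constant."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares line; returns (slope, intercept)."""
    x, y = _paired(x, y, 2)
    if np.ptp(x) == 0:
        raise ValidationError("linear fit undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Bland–Altman agreement: (bias, loa_low, loa_high).

    bias = mean(a − b); limits of agreement = bias ± 2·SD of the
    differences (sample SD, n−1 denominator).
    """
    a, b = _paired(a, b, 2)
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 2.0 * sd, bias + 2.0 * sd


def agreement(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Full comparison of method a against comparator b."""
    r = pearson_r(b, a)
    slope, intercept = linear_fit(b, a)
    bias, lo, hi = bland_altman(a, b)
    return AgreementResult(r, slope, intercept, bias, lo, hi, len(a))


def positivity_concordance(
    calls_a: Sequence[str],
    calls_b: Sequence[str],
    sample_ids: Optional[Sequence[str]] = None,
) -> ConcordanceTable:
    """Cross-tabulate paired positive/negative calls; list discordant samples."""
    if len(calls_a) != len(calls_b):
        raise ValidationError("unpaired call vectors")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(calls_a))]
    elif len(sample_ids) != len(calls_a):
        raise ValidationError("sample_ids length mismatch")
    counts = {"pp": 0, "pn": 0, "np": 0, "nn": 0}
    discordant: list[str] = []
    for sid, ca, cb in zip(sample_ids, calls_a, calls_b):
        if ca not in ("positive", "negative") or cb not in ("positive", "negative"):
            raise ValidationError(f"calls must be positive/negative, got {ca!r}, {cb!r}")
        key = ("p" if ca == "positive" else "n") + ("p" if cb == "positive" else "n")
        counts[key] += 1
        if ca != cb:
            discordant.append(sid)
    return ConcordanceTable(
        counts["pp"], counts["pn"], counts["np"], counts["nn"], tuple(discordant)
    )


def compare_group_counts(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Mann–Whitney U (tie-corrected normal approximation) for two groups.

    Returns (U for the first group, two-sided p).  This is the two-group
    rank comparison used for informative-marker counts of related vs
    unrelated donor/recipient pairs.
    """
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValidationError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        counts_a, counts_b, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
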