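"""Post-transplant chimerism quantification by relative qPCR (ΔΔCq).

For a recipient-specific marker, the marker Cq is compared with the
reference-assay Cq within each sample (ΔCq, controlling for DNA input);
the change from the pre-transplant recipient sample to the
post-transplant sample (ΔΔCq) converts to percent recipient chimerism as

    % recipient = 100 · (1+e)^(−ΔΔCq)

with e the amplification efficiency increment (e = 1, perfect doubling,
gives the classic 2^−ΔΔCq form).  The pre-transplant 100%-recipient
sample is the calibrator; no external standard curve is used.

A post-transplant sample whose marker never amplifies is reported as
NOT_DETECTED — a status, never 0% — so absence of signal stays
distinguishable from a measured zero.
"""

from __future__ import annotations

import dataclasses
import math
from statistics import fmean, stdev
from typing import Optional, Sequence

from .errors import ConfigurationError, QCError, ValidationError
from .panel import MarkerAssay, WellMeasurement
from .typing_engine import mean_amplified_cq

# flags
CLIPPED_ABOVE_100 = "clipped_above_100"
ATYPICAL_EXCLUDED = "atypical_excluded"
PARTIAL_REPLICATE_DROPOUT = "partial_replicate_dropout"

# statuses
QUANTIFIED = "quantified"
NOT_DETECTED = "not_detected"
ATYPICAL = "atypical"


@dataclasses.dataclass(frozen=True)
class ChimerismEstimate:
    """Per-marker chimerism estimate with QC flags."""

    marker: str
    dcq_pre: float
    dcq_post: Optional[float]
    ddcq: Optional[float]
    percent_recipient: Optional[float]
    status: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.percent_recipient is None) != (self.ddcq is None):
            raise ValidationError("percent_recipient present iff ddcq present")
        if self.percent_recipient is not None and not (
            0.0 <= self.percent_recipient <= 100.0
        ):
            raise ValidationError(
                f"percent_recipient outside [0,100]: {self.percent_recipient}"
            )


@dataclasses.dataclass(frozen=True)
class SampleChimerismReport:
    """Multi-marker summary: mean percent, CV across markers, detection."""

    estimates: tuple[ChimerismEstimate, ...]
    mean_percent: Optional[float]
    cv_percent: Optional[float]
    detected: bool


def delta_cq(marker_cq: float, reference_cq: Optional[float]) -> float:
    """ΔCq = marker Cq − reference Cq within one sample."""
    if reference_cq is None:
        raise QCError("reference assay absent; cannot form delta Cq")
    return marker_cq - reference_cq


def delta_delta_cq(dcq_post: float, dcq_pre: float) -> float:
    """ΔΔCq = post-transplant ΔCq − pre-transplant ΔCq."""
    return dcq_post - dcq_pre


def percent_chimerism(
    ddcq: float, efficiency_increment: float = 1.0
) -> tuple[float, frozenset[str]]:
    """Convert ΔΔCq to percent recipient chimerism.

    raw = 100 · (1+e)^(−ΔΔCq); values above 100 (negative ΔΔCq, i.e. more
    marker signal post than in the calibrator) are clipped to 100 and
    flagged.
    """
    if not 0.0 < efficiency_increment <= 1.0:
        raise ValidationError(
            f"efficiency_increment must be in (0,1], got {efficiency_increment}"
        )
    raw = 100.0 * (1.0 + efficiency_increment) ** (-ddcq)
    if raw > 100.0:
        return 100.0, frozenset({CLIPPED_ABOVE_100})
    return raw, frozenset()


def quantify_marker(
    pre_marker_wells: Sequence[WellMeasurement],
    pre_reference_wells: Sequence[WellMeasurement],
    post_marker_wells: Sequence[WellMeasurement],
    post_reference_wells: Sequence[WellMeasurement],
    assay: MarkerAssay,
    efficiency_increment: float = 1.0,
) -> ChimerismEstimate:
    """Quantify one recipient-specific marker for one post sample.

    Replicates are aggregated by mean Cq over amplified wells (partial
    dropout is flagged); the assay's Cq window is applied to the post
    marker mean (outside → atypical, excluded from quantification); the
    pre-transplant calibrator must amplify cleanly inside the window,
    otherwise the marker was never usable and a configuration error is
    raised.
    """
    pre_ref = mean_amplified_cq(pre_reference_wells)
    post_ref = mean_amplified_cq(post_reference_wells)
    if pre_ref is None or post_ref is None:
        raise QCError("reference assay did not amplify; sample invalid")

    pre_marker = mean_amplified_cq(pre_marker_wells)
    if pre_marker is None:
        raise ConfigurationError(
            f"marker {assay.id} absent in the pre-transplant sample; not informative"
        )
    if not assay.cq_in_window(pre_marker):
        raise ConfigurationError(
            f"marker {assay.id} atypical in the pre-transplant sample"
        )
    dcq_pre = delta_cq(pre_marker, pre_ref)

    flags: set[str] = set()
    post_amplified = [w for w in post_marker_wells if w.amplified]
    if post_amplified and len(post_amplified) < len(post_marker_wells):
        flags.add(PARTIAL_REPLICATE_DROPOUT)

    post_marker = mean_amplified_cq(post_marker_wells)
    if post_marker is None:
        return ChimerismEstimate(
            assay.id, dcq_pre, None, None, None, NOT_DETECTED, frozenset(flags)
        )
    if not assay.cq_in_window(post_marker):
        flags.add(ATYPICAL_EXCLUDED)
        return ChimerismEstimate(
            assay.id,
            dcq_pre,
            delta_cq(post_marker, post_ref),
            None,
            None,
            ATYPICAL,
            frozenset(flags),
        )

    dcq_post = delta_cq(post_marker, post_ref)
    ddcq = delta_delta_cq(dcq_post, dcq_pre)
    percent, clip_flags = percent_chimerism(ddcq, efficiency_increment)
    return ChimerismEstimate(
        assay.id, dcq_pre, dcq_post, ddcq, percent, QUANTIFIED,
        frozenset(flags | set(clip_flags)),
    )


def summarize_sample(
    estimates: Sequence[ChimerismEstimate],
) -> SampleChimerismReport:
    """Aggregate per-marker estimates into a sample-level report.

    The mean is over markers with a value; CV = sample SD / mean over the
    same markers (undefined for fewer than two values or a zero mean).
    A sample is detected when at least one marker has a value.
    """
    if not estimates:
        raise ValidationError("summarize_sample requires at least one estimate")
    values = [
        e.percent_recipient for e in estimates if e.percent_recipient is not None
    ]
    if not values:
        return SampleChimerismReport(tuple(estimates), None, None, False)
    mean = fmean(values)
    cv: Optional[float] = None
    if len(values) >= 2 and not math.isclose(mean, 0.0):
        cv = stdev(values) / mean
    return SampleChimerismReport(tuple(estimates), mean, cv, True)
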