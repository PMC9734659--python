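"""Pre-transplant screening: marker calls, informativity, panel selection.

A marker is *positive* for a subject when it amplifies close to the
reference assay (small ΔCq), *negative* when it does not amplify at all
or amplifies far behind the reference, and *atypical* when the raw Cq
falls outside the assay's preset window or the ΔCq lands in the
ambiguous band between the positive and negative thresholds — atypical
amplifications are excluded as possibly non-specific.

A marker is informative for a donor/recipient pair when exactly one
subject carries it; the recipient-specific direction is the one used for
chimerism monitoring.  ``select_covering_markers`` finds a small marker
subset covering most pairs with at least one recipient-specific marker
(greedy set cover).
"""

from __future__ import annotations

import dataclasses
import itertools
from statistics import fmean
from typing import Iterable, Mapping, Optional, Sequence

from .errors import QCError, ValidationError
from .panel import MarkerAssay, Panel, WellMeasurement

POSITIVE = "positive"
NEGATIVE = "negative"
ATYPICAL = "atypical"

RECIPIENT_SPECIFIC = "recipient_specific"
DONOR_SPECIFIC = "donor_specific"
NON_INFORMATIVE = "non_informative"
INDETERMINATE = "indeterminate"


@dataclasses.dataclass(frozen=True)
class TypingCall:
    """Positive/negative/atypical call with the ΔCq it was based on."""

    status: str
    dcq: Optional[float] = None


@dataclasses.dataclass(frozen=True)
class PairScreenResult:
    """Per-marker informativity of one pair plus summary counts."""

    pair_id: str
    calls: Mapping[str, str]  # marker id -> informativity category

    @property
    def n_recipient_specific(self) -> int:
        return sum(1 for c in self.calls.values() if c == RECIPIENT_SPECIFIC)

    @property
    def n_donor_specific(self) -> int:
        return sum(1 for c in self.calls.values() if c == DONOR_SPECIFIC)

    @property
    def n_informative(self) -> int:
        return self.n_recipient_specific + self.n_donor_specific

    def recipient_specific_markers(self) -> frozenset[str]:
        return frozenset(m for m, c in self.calls.items() if c == RECIPIENT_SPECIFIC)


def mean_amplified_cq(wells: Sequence[WellMeasurement]) -> Optional[float]:
    """Mean Cq over amplified replicate wells; None if none amplified."""
    cqs = [w.cq for w in wells if w.cq is not None]
    return fmean(cqs) if cqs else None


def call_typing(
    marker_wells: Sequence[WellMeasurement],
    reference_wells: Sequence[WellMeasurement],
    assay: MarkerAssay,
) -> TypingCall:
    """Call one marker for one subject from its typing wells.

    No marker amplification in any replicate is a confident negative.
    Otherwise the mean amplified Cq must lie inside the assay's window
    (else atypical), and the ΔCq against the mean reference Cq is
    trichotomised: ≤ positive_dcq_max → positive, ≥ negative_dcq_min →
    negative, in between → atypical.  A sample whose reference assay
    never amplified is invalid, which is an error, not a negative call.
    """
    ref_cq = mean_amplified_cq(reference_wells)
    if ref_cq is None:
        raise QCError("reference assay did not amplify; sample invalid")
    marker_cq = mean_amplified_cq(marker_wells)
    if marker_cq is None:
        return TypingCall(NEGATIVE, None)
    if not assay.cq_in_window(marker_cq):
        return TypingCall(ATYPICAL, marker_cq - ref_cq)
    dcq = marker_cq - ref_cq
    if dcq <= assay.positive_dcq_max:
        return TypingCall(POSITIVE, dcq)
    if dcq >= assay.negative_dcq_min:
        return TypingCall(NEGATIVE, dcq)
    return TypingCall(ATYPICAL, dcq)


def classify_informativity(recipient: TypingCall, donor: TypingCall) -> str:
    """Informativity category of one marker for a pair.

    Total over the 3×3 status grid: any atypical call is indeterminate;
    a marker positive in exactly one subject is specific to that subject;
    concordant calls are non-informative.
    """
    if ATYPICAL in (recipient.status, donor.status):
        return INDETERMINATE
    if recipient.status == POSITIVE and donor.status == NEGATIVE:
        return RECIPIENT_SPECIFIC
    if donor.status == POSITIVE and recipient.status == NEGATIVE:
        return DONOR_SPECIFIC
    return NON_INFORMATIVE


def screen_pair(
    wells: Iterable[WellMeasurement],
    panel: Panel,
    recipient_sample: str,
    donor_sample: str,
    pair_id: str = "pair",
) -> PairScreenResult:
    """Type every marker for both subjects and classify informativity."""
    by_subject_assay: dict[tuple[str, str], list[WellMeasurement]] = {}
    for w in wells:
        by_subject_assay.setdefault((w.sample_id, w.assay_id), []).append(w)

    calls: dict[str, str] = {}
    for sample in (recipient_sample, donor_sample):
        if not any(key[0] == sample for key in by_subject_assay):
            raise ValidationError(f"no wells found for sample {sample!r}")
    for assay in panel.assays:
        subject_calls = {}
        for sample in (recipient_sample, donor_sample):
            marker_wells = by_subject_assay.get((sample, assay.id), [])
            ref_wells = by_subject_assay.get((sample, panel.reference_id), [])
            subject_calls[sample] = call_typing(marker_wells, ref_wells, assay)
        calls[assay.id] = classify_informativity(
            subject_calls[recipient_sample], subject_calls[donor_sample]
        )
    return PairScreenResult(pair_id, calls)


def coverage_fraction(
    screens: Sequence[PairScreenResult], subset: Iterable[str]
) -> float:
    """Fraction of pairs with ≥1 recipient-specific marker in the subset."""
    if not screens:
        return 0.0
    chosen = set(subset)
    covered = sum(
        1 for s in screens if s.recipient_specific_markers() & chosen
    )
    return covered / len(screens)


def select_covering_markers(
    screens: Sequence[PairScreenResult], k: int
) -> tuple[list[str], float]:
    """Greedy minimal marker subset covering pairs via recipient-specific markers.

    Repeatedly adds the marker covering the most yet-uncovered pairs
    (ties broken by lexicographic marker id), stopping early once no
    marker adds coverage.  Returns (ordered subset of size ≤ k, covered
    fraction).  Indeterminate markers never cover a pair.
    """
    if k < 0:
        raise ValidationError(f"k must be >= 0, got {k}")
    marker_to_pairs: dict[str, set[int]] = {}
    for i, s in enumerate(screens):
        for m in s.recipient_specific_markers():
            marker_to_pairs.setdefault(m, set()).add(i)

    selected: list[str] = []
    uncovered = set(range(len(screens)))
    for _ in range(k):
        best: Optional[str] = None
        best_gain = 0
        for m in sorted(marker_to_pairs):
            if m in selected:
                continue
            gain = len(marker_to_pairs[m] & uncovered)
            if gain > best_gain:
                best, best_gain = m, gain
        if best is None:
            break
        selected.append(best)
        uncovered -= marker_to_pairs[best]
    return selected, coverage_fraction(screens, selected)


def brute_force_cover(
    screens: Sequence[PairScreenResult], k: int
) -> tuple[tuple[str, ...], float]:
    """Exhaustive best coverage over all ≤k-subsets (oracle for small panels)."""
    markers = sorted({m for s in screens for m in s.recipient_specific_markers()})
    best: tuple[tuple[str, ...], float] = ((), coverage_fraction(screens, ()))
    for size in range(1, min(k, len(markers)) + 1):
        for combo in itertools.combinations(markers, size):
            cov = coverage_fraction(screens, combo)
            if cov > best[1]:
                best = (combo, cov)
    return best
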