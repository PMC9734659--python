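"""Cohort-level orchestration used by the command-line interface.

Ties measurements, sample sheets and the panel together: screen each
pair's typing plate, and quantify post-transplant samples against their
pre-transplant calibrators marker by marker.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, ValidationError
from .panel import Panel, SampleSheet, WellMeasurement
from .quantify import ChimerismEstimate, SampleChimerismReport, quantify_marker, summarize_sample
from .typing_engine import PairScreenResult, screen_pair


def _index_wells(
    wells: Iterable[WellMeasurement],
) -> dict[tuple[str, str], list[WellMeasurement]]:
    idx: dict[tuple[str, str], list[WellMeasurement]] = {}
    for w in wells:
        idx.setdefault((w.sample_id, w.assay_id), []).append(w)
    return idx


def screen_cohort(
    wells: Sequence[WellMeasurement], sheet: SampleSheet, panel: Panel
) -> list[PairScreenResult]:
    """Screen every pair in the sheet (pre-transplant donor vs recipient)."""
    results = []
    for pair_id in sheet.pair_ids():
        recipient = sheet.calibrator(pair_id)
        donors = sheet.find(pair_id, "donor", "pre")
        if not donors:
            raise ValidationError(f"pair {pair_id!r} has no pre-transplant donor sample")
        results.append(
            screen_pair(wells, panel, recipient.sample_id, donors[0].sample_id, pair_id)
        )
    return results


def quantify_post_sample(
    wells: Sequence[WellMeasurement],
    panel: Panel,
    pre_sample: str,
    post_sample: str,
    markers: Optional[Sequence[str]] = None,
    efficiency_increment: float = 1.0,
) -> SampleChimerismReport:
    """Quantify one post-transplant sample against its calibrator.

    With an explicit marker list, a marker unusable in the calibrator is
    an error; without one, every panel marker that amplifies cleanly in
    the calibrator is quantified and the rest are skipped.
    """
    idx = _index_wells(wells)
    explicit = markers is not None
    marker_ids = list(markers) if explicit else list(panel.marker_ids)
    estimates: list[ChimerismEstimate] = []
    for marker in marker_ids:
        assay = panel[marker]
        try:
            estimates.append(
                quantify_marker(
                    idx.get((pre_sample, marker), []),
                    idx.get((pre_sample, panel.reference_id), []),
                    idx.get((post_sample, marker), []),
                    idx.get((post_sample, panel.reference_id), []),
                    assay,
                    efficiency_increment,
                )
            )
        except ConfigurationError:
            if explicit:
                raise
    if not estimates:
        raise ConfigurationError(
            f"no usable marker for post sample {post_sample!r} "
            f"(calibrator {pre_sample!r})"
        )
    return summarize_sample(estimates)


def track_cohort(
    wells: Sequence[WellMeasurement],
    sheet: SampleSheet,
    panel: Panel,
    markers: Optional[Sequence[str]] = None,
    efficiency_increment: float = 1.0,
) -> list[tuple[str, str, SampleChimerismReport]]:
    """Quantify every post-transplant recipient sample in the sheet.

    Returns (pair_id, post sample id, report) triples.
    """
    out = []
    for pair_id in sheet.pair_ids():
        posts = sheet.find(pair_id, "recipient", "post")
        if not posts:
            continue
        calibrator = sheet.calibrator(pair_id)
        for post in posts:
            report = quantify_post_sample(
                wells, panel, calibrator.sample_id, post.sample_id,
                markers, efficiency_increment,
            )
            out.append((pair_id, post.sample_id, report))
    return out
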