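"""Virtual-mixture validation workflows.

Glue between the simulator and the quantifier: run a titration study end
to end, correlate estimates with the known mixture fractions, measure
well dropout at sub-percent chimerism, and locate the sample-level limit
of detection.  These are the in-silico twins of validating a chimerism
assay on DNA mixtures of known composition.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compare import pearson_r
from .errors import ValidationError
from .panel import Panel, WellMeasurement
from .quantify import quantify_marker
from .simulate import (
    MixtureSpec,
    SimulationParams,
    TitrationStudy,
    generate_titration_study,
    recipient_specific_pair,
    simulate_mixture_plate,
)

#: Fig-style titration grids: high range in percent ≥ 1, low range < 1.
HIGH_RANGE_LEVELS = (0.01, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 1.00)
LOW_RANGE_LEVELS = tuple(round(0.001 * i, 4) for i in range(1, 10))

#: The seven most informative markers used for tracking validation.
TOP_MARKERS = ("KMR019", "KMR028", "KMR037", "KMR041", "KMR045", "KMR049", "KMR051")

#: Replicate aliquots per titration sample.  Standard qPCR practice is to
#: measure each sample in triplicate and aggregate by mean Cq; the
#: within-sample CV across aliquots is only defined with >= 2.
TITRATION_REPLICATES = 3

#: Well allocation of the low-template dropout study: 16 wells across the
#: 0 / 0.1 / 0.2 % levels.  The published design gives only the total.
DROPOUT_WELL_ALLOCATION: Mapping[float, int] = {0.0: 6, 0.001: 5, 0.002: 5}


def quantify_titration(
    study: TitrationStudy, panel: Panel, params: SimulationParams
) -> pd.DataFrame:
    """Quantify every mixture sample of a titration study.

    Returns one row per (level, marker) with the estimated percent
    recipient chimerism (NaN when the marker never amplified) next to the
    true fraction.
    """
    by_sample_assay: dict[tuple[str, str], list[WellMeasurement]] = {}
    for w in study.wells:
        by_sample_assay.setdefault((w.sample_id, w.assay_id), []).append(w)

    rows = []
    for rec in study.truth.itertuples(index=False):
        assay = panel[rec.marker]
        est = quantify_marker(
            pre_marker_wells=by_sample_assay[(rec.calibrator_id, rec.marker)],
            pre_reference_wells=by_sample_assay[(rec.calibrator_id, panel.reference_id)],
            post_marker_wells=by_sample_assay[(rec.sample_id, rec.marker)],
            post_reference_wells=by_sample_assay[(rec.sample_id, panel.reference_id)],
            assay=assay,
            efficiency_increment=params.efficiency_increment,
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "marker": rec.marker,
                "true_fraction": rec.true_fraction,
                "true_percent": 100.0 * rec.true_fraction,
                "percent_estimate": (
                    math.nan
                    if est.percent_recipient is None
                    else est.percent_recipient
                ),
                "status": est.status,
            }
        )
    return pd.DataFrame.from_records(rows)


def titration_correlation(results: pd.DataFrame) -> float:
    """Pearson r between estimated and true percent, dropouts excluded."""
    valued = results.dropna(subset=["percent_estimate"])
    return pearson_r(valued["true_percent"], valued["percent_estimate"])


def run_titration(
    panel: Panel,
    levels: Sequence[float],
    params: SimulationParams,
    seed: int,
    markers: Sequence[str] = TOP_MARKERS,
    n_replicates: int = TITRATION_REPLICATES,
) -> pd.DataFrame:
    """Simulate + quantify one titration over recipient-specific markers.

    The simulated pair carries every selected marker heterozygously in
    the recipient and not at all in the donor; each mixture and
    calibrator sample is measured in replicate aliquots aggregated by
    mean Cq.
    """
    pair = recipient_specific_pair(panel, markers)
    rng = np.random.default_rng(seed)
    study = generate_titration_study(
        pair, levels, panel, params, rng, markers=markers, n_replicates=n_replicates
    )
    return quantify_titration(study, panel, params)


def high_range_correlation(
    panel: Panel, params: SimulationParams, seed: int
) -> float:
    """r between estimate and truth on the 1–100% grid, 7 markers/level."""
    return titration_correlation(
        run_titration(panel, HIGH_RANGE_LEVELS, params, seed)
    )


def low_range_correlation(
    panel: Panel, params: SimulationParams, seeds: Sequence[int]
) -> float:
    """Mean r over seeds on the 0.1–0.9% grid, dropout wells excluded."""
    rs = [
        titration_correlation(run_titration(panel, LOW_RANGE_LEVELS, params, s))
        for s in seeds
    ]
    return float(np.mean(rs))


def dropout_study(
    panel: Panel,
    params: SimulationParams,
    rng: np.random.Generator,
    well_allocation: Mapping[float, int] = DROPOUT_WELL_ALLOCATION,
    marker: str = TOP_MARKERS[0],
) -> tuple[int, int]:
    """Count non-amplified marker wells at very low recipient fractions.

    Simulates ``well_allocation[level]`` single-marker 10 ng wells per
    level (recipient heterozygous, donor non-carrier) and returns
    (dropout wells, total wells).
    """
    sub = panel.subset([marker])
    sub_pair = recipient_specific_pair(sub, [marker])
    dropouts = total = 0
    for level, n_wells in well_allocation.items():
        spec = MixtureSpec(true_fraction=level, n_replicates=n_wells)
        wells = simulate_mixture_plate(sub_pair, spec, params, sub, rng)
        marker_wells = [w for w in wells if w.assay_id == marker]
        total += len(marker_wells)
        dropouts += sum(1 for w in marker_wells if not w.amplified)
    return dropouts, total


def limit_of_detection(
    panel: Panel,
    params: SimulationParams,
    rng: np.random.Generator,
    levels: Sequence[float] = tuple(round(0.001 * i, 4) for i in range(3, 10)),
    markers: Sequence[str] = TOP_MARKERS,
) -> Optional[float]:
    """Lowest level from which detection is universal, for one replication.

    A sample is detected when at least one of its marker wells amplifies
    (any-marker rule).  Returns the lowest level L such that every sample
    at L and above is detected, or None if even the highest level drops
    out.
    """
    if not levels:
        raise ValidationError("levels must be non-empty")
    levels = sorted(levels)
    sub = panel.subset(list(markers))
    pair = recipient_specific_pair(sub, markers)
    detected = []
    for level in levels:
        spec = MixtureSpec(true_fraction=level, n_replicates=1)
        wells = simulate_mixture_plate(pair, spec, params, sub, rng)
        marker_wells = [w for w in wells if w.assay_id != sub.reference_id]
        detected.append(any(w.amplified for w in marker_wells))
    lod: Optional[float] = None
    for level, ok in zip(reversed(levels), reversed(detected)):
        if not ok:
            break
        lod = level
    return lod
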