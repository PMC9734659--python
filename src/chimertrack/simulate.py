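"""Synthetic genotypes and qPCR plates.

The generator reproduces the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without cohort data:

* genotypes — biallelic indel presence/absence markers under
  Hardy–Weinberg equilibrium for unrelated subjects, with Mendelian
  transmission for sibling and parent/child pairs;
* Cq measurements — each 10 ng well contains a Poisson number of usable
  template copies (rate proportional to DNA mass, marker copy number and
  a per-copy detection probability), amplification is log-linear with
  per-cycle factor (1+e), and a Gaussian jitter is added to every Cq.
  Zero detected copies means no amplification (an absent Cq), which is
  what limits detection at sub-percent chimerism.

With ``deterministic=True`` the Poisson draw is replaced by the exact
rate (k := λ) so closed-form identities hold to floating point; Gaussian
noise is still governed by ``cq_noise_sd`` (set it to 0 for fully
noise-free plates).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError
from .panel import (
    MarkerGenotype,
    PairGenotypes,
    Panel,
    WellMeasurement,
    VALID_RELATIONSHIPS,
)


class SimulationParams(BaseModel):
    """Generative constants of the qPCR model.

    Parameters
    ----------
    c0 : float
        Cq of a single detected template copy (cycles).  Only Cq
        differences matter downstream, so the absolute value is a
        convention; 38 cycles is typical for single-template qPCR.
    efficiency_increment : float
        Per-cycle amplification factor is ``1 + e``; ``e = 1`` is perfect
        doubling.
    cq_noise_sd : float
        SD of the Gaussian jitter added to each amplified well's Cq.
    p_det : float
        Per-template-copy detection/usability probability; thins the
        Poisson rate.  Together with ``cq_noise_sd`` this is calibrated
        so a 10 ng titration shows ~50% well dropout at ≤0.2% recipient
        DNA (0% wells included) and near-universal amplification ≥0.3%.
    genome_mass_pg : float
        Picograms of DNA per diploid human genome.
    deterministic : bool
        Replace the Poisson draw with k := λ exactly.
    seed : int
        Default RNG seed when no generator is passed explicitly.
    """

    c0: float = Field(default=38.0, gt=0)
    efficiency_increment: float = Field(default=1.0, gt=0, le=1)
    cq_noise_sd: float = Field(default=0.15, ge=0)
    p_det: float = Field(default=0.7, gt=0, le=1)
    genome_mass_pg: float = Field(default=6.6, gt=0)
    deterministic: bool = False
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class MixtureSpec(BaseModel):
    """One virtual DNA mixture: recipient fraction, mass per well, replicates."""

    true_fraction: float = Field(ge=0.0, le=1.0)
    dna_mass_ng: float = Field(default=10.0, gt=0)
    n_replicates: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _ok(self) -> "MixtureSpec":
        return self


def genome_count(dna_mass_ng: float, genome_mass_pg: float = 6.6) -> int:
    """Diploid genome copies in a well: floor(mass[pg] / genome mass[pg])."""
    return int(dna_mass_ng * 1000.0 / genome_mass_pg)


def simulate_unrelated_genotype(
    panel: Panel, rng: np.random.Generator
) -> dict[str, MarkerGenotype]:
    """Draw one subject's genotypes under Hardy–Weinberg equilibrium.

    Copy number at each marker is Binomial(2, q) with that marker's
    population indel-presence frequency q.
    """
    qs = np.array([a.allele_freq for a in panel.assays])
    copies = rng.binomial(2, qs)
    return {a.id: MarkerGenotype(int(c)) for a, c in zip(panel.assays, copies)}


def _transmit(parent_copies: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Mendelian allele per marker from a parent with given copy numbers."""
    return rng.random(parent_copies.shape) < parent_copies / 2.0


def simulate_pair(
    panel: Panel, relationship: str, rng: np.random.Generator
) -> PairGenotypes:
    """Draw a donor/recipient pair.

    unrelated — two independent Hardy–Weinberg draws.
    sibling — two parents under HWE; each sib inherits one allele from
    each parent, independently.
    parent_child — the donor is the parent; the child inherits one
    parental allele plus one population allele Bernoulli(q).
    """
    if relationship not in VALID_RELATIONSHIPS:
        raise ValidationError(
            f"relationship must be one of {VALID_RELATIONSHIPS}, got {relationship!r}"
        )
    qs = np.array([a.allele_freq for a in panel.assays])
    ids = panel.marker_ids

    def wrap(copies: np.ndarray) -> dict[str, MarkerGenotype]:
        return {m: MarkerGenotype(int(c)) for m, c in zip(ids, copies)}

    if relationship == "unrelated":
        donor = simulate_unrelated_genotype(panel, rng)
        recipient = simulate_unrelated_genotype(panel, rng)
        return PairGenotypes(donor, recipient, relationship)

    if relationship == "sibling":
        mother = rng.binomial(2, qs)
        father = rng.binomial(2, qs)
        sib1 = _transmit(mother, rng).astype(int) + _transmit(father, rng).astype(int)
        sib2 = _transmit(mother, rng).astype(int) + _transmit(father, rng).astype(int)
        return PairGenotypes(wrap(sib1), wrap(sib2), relationship)

    # parent_child
    parent = rng.binomial(2, qs)
    child = _transmit(parent, rng).astype(int) + (rng.random(qs.shape) < qs).astype(int)
    return PairGenotypes(wrap(parent), wrap(child), relationship)


def template_rates(
    pair: PairGenotypes,
    true_fraction: float,
    params: SimulationParams,
    panel: Panel,
    dna_mass_ng: float = 10.0,
) -> dict[str, float]:
    """Poisson template rates λ per assay for a mixture well.

    λ_marker = N_g · [f·z_recipient + (1−f)·z_donor] · p_det with N_g the
    diploid genome count; the reference assay sees both alleles of every
    genome: λ_ref = N_g · 2 · p_det.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValidationError(f"true_fraction must be in [0,1], got {true_fraction}")
    n_g = genome_count(dna_mass_ng, params.genome_mass_pg)
    f = true_fraction
    rates: dict[str, float] = {}
    for assay in panel.assays:
        z_r = pair.recipient[assay.id].copies
        z_d = pair.donor[assay.id].copies
        rates[assay.id] = n_g * (f * z_r + (1.0 - f) * z_d) * params.p_det
    rates[panel.reference_id] = n_g * 2.0 * params.p_det
    return rates


def _cq_from_copies(
    k: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Cq = c0 − log_{1+e}(k) + N(0, σ); k ≤ 0 yields NaN (no amplification)."""
    cq = np.full(k.shape, np.nan)
    amp = k > 0
    log_base = math.log(1.0 + params.efficiency_increment)
    cq[amp] = params.c0 - np.log(k[amp]) / log_base
    if params.cq_noise_sd > 0:
        cq[amp] += rng.normal(0.0, params.cq_noise_sd, size=int(amp.sum()))
    return cq


def simulate_mixture_plate(
    pair: PairGenotypes,
    spec: MixtureSpec,
    params: SimulationParams,
    panel: Panel,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "S1",
) -> list[WellMeasurement]:
    """Simulate all marker + reference wells for one mixture sample.

    Each replicate well draws detected copies k ~ Poisson(λ) (or k := λ
    in deterministic mode); k = 0 gives an absent Cq, otherwise
    Cq = c0 − log_{1+e}(k) + Gaussian noise.
    """
    if rng is None:
        rng = params.rng()
    pair.validate_against(panel)
    rates = template_rates(pair, spec.true_fraction, params, panel, spec.dna_mass_ng)
    wells: list[WellMeasurement] = []
    assay_ids = list(panel.marker_ids) + [panel.reference_id]
    for assay_id in assay_ids:
        lam = rates[assay_id]
        if params.deterministic:
            k = np.full(spec.n_replicates, lam)
        else:
            k = rng.poisson(lam, size=spec.n_replicates).astype(float)
        cqs = _cq_from_copies(k, params, rng)
        for rep, cq in enumerate(cqs, start=1):
            wells.append(
                WellMeasurement(
                    sample_id, assay_id, rep, None if np.isnan(cq) else float(cq)
                )
            )
    return wells


@dataclasses.dataclass(frozen=True)
class TitrationStudy:
    """A simulated titration: wells plus truth labels.

    ``truth`` has one row per (level, marker) mixture sample with columns
    sample_id, calibrator_id, marker, true_fraction.  Calibrator samples
    are pure recipient DNA (f = 1) and play the pre-transplant role.
    """

    wells: tuple[WellMeasurement, ...]
    truth: pd.DataFrame


def generate_titration_study(
    pair: PairGenotypes,
    levels: Sequence[float],
    panel: Panel,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    markers: Optional[Sequence[str]] = None,
    dna_mass_ng: float = 10.0,
    n_replicates: int = 1,
) -> TitrationStudy:
    """Simulate the virtual-mixture validation experiment.

    One mixture sample per (level × marker), each with its own
    pure-recipient calibrator wells; the true fraction of every sample is
    retained so estimates can be validated against the labels.
    """
    if len(levels) == 0:
        raise ValidationError("levels must be non-empty")
    for f in levels:
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"titration level {f} outside [0,1]")
    if rng is None:
        rng = params.rng()
    marker_ids = tuple(markers) if markers is not None else panel.marker_ids

    wells: list[WellMeasurement] = []
    records: list[dict[str, object]] = []
    for marker in marker_ids:
        sub = panel.subset([marker])
        sub_pair = PairGenotypes(
            donor={marker: pair.donor[marker]},
            recipient={marker: pair.recipient[marker]},
            relationship=pair.relationship,
        )
        for level in levels:
            sid = f"mix_{marker}_{level:g}"
            cal_id = f"cal_{marker}_{level:g}"
            cal_spec = MixtureSpec(
                true_fraction=1.0, dna_mass_ng=dna_mass_ng, n_replicates=n_replicates
            )
            mix_spec = MixtureSpec(
                true_fraction=level, dna_mass_ng=dna_mass_ng, n_replicates=n_replicates
            )
            wells += simulate_mixture_plate(sub_pair, cal_spec, params, sub, rng, cal_id)
            wells += simulate_mixture_plate(sub_pair, mix_spec, params, sub, rng, sid)
            records.append(
                {
                    "sample_id": sid,
                    "calibrator_id": cal_id,
                    "marker": marker,
                    "true_fraction": level,
                }
            )
    return TitrationStudy(tuple(wells), pd.DataFrame.from_records(records))


def recipient_specific_pair(
    panel: Panel, markers: Optional[Sequence[str]] = None, recipient_copies: int = 1
) -> PairGenotypes:
    """A pair where every (selected) marker is recipient-specific.

    The recipient is a heterozygous carrier by default and the donor a
    non-carrier, the configuration a virtual-mixture validation targets.
    """
    chosen = set(markers) if markers is not None else set(panel.marker_ids)
    donor = {m: MarkerGenotype(0) for m in panel.marker_ids}
    recipient = {
        m: MarkerGenotype(recipient_copies if m in chosen else 0)
        for m in panel.marker_ids
    }
    return PairGenotypes(donor, recipient, "unrelated")
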