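"""Marker panels, genotypes, samples and qPCR measurements.

An indel marker is assayed by presence/absence qPCR: a diploid genotype
carries 0, 1 or 2 copies of the indel-presence allele.  A panel bundles
the marker assays with the invariant internal reference assay used as
the denominator of every ΔCq.  On-disk formats are deliberately plain:
panels are JSON, Cq plates are CSV (one row per well, an empty Cq cell
meaning no amplification), reports are TSV.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import FormatError, ValidationError

#: Cq values accepted on input as "no amplification" besides the empty cell.
NO_AMP_TOKENS = {"", "undetermined", "no amp", "na"}

VALID_RELATIONSHIPS = ("unrelated", "sibling", "parent_child")


class MarkerAssay(BaseModel):
    """One indel qPCR assay.

    Parameters
    ----------
    id : str
        Short assay name, e.g. ``"KMR019"``.
    allele_freq : float
        Population frequency q of the indel-presence allele, in [0, 1].
    cq_window : (float, float)
        Acceptable raw-Cq range; a Cq outside it is an atypical
        amplification and is excluded as possibly non-specific.
    positive_dcq_max : float
        Largest ΔCq (marker − reference) still called a confident positive.
    negative_dcq_min : float
        Smallest ΔCq still called a confident negative.  ΔCq values in the
        open band between the two thresholds are atypical.
    """

    id: str = Field(min_length=1)
    allele_freq: float = Field(ge=0.0, le=1.0)
    cq_window: tuple[float, float]
    positive_dcq_max: float = 3.0
    negative_dcq_min: float = 6.0

    @model_validator(mode="after")
    def _check_windows(self) -> "MarkerAssay":
        lo, hi = self.cq_window
        if not lo < hi:
            raise ValueError(f"cq_window low must be < high, got {self.cq_window}")
        if not self.positive_dcq_max < self.negative_dcq_min:
            raise ValueError(
                "positive_dcq_max must be < negative_dcq_min "
                f"({self.positive_dcq_max} vs {self.negative_dcq_min})"
            )
        return self

    def cq_in_window(self, cq: float) -> bool:
        lo, hi = self.cq_window
        return lo <= cq <= hi


class Panel(BaseModel):
    """An ordered set of marker assays plus the internal reference assay id."""

    assays: tuple[MarkerAssay, ...]
    reference_id: str = Field(min_length=1)

    @model_validator(mode="after")
    def _check_ids(self) -> "Panel":
        ids = [a.id for a in self.assays]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate assay ids: {sorted(dupes)}")
        if self.reference_id in ids:
            raise ValueError(f"reference_id {self.reference_id!r} collides with a marker id")
        return self

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.assays)

    def __getitem__(self, marker_id: str) -> MarkerAssay:
        for a in self.assays:
            if a.id == marker_id:
                return a
        raise KeyError(marker_id)

    def __contains__(self, assay_id: str) -> bool:
        return assay_id == self.reference_id or any(a.id == assay_id for a in self.assays)

    def subset(self, marker_ids: Sequence[str]) -> "Panel":
        """Panel restricted to the given markers (order preserved)."""
        missing = [m for m in marker_ids if m not in self.marker_ids]
        if missing:
            raise ValidationError(f"markers not in panel: {missing}")
        return Panel(
            assays=tuple(a for a in self.assays if a.id in set(marker_ids)),
            reference_id=self.reference_id,
        )


@dataclasses.dataclass(frozen=True)
class MarkerGenotype:
    """Indel-presence allele copies per diploid genome: 0, 1 or 2.

    The qPCR readout does not distinguish heterozygous from homozygous
    carriers; the copy number matters only for template-rate simulation.
    """

    copies: int

    def __post_init__(self) -> None:
        if self.copies not in (0, 1, 2):
            raise ValidationError(f"copies must be 0, 1 or 2, got {self.copies}")

    @property
    def carrier(self) -> bool:
        return self.copies > 0


@dataclasses.dataclass(frozen=True)
class PairGenotypes:
    """Genotypes of one donor/recipient pair over a panel's markers."""

    donor: Mapping[str, MarkerGenotype]
    recipient: Mapping[str, MarkerGenotype]
    relationship: str = "unrelated"

    def __post_init__(self) -> None:
        if self.relationship not in VALID_RELATIONSHIPS:
            raise ValidationError(
                f"relationship must be one of {VALID_RELATIONSHIPS}, got {self.relationship!r}"
            )
        if set(self.donor) != set(self.recipient):
            raise ValidationError("donor and recipient genotype maps cover different markers")

    def validate_against(self, panel: Panel) -> None:
        if set(self.donor) != set(panel.marker_ids):
            raise ValidationError("pair genotypes do not cover exactly the panel's markers")


@dataclasses.dataclass(frozen=True)
class WellMeasurement:
    """One well's Cq; ``cq is None`` encodes no amplification."""

    sample_id: str
    assay_id: str
    replicate: int
    cq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.cq is not None:
            if not (self.cq >= 0.0) or self.cq != self.cq or self.cq == float("inf"):
                raise ValidationError(f"cq must be finite and >= 0, got {self.cq}")

    @property
    def amplified(self) -> bool:
        return self.cq is not None


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subject_role: str  # donor | recipient
    timepoint: str  # pre | post
    pair_id: str


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to pair / role / timepoint."""

    rows: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.subject_role not in ("donor", "recipient"):
                raise ValidationError(f"bad subject_role {r.subject_role!r} for {r.sample_id}")
            if r.timepoint not in ("pre", "post"):
                raise ValidationError(f"bad timepoint {r.timepoint!r} for {r.sample_id}")

    def pair_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rows:
            if r.pair_id not in seen:
                seen.append(r.pair_id)
        return tuple(seen)

    def find(self, pair_id: str, subject_role: str, timepoint: str) -> tuple[SampleRecord, ...]:
        return tuple(
            r
            for r in self.rows
            if r.pair_id == pair_id and r.subject_role == subject_role and r.timepoint == timepoint
        )

    def calibrator(self, pair_id: str) -> SampleRecord:
        """The unique pre-transplant recipient sample of a pair."""
        hits = self.find(pair_id, "recipient", "pre")
        if len(hits) != 1:
            raise ValidationError(
                f"pair {pair_id!r} must have exactly one recipient/pre sample, found {len(hits)}"
            )
        return hits[0]


# ---------------------------------------------------------------------------
# File I/O


def read_panel(path: str | Path) -> Panel:
    """Read a panel JSON file.

    Schema: ``{"reference_id": str, "assays": [{"id", "allele_freq",
    "cq_window", "positive_dcq_max", "negative_dcq_min"}, ...]}``.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    return panel_from_dict(raw, source=str(path))


def panel_from_dict(raw: object, source: str = "<dict>") -> Panel:
    try:
        return Panel.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries field locations
        raise FormatError(f"{source}: invalid panel: {exc}") from exc


def write_panel(panel: Panel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(panel.model_dump(), indent=1) + "\n")


def default_panel() -> Panel:
    """The bundled 39-marker panel (30 core + 9 extended assays).

    Allele frequencies are a uniform placeholder q = 0.25 — the real
    per-marker population frequencies are not published — and every field
    is overridable via a user panel file.
    """
    resource = importlib.resources.files("chimertrack") / "data" / "default_panel.json"
    with resource.open() as fh:
        return panel_from_dict(json.load(fh), source="default_panel.json")


def _parse_cq_cell(value: object) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text.lower() in NO_AMP_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"unparseable cq value {value!r}")


def read_cq_table(path: str | Path, panel: Panel) -> list[WellMeasurement]:
    """Read a Cq CSV (columns sample_id, assay_id, replicate, cq).

    An empty cq cell (or "Undetermined") means no amplification.  Every
    assay id must be a panel marker or the reference assay.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ["sample_id", "assay_id", "replicate", "cq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    wells: list[WellMeasurement] = []
    for row in df.itertuples(index=False):
        assay_id = row.assay_id
        if assay_id not in panel:
            raise ValidationError(f"{path}: unknown assay id {assay_id!r}")
        cq = _parse_cq_cell(row.cq)
        if cq is not None and cq < 0:
            raise ValidationError(f"{path}: negative cq {cq} for sample {row.sample_id!r}")
        try:
            replicate = int(row.replicate)
        except ValueError:
            raise FormatError(f"{path}: non-integer replicate {row.replicate!r}")
        wells.append(WellMeasurement(row.sample_id, assay_id, replicate, cq))
    return wells


def write_cq_table(
    wells: Iterable[WellMeasurement], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write wells as the canonical Cq CSV (empty cell = no amplification)."""
    df = pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "assay_id": [w.assay_id for w in wells],
            "replicate": [w.replicate for w in wells],
            "cq": [("" if w.cq is None else repr(w.cq)) for w in wells],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = ["sample_id", "subject_role", "timepoint", "pair_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    rows = tuple(
        SampleRecord(r.sample_id, r.subject_role, r.timepoint, r.pair_id)
        for r in df.itertuples(index=False)
    )
    return SampleSheet(rows)


REPORT_COLUMNS = [
    "pair_id",
    "sample_id",
    "marker",
    "dcq_pre",
    "dcq_post",
    "ddcq",
    "percent_recipient",
    "status",
    "flags",
]


def write_report(rows: Iterable[Mapping[str, object]], path: str | Path,
                 header_lines: Sequence[str] = ()) -> None:
    """Write per-marker chimerism rows as TSV with a stable column order.

    Missing values (no amplification / not detected) are written as empty
    cells; ``flags`` is a comma-joined list.
    """

    def fmt(value: object) -> str:
        if value is None:
            return ""
        if isinstance(value, float):
            return repr(value)
        if isinstance(value, (set, frozenset, list, tuple)):
            return ",".join(sorted(str(v) for v in value))
        return str(value)

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row.get(c)) for c in REPORT_COLUMNS) + "\n")


def read_report(path: str | Path) -> list[dict[str, object]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    out: list[dict[str, object]] = []
    for r in df.itertuples(index=False):
        row: dict[str, object] = {}
        for col in REPORT_COLUMNS:
            text = getattr(r, col)
            if col in ("dcq_pre", "dcq_post", "ddcq", "percent_recipient"):
                row[col] = None if text == "" else float(text)
            elif col == "flags":
                row[col] = frozenset(text.split(",")) if text else frozenset()
            else:
                row[col] = text
        out.append(row)
    return out
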