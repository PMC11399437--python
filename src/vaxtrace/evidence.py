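"""Vaccine evidence table: typed records, probability conversions, box layouts.

The decision task presents eight licensed COVID-19 vaccines, each with three
side effects (with frequencies per 1,000,000) and three protection benefits
(with effectiveness percentages).  Side-effect frequencies and effectiveness
percentages are converted to fractions on load.  Each vaccine also carries a
three-level country-of-origin category (US, China, other) and a three-level
technology category (mRNA, vector, other) used for sum-to-zero vaccine
contrasts in the decision model.

The 15 distinct side effects are partitioned by severity: 4 mild, 5 severe
and 6 extreme.  Benefits have no severity class.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "MISSING",
    "OutcomeSpec",
    "VaccineSpec",
    "EvidenceTable",
    "EvidenceValidationError",
    "UnknownLabelError",
    "Box",
    "load_evidence_table",
    "write_evidence_table",
    "convert_probability",
    "normalize_label",
    "severity_of",
    "evidence_layout",
    "SEVERITY_CLASSES",
]

#: sentinel for benefit probabilities that were not presented ("–" cells)
MISSING = None

SIDE_EFFECT = "side_effect"
BENEFIT = "benefit"

KINDS = (SIDE_EFFECT, BENEFIT)
SEVERITIES = ("mild", "severe", "extreme", "not_applicable")
COUNTRY_CATEGORIES = ("US", "China", "other")
TECHNOLOGY_CATEGORIES = ("mRNA", "vector", "other")
PROBABILITY_FORMATS = ("per_million", "percent")

#: canonical severity partition of the 15 side-effect labels
SEVERITY_CLASSES: dict[str, frozenset[str]] = {
    "mild": frozenset({"fever", "tiredness", "headache", "muscle pain"}),
    "severe": frozenset(
        {
            "severe general discomfort",
            "severe drowsiness",
            "severe tiredness",
            "severe headache",
            "severe muscle pain",
        }
    ),
    "extreme": frozenset(
        {
            "blood clots",
            "immune system attacks nerves",
            "immune system attacks blood",
            "facial paralysis",
            "heart muscle inflammation",
            "heart membrane inflammation",
        }
    ),
}

_LABEL_TO_SEVERITY = {
    label: sev for sev, labels in SEVERITY_CLASSES.items() for label in labels
}


class EvidenceValidationError(ValueError):
    """Raised when an evidence table violates its schema or invariants."""


class UnknownLabelError(KeyError):
    """Raised for side-effect labels outside the known 15."""


def normalize_label(label: str) -> str:
    """Canonicalize an outcome label: lowercase, collapse whitespace,
    strip parenthetical clarifications such as "(myocarditis)"."""
    s = re.sub(r"\([^)]*\)", " ", label)
    s = re.sub(r"\s+", " ", s).strip().lower()
    return s


def severity_of(label: str) -> str:
    """Severity class (mild / severe / extreme) of a side-effect label."""
    key = normalize_label(label)
    try:
        return _LABEL_TO_SEVERITY[key]
    except KeyError:
        known = sorted(_LABEL_TO_SEVERITY)
        raise UnknownLabelError(
            f"unknown side-effect label {label!r}; known labels: {known}"
        ) from None


def convert_probability(raw: float, format: str) -> float:
    """Convert a displayed probability (cases per 1,000,000 or a percent)
    to a fraction in [0, 1]."""
    if format not in PROBABILITY_FORMATS:
        raise EvidenceValidationError(f"unknown probability format {format!r}")
    if raw < 0:
        raise EvidenceValidationError(f"negative probability value {raw!r}")
    if format == "per_million":
        if raw > 1_000_000:
            raise EvidenceValidationError(f"per-million value {raw!r} exceeds 1,000,000")
        return raw / 1e6
    if raw > 100:
        raise EvidenceValidationError(f"percent value {raw!r} exceeds 100")
    return raw / 100.0


@dataclass(frozen=True)
class OutcomeSpec:
    """One vaccine outcome as shown in the task: a side effect or a benefit,
    with its displayed probability converted to a fraction (``MISSING`` for
    benefits whose effectiveness was not presented)."""

    label: str
    kind: str
    severity: str
    probability: float | None
    display_format: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise EvidenceValidationError(f"{self.label!r}: bad kind {self.kind!r}")
        if self.severity not in SEVERITIES:
            raise EvidenceValidationError(
                f"{self.label!r}: bad severity {self.severity!r}"
            )
        if (self.severity == "not_applicable") != (self.kind == BENEFIT):
            raise EvidenceValidationError(
                f"{self.label!r}: severity is not_applicable iff kind is benefit"
            )
        if self.probability is MISSING:
            if self.kind != BENEFIT:
                raise EvidenceValidationError(
                    f"{self.label!r}: only benefits may lack a probability"
                )
        elif not 0.0 <= self.probability <= 1.0:
            raise EvidenceValidationError(
                f"{self.label!r}: probability {self.probability!r} outside [0, 1]"
            )
        if self.display_format not in PROBABILITY_FORMATS:
            raise EvidenceValidationError(
                f"{self.label!r}: bad display format {self.display_format!r}"
            )


@dataclass(frozen=True)
class VaccineSpec:
    """One vaccine: brand, category codings, three side effects, three benefits."""

    brand: str
    country_category: str
    technology_category: str
    side_effects: tuple[OutcomeSpec, ...]
    benefits: tuple[OutcomeSpec, ...]

    def __post_init__(self) -> None:
        if self.country_category not in COUNTRY_CATEGORIES:
            raise EvidenceValidationError(
                f"{self.brand!r}: bad country category {self.country_category!r}"
            )
        if self.technology_category not in TECHNOLOGY_CATEGORIES:
            raise EvidenceValidationError(
                f"{self.brand!r}: bad technology category {self.technology_category!r}"
            )
        if len(self.side_effects) != 3 or any(
            o.kind != SIDE_EFFECT for o in self.side_effects
        ):
            raise EvidenceValidationError(
                f"{self.brand!r}: expected exactly 3 side effects"
            )
        if len(self.benefits) != 3 or any(o.kind != BENEFIT for o in self.benefits):
            raise EvidenceValidationError(f"{self.brand!r}: expected exactly 3 benefits")

    @property
    def outcomes(self) -> tuple[OutcomeSpec, ...]:
        return self.side_effects + self.benefits


@dataclass(frozen=True)
class EvidenceTable:
    """The full 8-vaccine evidence grid plus the severity partition of the
    side-effect labels appearing in it."""

    vaccines: tuple[VaccineSpec, ...]
    severity_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.vaccines) != 8:
            raise EvidenceValidationError(
                f"expected exactly 8 vaccines, got {len(self.vaccines)}"
            )
        labels = self.side_effect_labels()
        if set(self.severity_map) != set(labels):
            raise EvidenceValidationError(
                "severity_map must cover exactly the side-effect labels present"
            )
        for label, sev in self.severity_map.items():
            if sev != severity_of(label):
                raise EvidenceValidationError(
                    f"severity_map[{label!r}] = {sev!r} contradicts canonical class"
                )

    def side_effect_labels(self) -> list[str]:
        """Distinct normalized side-effect labels across all vaccines."""
        seen: dict[str, None] = {}
        for v in self.vaccines:
            for o in v.side_effects:
                seen.setdefault(normalize_label(o.label), None)
        return list(seen)

    def vaccine(self, brand: str) -> VaccineSpec:
        for v in self.vaccines:
            if v.brand == brand:
                return v
        raise KeyError(f"unknown vaccine brand {brand!r}")

    @property
    def brands(self) -> list[str]:
        return [v.brand for v in self.vaccines]


_CSV_COLUMNS = [
    "vaccine",
    "country_category",
    "technology_category",
    "outcome_kind",
    "outcome_label",
    "severity",
    "probability_raw",
    "probability_format",
]


def _packaged_csv() -> Iterable[str]:
    return (
        resources.files("vaxtrace.data")
        .joinpath("evidence_table.csv")
        .read_text(encoding="utf-8")
        .splitlines()
    )


def load_evidence_table(source: str | Path | None = None) -> EvidenceTable:
    """Load and validate an evidence table.

    With ``source=None`` the packaged transcription of the study's evidence
    grid is used; otherwise ``source`` must be a CSV file in the same schema
    (see the packaged ``data/evidence_table.csv`` for the column set).
    """
    if source is None:
        lines: Iterable[str] = _packaged_csv()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    reader = csv.DictReader(lines)
    missing_cols = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
    if missing_cols:
        raise EvidenceValidationError(f"missing columns: {sorted(missing_cols)}")

    rows_by_vaccine: dict[str, list[dict[str, str]]] = {}
    for i, row in enumerate(reader, start=2):
        if not row.get("vaccine"):
            raise EvidenceValidationError(f"row {i}: empty vaccine name")
        rows_by_vaccine.setdefault(row["vaccine"], []).append(row | {"_line": str(i)})

    vaccines = []
    for brand, rows in rows_by_vaccine.items():
        side_effects, benefits = [], []
        country = rows[0]["country_category"]
        tech = rows[0]["technology_category"]
        for row in rows:
            kind = row["outcome_kind"]
            raw = row["probability_raw"].strip()
            fmt = row["probability_format"]
            if raw == "":
                if kind != BENEFIT:
                    raise EvidenceValidationError(
                        f"row {row['_line']}: missing probability for a side effect"
                    )
                prob = MISSING
            else:
                try:
                    prob = convert_probability(float(raw), fmt)
                except (ValueError, EvidenceValidationError) as exc:
                    raise EvidenceValidationError(
                        f"row {row['_line']}: {exc}"
                    ) from None
            outcome = OutcomeSpec(
                label=row["outcome_label"],
                kind=kind,
                severity=row["severity"],
                probability=prob,
                display_format=fmt,
            )
            if kind == SIDE_EFFECT:
                if outcome.severity != severity_of(outcome.label):
                    raise EvidenceValidationError(
                        f"row {row['_line']}: severity {outcome.severity!r} "
                        f"contradicts canonical class for {outcome.label!r}"
                    )
                side_effects.append(outcome)
            else:
                benefits.append(outcome)
        vaccines.append(
            VaccineSpec(
                brand=brand,
                country_category=country,
                technology_category=tech,
                side_effects=tuple(side_effects),
                benefits=tuple(benefits),
            )
        )

    severity_map: dict[str, str] = {}
    for v in vaccines:
        for o in v.side_effects:
            severity_map[normalize_label(o.label)] = o.severity
    return EvidenceTable(vaccines=tuple(vaccines), severity_map=severity_map)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    """Write an evidence table back to CSV in the packaged schema."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for v in table.vaccines:
            for o in v.outcomes:
                if o.probability is MISSING:
                    raw = ""
                elif o.display_format == "per_million":
                    raw = format(o.probability * 1e6, "g")
                else:
                    raw = format(o.probability * 100, "g")
                writer.writerow(
                    [
                        v.brand,
                        v.country_category,
                        v.technology_category,
                        o.kind,
                        o.label,
                        o.severity,
                        raw,
                        o.display_format,
                    ]
                )


@dataclass(frozen=True)
class Box:
    """One hideable information box in a trial.

    ``slot`` is positional ("se1".."se3", "b1".."b3"); ``part`` is either
    "outcome" or "prob".  The brand, country and technology banner is always
    visible and is not a box.
    """

    slot: str
    part: str
    outcome_label: str

    @property
    def box_id(self) -> str:
        return f"{self.slot}:{self.part}"


def evidence_layout(vaccine: VaccineSpec) -> list[Box]:
    """Ordered boxes for one trial: an outcome box and a probability box per
    outcome.  A benefit with no presented effectiveness contributes an
    outcome box only."""
    boxes: list[Box] = []
    for prefix, outcomes in (("se", vaccine.side_effects), ("b", vaccine.benefits)):
        for i, o in enumerate(outcomes, start=1):
            slot = f"{prefix}{i}"
            boxes.append(Box(slot=slot, part="outcome", outcome_label=o.label))
            if o.probability is not MISSING:
                boxes.append(Box(slot=slot, part="prob", outcome_label=o.label))
    return boxes
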