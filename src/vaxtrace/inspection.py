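"""Preprocessing of Mouselab hover logs into deliberate-ignorance indices.

Hover events shorter than 200 ms are treated as incidental mouse passes and
removed (an event lasting exactly 200 ms is retained).  All downstream
indices use inspection *counts*, never durations.

Each trial is assigned one of three deliberate-ignorance levels:

* ``full``    — no evidence box was inspected;
* ``none``    — every evidence box was inspected at least once;
* ``partial`` — anything in between.

Probability neglect is flagged per category (side effects overall, mild /
severe / extreme side effects, benefits) when at least one outcome box in
the category was inspected while its paired probability box was never
inspected.  The definition is strict and one-directional: inspecting a
probability without its outcome is not neglect, and a benefit whose
effectiveness was never presented (no probability box) cannot produce a
neglect flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import Box, EvidenceTable, evidence_layout

__all__ = [
    "MIN_DELIBERATE_MS",
    "InspectionEvent",
    "CleanedLog",
    "TrialIgnoranceSummary",
    "filter_incidental",
    "classify_ignorance_level",
    "detect_probability_neglect",
    "summarize_trials",
    "summaries_to_frame",
    "summarize_ignorance",
    "process_events",
]

#: inspections shorter than this many milliseconds are incidental
MIN_DELIBERATE_MS = 200

_SLOTS = ("se1", "se2", "se3", "b1", "b2", "b3")
_SEVERITIES = ("mild", "severe", "extreme")


@dataclass(frozen=True)
class InspectionEvent:
    """One hover event over a labeled box in one trial."""

    participant_id: str
    trial_index: int
    vaccine: str
    box_id: str
    onset_ms: int
    duration_ms: int

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(
                f"duration must be positive, got {self.duration_ms} "
                f"(participant {self.participant_id}, trial {self.trial_index})"
            )
        if self.onset_ms < 0:
            raise ValueError("onset must be nonnegative")


@dataclass
class CleanedLog:
    """Duration-filtered events plus per-trial, per-box inspection counts."""

    events: list[InspectionEvent]
    counts: dict[tuple[str, int], dict[str, int]]  # (participant, trial) -> box -> n


def filter_incidental(events: Iterable[InspectionEvent]) -> CleanedLog:
    """Drop events shorter than 200 ms and tally inspections per box."""
    kept = [e for e in events if e.duration_ms >= MIN_DELIBERATE_MS]
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for e in kept:
        trial = counts.setdefault((e.participant_id, e.trial_index), {})
        trial[e.box_id] = trial.get(e.box_id, 0) + 1
    return CleanedLog(events=kept, counts=counts)


def classify_ignorance_level(
    counts: Mapping[str, int], layout: Sequence[Box]
) -> str:
    """full / partial / none from per-box inspection counts."""
    box_ids = {b.box_id for b in layout}
    unknown = set(counts) - box_ids
    if unknown:
        raise ValueError(f"counts reference boxes outside the layout: {sorted(unknown)}")
    inspected = {b for b, n in counts.items() if n > 0}
    if not inspected:
        return "full"
    if inspected == box_ids:
        return "none"
    return "partial"


def detect_probability_neglect(
    counts: Mapping[str, int],
    layout: Sequence[Box],
    severity_map: Mapping[str, str],
) -> dict[str, bool]:
    """Per-category neglect flags from one trial's inspection counts.

    Returns keys ``side_effects``, ``benefits``, ``mild``, ``severe``,
    ``extreme``.  A category is flagged iff some outcome box in it was
    inspected while its existing probability box was not.
    """
    from .evidence import normalize_label

    flags = {k: False for k in ("side_effects", "benefits", *_SEVERITIES)}
    prob_slots = {b.slot for b in layout if b.part == "prob"}
    for box in layout:
        if box.part != "outcome" or box.slot not in prob_slots:
            continue
        outcome_seen = counts.get(f"{box.slot}:outcome", 0) > 0
        prob_seen = counts.get(f"{box.slot}:prob", 0) > 0
        if outcome_seen and not prob_seen:
            if box.slot.startswith("se"):
                flags["side_effects"] = True
                flags[severity_map[normalize_label(box.outcome_label)]] = True
            else:
                flags["benefits"] = True
    return flags


@dataclass
class TrialIgnoranceSummary:
    """Ignorance level and neglect flags for one participant x trial."""

    participant_id: str
    trial_index: int
    vaccine: str
    ignorance_level: str
    neglect_side_effects: bool
    neglect_benefits: bool
    neglect_by_severity: dict[str, bool]
    slot_inspected: dict[str, bool]  # outcome box inspected, per slot
    slot_prob_inspected: dict[str, bool]  # probability box inspected, per slot

    def __post_init__(self) -> None:
        any_neglect = (
            self.neglect_side_effects
            or self.neglect_benefits
            or any(self.neglect_by_severity.values())
        )
        if self.ignorance_level in ("full", "none") and any_neglect:
            raise ValueError(
                f"{self.ignorance_level} ignorance cannot carry neglect flags"
            )
        if self.neglect_side_effects != any(self.neglect_by_severity.values()):
            raise ValueError("side-effect neglect must be the OR of severity flags")


def summarize_trials(
    log: CleanedLog,
    table: EvidenceTable,
    trial_vaccines: Mapping[tuple[str, int], str],
) -> list[TrialIgnoranceSummary]:
    """Build one summary per (participant, trial) listed in
    ``trial_vaccines`` (trials with no retained events count as full
    ignorance)."""
    out = []
    for (pid, trial), brand in trial_vaccines.items():
        vaccine = table.vaccine(brand)
        layout = evidence_layout(vaccine)
        counts = log.counts.get((pid, trial), {})
        level = classify_ignorance_level(counts, layout)
        flags = detect_probability_neglect(counts, layout, table.severity_map)
        out.append(
            TrialIgnoranceSummary(
                participant_id=pid,
                trial_index=trial,
                vaccine=brand,
                ignorance_level=level,
                neglect_side_effects=flags["side_effects"],
                neglect_benefits=flags["benefits"],
                neglect_by_severity={s: flags[s] for s in _SEVERITIES},
                slot_inspected={
                    s: counts.get(f"{s}:outcome", 0) > 0 for s in _SLOTS
                },
                slot_prob_inspected={
                    s: counts.get(f"{s}:prob", 0) > 0 for s in _SLOTS
                },
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[TrialIgnoranceSummary]) -> pd.DataFrame:
    """Tabular form consumed by the model-assembly and statistics modules."""
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "trial_index": s.trial_index,
            "vaccine": s.vaccine,
            "ignorance_level": s.ignorance_level,
            "neglect_side_effects": s.neglect_side_effects,
            "neglect_benefits": s.neglect_benefits,
        }
        for sev, flag in s.neglect_by_severity.items():
            row[f"neglect_{sev}"] = flag
        for slot in _SLOTS:
            row[f"{slot}_insp"] = s.slot_inspected[slot]
            row[f"{slot}_prob_insp"] = s.slot_prob_inspected[slot]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_ignorance(
    summaries: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Group-level descriptives: proportion of trials at each ignorance
    level, proportion of trials with each neglect flag, and proportion of
    participants with at least one neglect trial.

    ``groups`` maps participant_id to attitude-group label.
    """
    df = summaries.copy()
    groups = dict(groups)
    unknown = set(df["participant_id"].astype(str)) - set(map(str, groups))
    if unknown:
        raise ValueError(f"participants without a group label: {sorted(unknown)[:5]}")
    df["group"] = df["participant_id"].astype(str).map({str(k): v for k, v in groups.items()})

    records = []
    flag_cols = [
        "neglect_side_effects", "neglect_benefits",
        "neglect_mild", "neglect_severe", "neglect_extreme",
    ]
    for group, sub in df.groupby("group"):
        rec: dict[str, float | str] = {"group": str(group), "n_trials": len(sub)}
        for level in ("full", "partial", "none"):
            rec[f"prop_{level}"] = float((sub["ignorance_level"] == level).mean())
        for col in flag_cols:
            rec[f"prop_{col}"] = float(sub[col].mean())
            by_participant = sub.groupby("participant_id")[col].any()
            rec[f"prop_participants_{col}"] = float(by_participant.mean())
        records.append(rec)
    return pd.DataFrame(records).set_index("group")


def process_events(
    events_df: pd.DataFrame,
    trials_df: pd.DataFrame,
    table: EvidenceTable,
    out_summaries: str | Path | None = None,
    out_descriptives: str | Path | None = None,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """End-to-end preprocessing of an events table (columns participant_id,
    trial_index, vaccine, box_id, onset_ms, duration_ms).  ``trials_df``
    enumerates every participant x trial x vaccine (typically the decisions
    table) so that trials with no retained events are still summarized, as
    full ignorance.  Optionally writes the per-trial summaries CSV and, when
    ``groups`` is given, the group-level descriptives JSON."""
    events = [
        InspectionEvent(
            participant_id=str(r.participant_id),
            trial_index=int(r.trial_index),
            vaccine=str(r.vaccine),
            box_id=str(r.box_id),
            onset_ms=int(r.onset_ms),
            duration_ms=int(r.duration_ms),
        )
        for r in events_df.itertuples(index=False)
    ]
    trial_vaccines = {
        (str(r.participant_id), int(r.trial_index)): str(r.vaccine)
        for r in trials_df.itertuples(index=False)
    }
    log = filter_incidental(events)
    frame = summaries_to_frame(summarize_trials(log, table, trial_vaccines))
    if out_summaries is not None:
        frame.to_csv(out_summaries, index=False)
    if groups is not None and out_descriptives is not None:
        desc = summarize_ignorance(frame, groups)
        Path(out_descriptives).write_text(
            json.dumps(desc.reset_index().to_dict(orient="records"), indent=2)
        )
    return frame
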