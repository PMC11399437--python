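"""Synthetic study cohorts with known ground truth.

Generates complete datasets in the shape of the vaccination study —
participants in three attitude groups (anti / neutral / pro), signed affect
ratings for all 18 outcomes, Mouselab hover-event logs, and binary
accept/refuse decisions — by sampling forward through the hierarchical
prospect-theory model.  Every decision is drawn from the exact acceptance
probability implied by the stored individual parameters and the planted
(post-filter) inspection pattern, so preprocessing and model fitting can be
validated against known truth.

The decision model says nothing about WHY information is ignored; the
``InspectionPolicy`` is therefore a purely descriptive construct whose
default rates are calibrated to the study's observed behavior (full
deliberate ignorance in 18/9/7% of trials for anti/neutral/pro, side-effect
probability neglect in roughly 15/13/9% of trials).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import ptmodel
from .evidence import (
    MISSING,
    EvidenceTable,
    VaccineSpec,
    evidence_layout,
    load_evidence_table,
    normalize_label,
)
from .inspection import MIN_DELIBERATE_MS
from .ptmodel import (
    GroupParameters,
    IndividualParameters,
    TrialInput,
    TrialOutcome,
    acceptance_probability,
    contrast_matrix,
    subjective_valuation,
    transform_individual_parameters,
)

__all__ = [
    "InspectionPolicy",
    "RatingConfig",
    "AttitudeGroup",
    "CohortConfig",
    "AffectRatings",
    "ParticipantProfile",
    "DecisionRecord",
    "CohortBundle",
    "default_group_parameters",
    "default_inspection_policy",
    "default_rating_config",
    "default_cohort_config",
    "sample_participants",
    "sample_affect_ratings",
    "sample_trial",
    "generate_cohort",
]

ATTITUDES = ("anti", "neutral", "pro")
#: attitude-group sizes in the study sample
STUDY_GROUP_SIZES = {"anti": 365, "neutral": 373, "pro": 462}

_SLOTS = ("se1", "se2", "se3", "b1", "b2", "b3")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InspectionPolicy:
    """Descriptive generator of per-trial inspection patterns.

    ``p_full_ignorance`` / ``p_no_ignorance``: probability a trial inspects
    nothing / everything.  In the remaining (partial) trials each outcome
    box is opened with probability ``p_outcome_inspect``; an opened
    outcome's probability box is then *skipped* with the category's neglect
    rate.  Incidental (<200 ms) hovers are injected per box at
    ``incidental_event_rate`` and carry no information.
    """

    p_full_ignorance: float
    p_no_ignorance: float
    p_neglect: dict[str, float]  # keys: mild, severe, extreme, benefit
    p_outcome_inspect: float = 0.75
    p_prob_only: float = 0.05  # probability box opened without its outcome
    incidental_event_rate: float = 0.05
    duration_median_ms: float = 800.0
    duration_sigma: float = 0.5

    def __post_init__(self) -> None:
        fractions = [
            self.p_full_ignorance, self.p_no_ignorance, self.p_outcome_inspect,
            self.p_prob_only, self.incidental_event_rate, *self.p_neglect.values(),
        ]
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("all policy rates must lie in [0, 1]")
        if self.p_full_ignorance + self.p_no_ignorance > 1.0:
            raise ValueError("p_full_ignorance + p_no_ignorance must not exceed 1")
        if set(self.p_neglect) != {"mild", "severe", "extreme", "benefit"}:
            raise ValueError("p_neglect needs keys mild/severe/extreme/benefit")


@dataclass(frozen=True)
class RatingConfig:
    """Ordinal distributions of affect ratings.

    ``side_effect_probs[(attitude, severity)]`` are probabilities over the
    rating values (-1, -2, -3, -4, -5); ``benefit_probs[attitude]`` over
    (1, 2, 3, 4, 5).
    """

    side_effect_probs: dict[tuple[str, str], tuple[float, ...]]
    benefit_probs: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for key, probs in {
            **self.side_effect_probs,
            **self.benefit_probs,
        }.items():
            if len(probs) != 5 or any(p < 0 for p in probs):
                raise ValueError(f"{key!r}: need 5 nonnegative probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{key!r}: probabilities must sum to 1")


@dataclass
class AttitudeGroup:
    name: str
    group_params: GroupParameters
    inspection_policy: InspectionPolicy
    n_participants: int

    def __post_init__(self) -> None:
        if self.name not in ATTITUDES:
            raise ValueError(f"attitude must be one of {ATTITUDES}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")


@dataclass
class CohortConfig:
    groups: list[AttitudeGroup]
    rating_config: RatingConfig
    table: EvidenceTable


def default_group_parameters(attitude: str) -> GroupParameters:
    """Plausible generating parameters per attitude group: a strong refusal
    bias and low probability sensitivity for the anti group, the most linear
    weighting in the neutral group, an acceptance bias in the pro group;
    loss aversion (Lambda = lambda/(1-lambda) of roughly 2.3-4) everywhere."""
    from scipy.special import ndtri

    presets = {
        # beta, lambda, gamma
        "anti": (-2.5, 0.70, 0.30),
        "neutral": (-0.6, 0.80, 0.60),
        "pro": (1.5, 0.80, 0.50),
    }
    beta, lam, gam = presets[attitude]
    return GroupParameters(
        beta=beta,
        beta_j=np.array([0.25, -0.35, 0.20, -0.10]),
        lambda_probit=float(ndtri(lam)),
        gamma_probit=float(ndtri(gam)),
        alpha_raw=0.0,  # alpha = 1: linear use of the rating scale
        phi_probit=float(ndtri(0.3)),  # phi = 0.3
        sigma=np.array([1.5, 0.4, 0.4]),
        correlation=np.eye(3),
    )


def default_inspection_policy(attitude: str) -> InspectionPolicy:
    """Rates calibrated to the observed group-level descriptives."""
    presets = {
        "anti": dict(p_full=0.18, p_none=0.35, se=0.14, ben=0.08),
        "neutral": dict(p_full=0.09, p_none=0.45, se=0.12, ben=0.06),
        "pro": dict(p_full=0.07, p_none=0.50, se=0.09, ben=0.04),
    }
    p = presets[attitude]
    return InspectionPolicy(
        p_full_ignorance=p["p_full"],
        p_no_ignorance=p["p_none"],
        p_neglect={
            "mild": p["se"], "severe": p["se"], "extreme": p["se"],
            "benefit": p["ben"],
        },
    )


def default_rating_config() -> RatingConfig:
    """Ordinal rating distributions reproducing the qualitative pattern of
    the study: extreme side effects rated most negative, mild least; the
    anti group most negative about side effects and least positive about
    benefits, the pro group the reverse."""
    base_se = {
        "mild": np.array([0.35, 0.35, 0.20, 0.07, 0.03]),
        "severe": np.array([0.08, 0.20, 0.34, 0.25, 0.13]),
        "extreme": np.array([0.02, 0.06, 0.17, 0.30, 0.45]),
    }
    tilt = {"anti": 0.25, "neutral": 0.0, "pro": -0.25}
    se_probs = {}
    for att in ATTITUDES:
        weights = np.exp(tilt[att] * np.arange(5))
        for sev, base in base_se.items():
            p = base * weights
            p = p / p.sum()
            se_probs[(att, sev)] = tuple(float(x) for x in p)
    benefit_probs = {
        "anti": (0.30, 0.30, 0.20, 0.12, 0.08),
        "neutral": (0.10, 0.20, 0.30, 0.25, 0.15),
        "pro": (0.03, 0.07, 0.20, 0.30, 0.40),
    }
    return RatingConfig(side_effect_probs=se_probs, benefit_probs=benefit_probs)


def default_cohort_config(
    sizes: dict[str, int] | None = None, table: EvidenceTable | None = None
) -> CohortConfig:
    sizes = dict(STUDY_GROUP_SIZES if sizes is None else sizes)
    table = table if table is not None else load_evidence_table()
    groups = [
        AttitudeGroup(
            name=att,
            group_params=default_group_parameters(att),
            inspection_policy=default_inspection_policy(att),
            n_participants=sizes[att],
        )
        for att in ATTITUDES
        if sizes.get(att, 0) > 0
    ]
    return CohortConfig(groups=groups, rating_config=default_rating_config(), table=table)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class AffectRatings:
    """Signed Likert valuations: -5..-1 per side effect, 1..5 per benefit."""

    side_effect_ratings: dict[str, int]
    benefit_ratings: dict[str, int]

    def __post_init__(self) -> None:
        if any(not -5 <= r <= -1 for r in self.side_effect_ratings.values()):
            raise ValueError("side-effect ratings must lie in -5..-1")
        if any(not 1 <= r <= 5 for r in self.benefit_ratings.values()):
            raise ValueError("benefit ratings must lie in 1..5")

    def rating_of(self, label: str) -> int:
        key = normalize_label(label)
        for ratings in (self.side_effect_ratings, self.benefit_ratings):
            if key in ratings:
                return ratings[key]
        raise KeyError(f"no rating for outcome {label!r}")


@dataclass
class ParticipantProfile:
    participant_id: str
    attitude: str
    true_beta_i: float
    true_lambda_i: float
    true_gamma_i: float
    affect_ratings: AffectRatings | None = None

    @property
    def individual(self) -> IndividualParameters:
        return IndividualParameters(
            beta_i=self.true_beta_i,
            lambda_i=self.true_lambda_i,
            gamma_i=self.true_gamma_i,
        )


@dataclass(frozen=True)
class DecisionRecord:
    participant_id: str
    trial_index: int
    vaccine: str
    decision: str  # "accept" | "refuse"
    p_accept: float  # generating probability, kept for consistency checks


def sample_participants(
    group: AttitudeGroup, seed: int | np.random.Generator
) -> list[ParticipantProfile]:
    """Draw individual parameters: displacements zeta_i ~ MVN(0, Sigma),
    beta_i = beta + zeta_b, lambda_i = Phi(lambda_probit + zeta_l),
    gamma_i = Phi(gamma_probit + zeta_g)."""
    from scipy.special import ndtr

    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    gp = group.group_params
    Sigma = gp.covariance
    try:
        chol = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        raise ValueError("displacement covariance is not positive-definite") from None
    zetas = rng.standard_normal((group.n_participants, 3)) @ chol.T
    out = []
    for i in range(group.n_participants):
        ind = transform_individual_parameters(gp, zetas[i])
        out.append(
            ParticipantProfile(
                participant_id=f"{group.name}-{i:04d}",
                attitude=group.name,
                true_beta_i=ind.beta_i,
                true_lambda_i=ind.lambda_i,
                true_gamma_i=ind.gamma_i,
            )
        )
    return out


def sample_affect_ratings(
    attitude: str,
    rating_config: RatingConfig,
    seed: int | np.random.Generator,
    table: EvidenceTable | None = None,
) -> AffectRatings:
    """Draw one participant's complete rating set (all 15 side effects and
    3 benefits), independently per outcome given attitude x severity."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    table = table if table is not None else load_evidence_table()
    se_ratings: dict[str, int] = {}
    for label in table.side_effect_labels():
        sev = table.severity_map[label]
        probs = rating_config.side_effect_probs[(attitude, sev)]
        level = int(rng.choice(5, p=probs))
        se_ratings[label] = -(level + 1)
    benefit_labels = [normalize_label(o.label) for o in table.vaccines[0].benefits]
    b_probs = rating_config.benefit_probs[attitude]
    b_ratings = {
        label: int(rng.choice(5, p=b_probs)) + 1 for label in benefit_labels
    }
    return AffectRatings(side_effect_ratings=se_ratings, benefit_ratings=b_ratings)


def _sample_inspection_pattern(
    vaccine: VaccineSpec,
    policy: InspectionPolicy,
    severity_map: dict[str, str],
    rng: np.random.Generator,
) -> tuple[set[str], set[str]]:
    """(inspected outcome slots, inspected probability slots)."""
    layout = evidence_layout(vaccine)
    prob_slots = {b.slot for b in layout if b.part == "prob"}
    u = rng.random()
    if u < policy.p_full_ignorance:
        return set(), set()
    if u < policy.p_full_ignorance + policy.p_no_ignorance:
        return set(_SLOTS), set(prob_slots)

    outcomes = vaccine.outcomes
    categories = [
        severity_map[normalize_label(o.label)] if o.kind == "side_effect" else "benefit"
        for o in outcomes
    ]
    insp: set[str] = set()
    probs: set[str] = set()
    for k, slot in enumerate(_SLOTS):
        if rng.random() < policy.p_outcome_inspect:
            insp.add(slot)
            if slot in prob_slots and rng.random() >= policy.p_neglect[categories[k]]:
                probs.add(slot)
        elif slot in prob_slots and rng.random() < policy.p_prob_only:
            probs.add(slot)
    if not insp and not probs:  # force a genuinely partial trial
        insp.add(_SLOTS[int(rng.integers(6))])
    elif insp == set(_SLOTS) and probs == prob_slots:
        drop = _SLOTS[int(rng.integers(6))]
        insp.discard(drop)
        probs.discard(drop)
    return insp, probs


def _trial_input(
    vaccine: VaccineSpec,
    ratings: AffectRatings,
    inspected: set[str],
    prob_inspected: set[str],
    x_row: np.ndarray,
) -> TrialInput:
    outcomes = []
    for slot, o in zip(_SLOTS, vaccine.outcomes):
        ignored = slot not in inspected
        has_prob = o.probability is not MISSING
        outcomes.append(
            TrialOutcome(
                rating=ratings.rating_of(o.label),
                probability=o.probability,
                kind=o.kind,
                outcome_ignored=ignored,
                probability_neglected=(
                    not ignored and has_prob and slot not in prob_inspected
                ),
            )
        )
    return TrialInput(outcomes=tuple(outcomes), x_row=x_row)


def sample_trial(
    profile: ParticipantProfile,
    vaccine: VaccineSpec,
    policy: InspectionPolicy,
    group_params: GroupParameters,
    seed: int | np.random.Generator,
    trial_index: int = 1,
    x_row: np.ndarray | None = None,
    severity_map: dict[str, str] | None = None,
) -> tuple[list[dict], DecisionRecord]:
    """Sample one trial: an inspection pattern, its hover events (deliberate
    events of >= 200 ms plus incidental sub-200 ms hovers), and a decision
    drawn from the acceptance probability implied by the post-filter
    pattern.  Events are returned as dict rows for the events table."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if severity_map is None:
        severity_map = {
            normalize_label(o.label): o.severity
            for o in vaccine.side_effects
        }
    if x_row is None:
        x_row = np.zeros(4)
    inspected, prob_inspected = _sample_inspection_pattern(
        vaccine, policy, severity_map, rng
    )

    layout = evidence_layout(vaccine)
    events: list[dict] = []
    t = 0
    for box in layout:
        opened = (
            box.slot in inspected
            if box.part == "outcome"
            else box.slot in prob_inspected
        )
        if opened:
            n_views = 1 + int(rng.poisson(0.3))
            for _ in range(n_views):
                dur = int(
                    max(
                        MIN_DELIBERATE_MS,
                        round(
                            policy.duration_median_ms
                            * math.exp(policy.duration_sigma * rng.standard_normal())
                        ),
                    )
                )
                events.append(
                    {
                        "participant_id": profile.participant_id,
                        "trial_index": trial_index,
                        "vaccine": vaccine.brand,
                        "box_id": box.box_id,
                        "onset_ms": t,
                        "duration_ms": dur,
                    }
                )
                t += dur + int(rng.integers(50, 400))
        if rng.random() < policy.incidental_event_rate:
            dur = int(rng.integers(50, MIN_DELIBERATE_MS))
            events.append(
                {
                    "participant_id": profile.participant_id,
                    "trial_index": trial_index,
                    "vaccine": vaccine.brand,
                    "box_id": box.box_id,
                    "onset_ms": t,
                    "duration_ms": dur,
                }
            )
            t += dur + int(rng.integers(50, 400))

    trial = _trial_input(
        vaccine, profile.affect_ratings, inspected, prob_inspected, x_row
    )
    V = subjective_valuation(trial, profile.individual, group_params.alpha)
    p_accept = acceptance_probability(
        profile.individual, x_row, group_params.beta_j, group_params.phi, V
    )
    decision = "accept" if rng.random() < p_accept else "refuse"
    record = DecisionRecord(
        participant_id=profile.participant_id,
        trial_index=trial_index,
        vaccine=vaccine.brand,
        decision=decision,
        p_accept=p_accept,
    )
    return events, record


# ---------------------------------------------------------------------------
# full-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    participants: pd.DataFrame
    ratings: pd.DataFrame
    events: pd.DataFrame
    decisions: pd.DataFrame
    truth: dict


def generate_cohort(
    config: CohortConfig, seed: int, out_dir: str | Path | None = None
) -> CohortBundle:
    """Generate the full synthetic study dataset (deterministic given
    ``seed``).  With ``out_dir``, writes participants.csv, ratings.csv,
    events.csv, decisions.csv and truth.json."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0_1102]))
    table = config.table
    X = contrast_matrix(table)
    part_rows, rating_rows, event_rows, decision_rows = [], [], [], []
    truth: dict = {"seed": seed, "groups": {}}

    for group in config.groups:
        profiles = sample_participants(group, rng)
        gp = group.group_params
        truth["groups"][group.name] = {
            "beta": gp.beta,
            "beta_j": gp.beta_j.tolist(),
            "lambda_probit": gp.lambda_probit,
            "gamma_probit": gp.gamma_probit,
            "lambda": float(ndtr(gp.lambda_probit)),
            "gamma": float(ndtr(gp.gamma_probit)),
            "alpha": gp.alpha,
            "phi": gp.phi,
            "sigma": gp.sigma.tolist(),
            "correlation": gp.correlation.tolist(),
            "participants": {},
        }
        for profile in profiles:
            profile.affect_ratings = sample_affect_ratings(
                group.name, config.rating_config, rng, table
            )
            part_rows.append(
                {"participant_id": profile.participant_id, "attitude": group.name}
            )
            for label, r in profile.affect_ratings.side_effect_ratings.items():
                rating_rows.append(
                    {
                        "participant_id": profile.participant_id,
                        "outcome_label": label,
                        "rating": r,
                    }
                )
            for label, r in profile.affect_ratings.benefit_ratings.items():
                rating_rows.append(
                    {
                        "participant_id": profile.participant_id,
                        "outcome_label": label,
                        "rating": r,
                    }
                )
            truth["groups"][group.name]["participants"][profile.participant_id] = {
                "beta_i": profile.true_beta_i,
                "lambda_i": profile.true_lambda_i,
                "gamma_i": profile.true_gamma_i,
            }
            for j, vaccine in enumerate(table.vaccines):
                events, record = sample_trial(
                    profile,
                    vaccine,
                    group.inspection_policy,
                    gp,
                    rng,
                    trial_index=j + 1,
                    x_row=X[j],
                    severity_map=dict(table.severity_map),
                )
                event_rows.extend(events)
                decision_rows.append(
                    {
                        "participant_id": record.participant_id,
                        "trial_index": record.trial_index,
                        "vaccine": record.vaccine,
                        "decision": record.decision,
                        "p_accept": record.p_accept,
                    }
                )

    bundle = CohortBundle(
        participants=pd.DataFrame(part_rows),
        ratings=pd.DataFrame(rating_rows),
        events=pd.DataFrame(
            event_rows,
            columns=[
                "participant_id", "trial_index", "vaccine",
                "box_id", "onset_ms", "duration_ms",
            ],
        ),
        decisions=pd.DataFrame(decision_rows),
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.participants.to_csv(out / "participants.csv", index=False)
        bundle.ratings.to_csv(out / "ratings.csv", index=False)
        bundle.events.to_csv(out / "events.csv", index=False)
        bundle.decisions.to_csv(out / "decisions.csv", index=False)
        (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    return bundle
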