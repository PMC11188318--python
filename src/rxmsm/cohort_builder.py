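"""Inception-cohort construction from raw dispensing streams.

Each patient's index date is their first-ever dispensing of one of the five
antihypertensive monotherapy classes; eligibility applies the new-user,
monotherapy-only ledger of rules (age, registration history, minimum class
prescriptions, lipid co-therapy, multiple monotherapies, fixed-dose
combinations, prior/early acute cardiac drug therapy, chronic exclusion
therapies).  Every rule is evaluated for every indexed patient -- no
short-circuiting -- so the decision carries the complete ordered list of
reason codes and a flowchart-style attrition table can be derived.

Cohort 2 holds all eligible patients regardless of adherence; cohort 1 is the
subset with whole-follow-up adherence >= 80% and follow-up > 365 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prescription_store import CodeCatalog, PrescriptionDatabase, age_at
from .episode_engine import EpisodeRules, FollowUpSummary, summarize_followup

__all__ = [
    "EligibilityRules",
    "EligibilityDecision",
    "find_index_date",
    "check_eligibility",
    "build_cohorts",
    "CohortResult",
    "REASON_ORDER",
]

#: Canonical rule order; attrition attributes each excluded patient to their
#: first failing rule in this order.
REASON_ORDER = [
    "AGE",
    "PRE_HISTORY",
    "POST_HISTORY",
    "MIN_PRESCRIPTIONS",
    "LIPID_CO_RX",
    "MULTI_CLASS",
    "FIXED_COMBO",
    "PRIOR_CDT",
    "EARLY_CDT",
    "CHRONIC_EXCLUSION",  # expands to CHRONIC_EXCLUSION:<name>
    "LOW_ADHERENCE",
    "SHORT_FOLLOWUP",
]


@dataclass
class EligibilityRules:
    """Named thresholds for every inclusion/exclusion rule.

    age_min: minimum age (completed years) at the index date.
    pre_history_days: the earliest dispensing of any kind must precede the
        index date by at least this many days (registration proxy).
    post_history_days: at least one dispensing of any kind must occur after
        index + this many days.
    min_rx: minimum dispensings of the index class in the first post-index year.
    first_year_days: length of the "first year" window.
    multi_class_limit: exclude when more than this many monotherapy classes
        each reach ``min_rx`` dispensings in the first year.
    lipid_window: (lo, hi) day offsets around the index date in which any
        antihyperlipidemic dispensing excludes; default is the year starting
        at the index date.
    fixed_combo_min_rx: fixed-dose combination dispensings in the first year
        needed to exclude.
    lookback_cdt_days / blanking_cdt_days: windows before/after the index
        date in which any outcome-proxy dispensing excludes.
    chronic_min_rx / chronic_lookback_days / chronic_blanking_days: chronic
        exclusion-therapy rule.
    adherence_threshold / min_followup_days: cohort-1 membership.
    """

    age_min: int = 18
    pre_history_days: int = 730
    post_history_days: int = 365
    min_rx: int = 3
    first_year_days: int = 365
    multi_class_limit: int = 2
    lipid_window: tuple[int, int] = (0, 365)
    fixed_combo_min_rx: int = 2
    lookback_cdt_days: int = 730
    blanking_cdt_days: int = 90
    chronic_min_rx: int = 2
    chronic_lookback_days: int = 730
    chronic_blanking_days: int = 90
    adherence_threshold: float = 0.80
    min_followup_days: int = 365


@dataclass
class EligibilityDecision:
    patient_id: str
    index_day: int | None
    exposure_class: str | None
    eligible_cohort2: bool = False
    eligible_cohort1: bool = False
    reason_codes: list[str] = field(default_factory=list)


def find_index_date(records: pd.DataFrame, catalog: CodeCatalog):
    """Earliest dispensing mapping to one of the five exposure classes.

    Returns ``(index_day, exposure_class)`` or ``None``.  ``records`` must be
    sorted by day.
    """
    days = records["day"].to_numpy()
    if len(days) > 1 and (np.diff(days) < 0).any():
        raise ValueError("records must be sorted by dispense date")
    roles = catalog.role_series(records["atc_code"])
    mask = roles.str.startswith("exposure:").to_numpy()
    if not mask.any():
        return None
    i = int(np.flatnonzero(mask)[0])
    return int(days[i]), roles.iloc[i].split(":", 1)[1]


def check_eligibility(
    patient: pd.Series,
    records: pd.DataFrame,
    catalog: CodeCatalog,
    rules: EligibilityRules = EligibilityRules(),
) -> EligibilityDecision:
    """Evaluate every inclusion/exclusion rule for one indexed patient.

    The adherence/follow-up codes of cohort 1 are not assessed here (they
    need the episode engine); ``eligible_cohort2`` reflects the raw-record
    rules only.
    """
    found = find_index_date(records, catalog)
    decision = EligibilityDecision(patient_id=str(patient["patient_id"]),
                                   index_day=None, exposure_class=None)
    if found is None:
        return decision
    index_day, exposure_class = found
    decision.index_day = index_day
    decision.exposure_class = exposure_class

    days = records["day"].to_numpy() - index_day
    roles = catalog.role_series(records["atc_code"]).to_numpy()
    reasons: list[str] = []

    if age_at(int(patient["birth_day"]), index_day) < rules.age_min:
        reasons.append("AGE")
    if len(days) == 0 or days.min() > -rules.pre_history_days:
        reasons.append("PRE_HISTORY")
    if not (days > rules.post_history_days).any():
        reasons.append("POST_HISTORY")

    first_year = (days >= 0) & (days < rules.first_year_days)
    n_index_class = int(
        ((roles == f"exposure:{exposure_class}") & first_year).sum()
    )
    if n_index_class < rules.min_rx:
        reasons.append("MIN_PRESCRIPTIONS")

    lo, hi = rules.lipid_window
    lipid = (roles == "antihyperlipidemic") & (days >= lo) & (days <= hi)
    if lipid.any():
        reasons.append("LIPID_CO_RX")

    exposure_roles = pd.Series(roles)[first_year]
    class_counts = exposure_roles[exposure_roles.str.startswith("exposure:")].value_counts()
    qualifying = int((class_counts >= rules.min_rx).sum())
    if qualifying > rules.multi_class_limit:
        reasons.append("MULTI_CLASS")

    fixed = (roles == "fixed_combination") & first_year
    if int(fixed.sum()) >= rules.fixed_combo_min_rx:
        reasons.append("FIXED_COMBO")

    outcome = roles == "outcome"
    if (outcome & (days >= -rules.lookback_cdt_days) & (days < 0)).any():
        reasons.append("PRIOR_CDT")
    if (outcome & (days >= 0) & (days <= rules.blanking_cdt_days)).any():
        reasons.append("EARLY_CDT")

    for name in catalog.exclusion_therapy_prefixes:
        hits = (
            (roles == f"exclusion_therapy:{name}")
            & (days >= -rules.chronic_lookback_days)
            & (days <= rules.chronic_blanking_days)
        )
        if int(hits.sum()) >= rules.chronic_min_rx:
            reasons.append(f"CHRONIC_EXCLUSION:{name}")

    decision.reason_codes = reasons
    decision.eligible_cohort2 = not reasons
    return decision


@dataclass
class CohortResult:
    decisions: list[EligibilityDecision]
    cohort1: pd.DataFrame
    cohort2: pd.DataFrame
    attrition: pd.DataFrame
    summaries: dict[str, FollowUpSummary]


def _attrition_key(code: str) -> int:
    base = code.split(":", 1)[0]
    return REASON_ORDER.index(base)


def build_cohorts(
    db: PrescriptionDatabase,
    catalog: CodeCatalog,
    rules: EligibilityRules = EligibilityRules(),
    episode_rules: EpisodeRules = EpisodeRules(),
    admin_end_day: int | None = None,
) -> CohortResult:
    """Apply the full eligibility ledger and split cohorts 1 and 2.

    Returns member tables (patient_id, index_day, exposure_class,
    followup_days, adherence_total, event, ...), the attrition table (one row
    per reason in rule order), and the follow-up summaries for downstream
    person-period construction.
    """
    if admin_end_day is None:
        admin_end_day = int(db.records["day"].max()) if len(db.records) else 0
    decisions: list[EligibilityDecision] = []
    members2 = []
    summaries: dict[str, FollowUpSummary] = {}
    grouped = dict(tuple(db.records.groupby("patient_id", sort=False)))
    for patient in db.patients.sort_values("patient_id").itertuples(index=False):
        pid = patient.patient_id
        recs = grouped.get(pid)
        if recs is None or recs.empty:
            continue
        decision = check_eligibility(
            pd.Series(patient._asdict()), recs, catalog, rules
        )
        if decision.index_day is None:
            continue
        if decision.eligible_cohort2:
            summary = summarize_followup(
                pid, recs, catalog, decision.index_day, decision.exposure_class,
                admin_end_day, episode_rules,
            )
            if summary is None:
                decision.eligible_cohort2 = False
                decision.reason_codes.append("SHORT_FOLLOWUP")
            else:
                summaries[pid] = summary
                if summary.adherence_total < rules.adherence_threshold:
                    decision.reason_codes.append("LOW_ADHERENCE")
                if summary.followup_days <= rules.min_followup_days:
                    decision.reason_codes.append("SHORT_FOLLOWUP")
                decision.eligible_cohort1 = not decision.reason_codes
                members2.append(
                    {
                        "patient_id": pid,
                        "index_day": decision.index_day,
                        "exposure_class": decision.exposure_class,
                        "followup_days": summary.followup_days,
                        "adherence_total": summary.adherence_total,
                        "event": summary.event,
                        "event_day": summary.event_day,
                        "censor_reason": summary.censor_reason,
                        "had_switch": summary.had_switch,
                        "had_addon": summary.had_addon,
                        "eligible_cohort1": decision.eligible_cohort1,
                    }
                )
        decisions.append(decision)

    cohort2 = pd.DataFrame(
        members2,
        columns=[
            "patient_id", "index_day", "exposure_class", "followup_days",
            "adherence_total", "event", "event_day", "censor_reason",
            "had_switch", "had_addon", "eligible_cohort1",
        ],
    )
    cohort1 = cohort2[cohort2["eligible_cohort1"]].reset_index(drop=True)
    if cohort2.empty:
        warnings.warn("no eligible patients; cohorts are empty", stacklevel=2)

    # Attrition: each excluded patient counted once under their first failing
    # rule in canonical order; eligible patients appear in the cohorts.
    counts: dict[str, int] = {}
    for d in decisions:
        if d.eligible_cohort2:
            continue
        first = min(d.reason_codes, key=_attrition_key)
        counts[first] = counts.get(first, 0) + 1
    rows = []
    for code in sorted(counts, key=_attrition_key):
        rows.append({"reason": code, "n_excluded": counts[code]})
    attrition = pd.DataFrame(rows, columns=["reason", "n_excluded"])
    return CohortResult(
        decisions=decisions,
        cohort1=cohort1,
        cohort2=cohort2,
        attrition=attrition,
        summaries=summaries,
    )
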