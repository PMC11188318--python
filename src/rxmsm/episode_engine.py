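"""Per-protocol follow-up: 180-day person-periods, adherence, and censoring.

Each cohort member's dispensing stream is turned into counting-process rows.
Follow-up runs from the index date (day 0) to the earliest of: the acute
cardiac-drug-therapy (CDT) event, treatment discontinuation, an add-on of a
second antihypertensive class, the 3,780-day (10-year) horizon, or the
administrative end of the database.  Two adherence measures are computed as
proportions of days covered: one over the whole follow-up and one within each
180-day interval.

All supply intervals are half-open ``[dispense_day, dispense_day + days_covered)``
and all window arithmetic is half-open on integer day offsets, so no day is
ever counted twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prescription_store import CodeCatalog, age_at, year_of_day

__all__ = [
    "EpisodeRules",
    "FollowUpSummary",
    "coverage_union",
    "compute_adherence_total",
    "compute_adherence_180",
    "detect_discontinuation",
    "detect_switch",
    "detect_addon",
    "ascertain_outcome",
    "determine_followup_end",
    "build_person_periods",
    "build_person_period_table",
    "CENSOR_PRIORITY",
]

#: Censoring reasons in tie-break priority order (earliest wins; ties resolved
#: in this order so that outcome capture is favored over protocol censoring).
CENSOR_PRIORITY = ["CDT_EVENT", "ADDON", "DISCONTINUATION", "MAX_FOLLOWUP", "ADMIN_END"]


@dataclass
class EpisodeRules:
    """Thresholds governing follow-up construction.

    interval_days: person-period length (days).
    max_followup_days: hard horizon; 3,780 days = twenty-one 180-day intervals.
    gap_days: supply gap beyond which the exposure is considered discontinued.
    gap_from: 'coverage_end' measures the gap from the end of drug supply,
        'dispense_date' from the dispensing date itself.
    switch_window_days: window after discontinuation in which a new class
        counts as a switch (descriptive only; never censors).
    outcome_window_days / outcome_window_mode: two qualifying outcome
        dispensings within this many days of each other ('rolling', default)
        or within the same fixed interval of the person-period grid ('grid').
    terminal_denominator: 'actual' divides the final partial interval's
        covered days by its true length; 'fixed' divides by interval_days.
    """

    interval_days: int = 180
    max_followup_days: int = 3780
    gap_days: int = 180
    gap_from: str = "coverage_end"
    switch_window_days: int = 180
    outcome_window_days: int = 180
    outcome_window_mode: str = "rolling"
    outcome_min_rx: int = 2
    terminal_denominator: str = "actual"


@dataclass
class FollowUpSummary:
    """Per-patient follow-up endpoint and whole-follow-up adherence."""

    patient_id: str
    exposure_class: str
    index_day: int
    followup_days: int
    adherence_total: float
    event: bool
    event_day: int | None
    censor_reason: str
    had_switch: bool
    had_addon: bool


# ---------------------------------------------------------------------------
# Coverage / adherence
# ---------------------------------------------------------------------------


def coverage_union(days: np.ndarray, covered: np.ndarray, window: tuple[int, int]) -> int:
    """Days covered by the union of supply intervals within ``[a, b)``.

    Each dispensing contributes ``[day, day + days_covered)``; overlapping
    supply counts once (no stockpiling credit).
    """
    a, b = window
    if b <= a:
        raise ValueError("empty window")
    if len(days) == 0:
        return 0
    days = np.asarray(days)
    covered = np.asarray(covered)
    starts = np.clip(days, a, b)
    ends = np.clip(days + covered, a, b)
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    reach = a
    for s, e in zip(starts, ends):
        if e > reach:
            total += e - max(s, reach)
            reach = e
    return int(total)


def compute_adherence_total(days, covered, followup_days: int) -> float:
    """Proportion of follow-up days covered by exposure-class supply."""
    if followup_days <= 0:
        raise ValueError(f"followup_days must be >= 1, got {followup_days}")
    return coverage_union(np.asarray(days), np.asarray(covered), (0, followup_days)) / followup_days


def compute_adherence_180(days, covered, start_day: int, stop_day: int,
                          terminal_denominator: str = "actual",
                          interval_days: int = 180) -> float:
    """Proportion of one person-period's days covered by exposure supply."""
    n_covered = coverage_union(np.asarray(days), np.asarray(covered), (start_day, stop_day))
    denom = (stop_day - start_day) if terminal_denominator == "actual" else interval_days
    return n_covered / denom


# ---------------------------------------------------------------------------
# Discontinuation / switch / add-on / outcome
# ---------------------------------------------------------------------------


def detect_discontinuation(days, covered, admin_end_day: int,
                           gap_days: int = 180, gap_from: str = "coverage_end"):
    """First supply gap longer than ``gap_days`` in the same-class stream.

    Returns the discontinuation day (the running coverage end before the gap)
    or ``None``.  The final dispensing counts as a gap when the administrative
    end lies more than ``gap_days`` beyond it.
    """
    days = np.asarray(days)
    covered = np.asarray(covered)
    if len(days) == 0:
        return None
    order = np.argsort(days, kind="stable")
    days, covered = days[order], covered[order]
    reach = int(days[0] + covered[0])
    ref = reach if gap_from == "coverage_end" else int(days[0])
    for i in range(1, len(days)):
        if days[i] - ref > gap_days:
            return reach
        reach = max(reach, int(days[i] + covered[i]))
        ref = reach if gap_from == "coverage_end" else int(days[i])
    if admin_end_day - ref > gap_days:
        return reach
    return None


def detect_switch(other_class_days, discontinuation_day, switch_window_days: int = 180):
    """True iff a different-class (or fixed-combination) dispensing falls in
    ``(discontinuation_day, discontinuation_day + window]``.  Never censors."""
    if discontinuation_day is None:
        return None
    other_class_days = np.asarray(other_class_days)
    in_window = (other_class_days > discontinuation_day) & (
        other_class_days <= discontinuation_day + switch_window_days
    )
    return bool(in_window.any())


def detect_addon(other_class_days, discontinuation_day, followup_cap: int):
    """Earliest different-class antihypertensive dispensing before
    discontinuation (or before the follow-up cap when no discontinuation);
    triggers censoring."""
    limit = discontinuation_day if discontinuation_day is not None else followup_cap
    other_class_days = np.asarray(other_class_days)
    before = other_class_days[(other_class_days > 0) & (other_class_days < limit)]
    return int(before.min()) if len(before) else None


def ascertain_outcome(outcome_days, rules: EpisodeRules = EpisodeRules()):
    """Event day: first outcome dispensing with a second one within the window.

    With the default rolling window the pair must lie within
    ``outcome_window_days`` of each other (closed on the right, so a gap of
    exactly 180 days qualifies); in 'grid' mode both must fall inside the same
    fixed interval of the person-period grid.
    """
    outcome_days = np.sort(np.asarray(outcome_days))
    need = rules.outcome_min_rx
    if len(outcome_days) < need:
        return None
    if rules.outcome_window_mode == "rolling":
        for i in range(len(outcome_days) - need + 1):
            if outcome_days[i + need - 1] - outcome_days[i] <= rules.outcome_window_days:
                return int(outcome_days[i])
        return None
    if rules.outcome_window_mode == "grid":
        cells = outcome_days // rules.interval_days
        for cell in np.unique(cells):
            members = outcome_days[cells == cell]
            if len(members) >= need:
                return int(members.min())
        return None
    raise ValueError(f"unknown outcome_window_mode {rules.outcome_window_mode!r}")


# ---------------------------------------------------------------------------
# Follow-up end
# ---------------------------------------------------------------------------


def determine_followup_end(
    patient_id: str,
    exposure_class: str,
    index_day: int,
    class_days,
    class_covered,
    other_class_days,
    outcome_days,
    admin_end_day: int,
    rules: EpisodeRules = EpisodeRules(),
) -> FollowUpSummary | None:
    """Resolve the end of follow-up and its reason.

    All day arguments are offsets from the index date.  The end is the
    earliest of event day, add-on day, discontinuation day, the 10-year
    horizon, and the administrative end; ties resolve in
    :data:`CENSOR_PRIORITY` order (event > add-on > discontinuation).
    """
    admin_offset = admin_end_day - index_day
    disc = detect_discontinuation(
        class_days, class_covered, admin_offset, rules.gap_days, rules.gap_from
    )
    addon = detect_addon(other_class_days, disc, min(rules.max_followup_days, admin_offset))
    event_day = ascertain_outcome(outcome_days, rules)
    candidates: dict[str, int] = {
        "MAX_FOLLOWUP": rules.max_followup_days,
        "ADMIN_END": admin_offset,
    }
    if event_day is not None:
        candidates["CDT_EVENT"] = event_day
    if addon is not None:
        candidates["ADDON"] = addon
    if disc is not None:
        candidates["DISCONTINUATION"] = disc
    end = min(candidates.values())
    reason = next(r for r in CENSOR_PRIORITY if candidates.get(r) == end)
    if end <= 0:
        warnings.warn(
            f"patient {patient_id}: non-positive follow-up ({reason}); dropped",
            stacklevel=2,
        )
        return None
    event = reason == "CDT_EVENT"
    switch = detect_switch(other_class_days, disc, rules.switch_window_days)
    adherence = compute_adherence_total(class_days, class_covered, end)
    return FollowUpSummary(
        patient_id=patient_id,
        exposure_class=exposure_class,
        index_day=index_day,
        followup_days=int(end),
        adherence_total=float(adherence),
        event=bool(event),
        event_day=int(event_day) if event else None,
        censor_reason=reason,
        had_switch=bool(switch) if switch is not None else False,
        had_addon=addon is not None and addon <= end,
    )


# ---------------------------------------------------------------------------
# Person-periods
# ---------------------------------------------------------------------------


def build_person_periods(
    summary: FollowUpSummary,
    class_days,
    class_covered,
    comorbidity_days: dict[str, np.ndarray],
    rules: EpisodeRules = EpisodeRules(),
) -> pd.DataFrame:
    """Tile ``[0, followup_days)`` into 180-day rows.

    Each row carries the within-interval adherence, flags for dispensings of
    the diabetes / RA / asthma-COPD drug sets whose dispense date falls in the
    interval, and -- on the final row only -- the event indicator and censoring
    reason.
    """
    F = summary.followup_days
    L = rules.interval_days
    n_rows = int(np.ceil(F / L))
    class_days = np.asarray(class_days)
    class_covered = np.asarray(class_covered)
    rows = []
    for k in range(n_rows):
        a, b = k * L, min((k + 1) * L, F)
        adh = compute_adherence_180(
            class_days, class_covered, a, b, rules.terminal_denominator, L
        )
        row = {
            "patient_id": summary.patient_id,
            "k": k,
            "start_day": a,
            "stop_day": b,
            "exposure_class": summary.exposure_class,
            "adherence_180": adh,
        }
        for name, days in comorbidity_days.items():
            d = np.asarray(days)
            row[f"{name}_rx"] = bool(((d >= a) & (d < b)).any())
        last = k == n_rows - 1
        row["event"] = bool(summary.event and last)
        row["censor_reason"] = summary.censor_reason if last else "none"
        rows.append(row)
    return pd.DataFrame(rows)


def _patient_streams(records: pd.DataFrame, catalog: CodeCatalog, index_day: int,
                     exposure_class: str):
    """Split one patient's records (absolute days) into the streams the
    episode logic needs, re-expressed as offsets from the index date."""
    roles = catalog.role_series(records["atc_code"])
    rel = records["day"].to_numpy() - index_day
    covered = records["days_covered"].to_numpy()
    is_class = (roles == f"exposure:{exposure_class}").to_numpy()
    class_mask = is_class & (rel >= 0)
    other_ah = (
        roles.str.startswith("exposure").to_numpy() & ~is_class
    ) | (roles == "fixed_combination").to_numpy()
    outcome = (roles == "outcome").to_numpy() & (rel >= 0)
    comorb = {
        name: rel[(roles == f"comorbidity:{name}").to_numpy()]
        for name in catalog.comorbidity_prefixes
    }
    return {
        "class_days": rel[class_mask],
        "class_covered": covered[class_mask],
        "other_class_days": rel[other_ah],
        "outcome_days": rel[outcome],
        "comorbidity_days": comorb,
    }


def summarize_followup(
    patient_id: str,
    records: pd.DataFrame,
    catalog: CodeCatalog,
    index_day: int,
    exposure_class: str,
    admin_end_day: int,
    rules: EpisodeRules = EpisodeRules(),
) -> FollowUpSummary | None:
    """Follow-up summary for one patient from their raw record rows."""
    streams = _patient_streams(records, catalog, index_day, exposure_class)
    return determine_followup_end(
        patient_id,
        exposure_class,
        index_day,
        streams["class_days"],
        streams["class_covered"],
        streams["other_class_days"],
        streams["outcome_days"],
        admin_end_day,
        rules,
    )


def build_person_period_table(
    members: pd.DataFrame,
    db,
    catalog: CodeCatalog,
    rules: EpisodeRules = EpisodeRules(),
    summaries: dict[str, FollowUpSummary] | None = None,
) -> pd.DataFrame:
    """Person-period rows for every cohort member, joined with the baseline
    covariates the weight models use (sex, age at index, calendar period).

    ``members`` needs columns patient_id, index_day, exposure_class; the
    database supplies sex and birth date.  Pass precomputed ``summaries``
    (from cohort building) to avoid re-deriving follow-up ends.
    """
    admin_end_day = int(db.records["day"].max()) if len(db.records) else 0
    pat = db.patients.set_index("patient_id")
    grouped = dict(tuple(db.records.groupby("patient_id", sort=False)))
    frames = []
    for row in members.itertuples(index=False):
        pid = row.patient_id
        recs = grouped[pid]
        summary = summaries.get(pid) if summaries else None
        if summary is None:
            summary = summarize_followup(
                pid, recs, catalog, int(row.index_day), row.exposure_class,
                admin_end_day, rules,
            )
        if summary is None:
            continue
        streams = _patient_streams(recs, catalog, int(row.index_day), row.exposure_class)
        pp = build_person_periods(
            summary, streams["class_days"], streams["class_covered"],
            streams["comorbidity_days"], rules,
        )
        pp["sex"] = pat.loc[pid, "sex"]
        pp["age_at_index"] = age_at(int(pat.loc[pid, "birth_day"]), int(row.index_day))
        pp["index_year"] = year_of_day(int(row.index_day))
        frames.append(pp)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
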