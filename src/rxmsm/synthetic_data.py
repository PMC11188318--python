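"""Synthetic prescription databases with known, planted treatment effects.

The real pharmacy database behind this kind of analysis is not public, so the
whole pipeline is validated on data generated here.  The generator plants:

* confounding by indication -- the choice among the five antihypertensive
  monotherapy classes depends on sex, age, and baseline comorbidity drug use
  (diabetes / rheumatoid arthritis / asthma-COPD drugs);
* class-dependent event hazards -- each 180-day interval, the acute
  cardiac-drug-therapy (CDT) event fires from a complementary log-log hazard
  whose linear predictor is the planted log hazard ratio of the assigned class
  (vs beta-blockers) plus comorbidity-flag effects, so planted coefficients
  are log hazard ratios on the same time grid the estimators use;
* adherence gaps, permanent discontinuations, switches and add-ons, plus
  co-medication streams that trigger each exclusion rule, and outcome-drug
  dispensings emitted after events.

By default the event hazard depends *only* on the exposure class and the
comorbidity-drug flags: sex, age and calendar time influence prescribing but
not the outcome.  That makes the planted class effects exactly the marginal
hazard ratios the weighted analysis estimates, so parameter-recovery checks
are sharp.  Knobs exist to break this (see ``SimulationConfig``).

Two renderings share one latent draw:

* :func:`simulate_person_periods` -- the person-period table directly
  (full adherence, no protocol censoring): the estimator test bed.
* :func:`simulate_population` -- a full prescription database (background
  dispensings, refills, gaps, switches, add-ons, comorbidity and outcome
  streams) to exercise cohort building and episode construction end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prescription_store import (
    CLASS_LABELS,
    CodeCatalog,
    PrescriptionDatabase,
    from_day,
    to_day,
    validate_database,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_person_periods",
    "simulate_population",
    "make_eligibility_fixture",
    "CLASS_ATC",
]

#: One representative level-5 product code per monotherapy class.
CLASS_ATC = {
    "ACEI": "C09AA02",     # enalapril
    "ARB": "C09CA01",      # losartan
    "BB": "C07AB02",       # metoprolol
    "CCB": "C08CA01",      # amlodipine
    "THIAZIDE": "C03AA03", # hydrochlorothiazide
}

COMORBIDITY_ATC = {"diabetes": "A10BA02", "ra": "M01CB01", "asthma_copd": "R03AC02"}
COMORBIDITIES = ("diabetes", "ra", "asthma_copd")

_ASSIGN_COVS = ("sex_male", "age_std", "diabetes", "ra", "asthma_copd")

# Class-share intercepts reproduce realistic initiation shares
# (BB ~34%, ACEI ~25%, thiazide ~22%, ARB ~9%, CCB ~9%).
_DEFAULT_INTERCEPTS = {"BB": 0.0, "ACEI": -0.30, "ARB": -1.32, "CCB": -1.34, "THIAZIDE": -0.45}

# Confounding by indication: diabetics preferentially start ACEI/ARB,
# asthma/COPD patients avoid beta-blockers (positive shift for the other
# four classes), RA patients lean toward CCBs.  Odds ratios kept in the
# 1.5-2.5 range typical of prescribing-channel effects.
_DEFAULT_ASSIGNMENT = {
    "BB": dict.fromkeys(_ASSIGN_COVS, 0.0),
    "ACEI": {"sex_male": 0.55, "age_std": 0.05, "diabetes": 1.20, "ra": 0.20, "asthma_copd": 0.55},
    "ARB": {"sex_male": 0.40, "age_std": 0.05, "diabetes": 1.00, "ra": 0.20, "asthma_copd": 0.55},
    "CCB": {"sex_male": 0.25, "age_std": 0.30, "diabetes": 0.60, "ra": 0.70, "asthma_copd": 0.55},
    "THIAZIDE": {"sex_male": -0.10, "age_std": 0.45, "diabetes": 0.60, "ra": 0.20, "asthma_copd": 0.55},
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic database.

    Defaults emulate a Dutch community-pharmacy database over 1996-2020:
    90-day chronic refills, ~6%/1%/8% baseline prevalence of diabetes / RA /
    asthma-COPD drug use, realistic initiation shares, and planted hazard
    ratios vs beta-blockers of 1.00 (ACEI), 0.79 (ARB), 1.10 (CCB) and 0.80
    (thiazide).  ``baseline_interval_hazard`` of 0.009 per 180-day interval
    yields a cumulative event fraction near 6% over a typical follow-up,
    matching the scale of the motivating analysis.
    """

    n_patients: int = 1000
    seed: int = 0
    study_start: str = "1996-01-01"
    study_end: str = "2020-12-31"
    interval_days: int = 180
    max_intervals: int = 21          # 3,780-day horizon / 180
    refill_days_covered: int = 90

    male_fraction: float = 0.45
    age_mean: float = 58.0
    age_sd: float = 13.7

    class_intercepts: dict = field(default_factory=lambda: dict(_DEFAULT_INTERCEPTS))
    class_assignment_coefficients: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_ASSIGNMENT.items()}
    )

    baseline_prevalence: dict = field(
        default_factory=lambda: {"diabetes": 0.08, "ra": 0.012, "asthma_copd": 0.08}
    )
    comorbidity_onset_probability: dict = field(
        default_factory=lambda: {"diabetes": 0.004, "ra": 0.001, "asthma_copd": 0.005}
    )

    true_log_hr: dict = field(
        default_factory=lambda: {
            "BB": 0.0,
            "ACEI": 0.0,
            "ARB": float(np.log(0.79)),
            "CCB": float(np.log(1.10)),
            "THIAZIDE": float(np.log(0.80)),
        }
    )
    baseline_interval_hazard: float = 0.009
    confounder_hazard_coefficients: dict = field(
        default_factory=lambda: {
            "diabetes": float(np.log(2.5)),
            "ra": float(np.log(1.3)),
            "asthma_copd": float(np.log(1.5)),
        }
    )
    # Optional hazard effects of prescribing covariates; zero by default so the
    # planted class effects are exactly marginal (see module docstring).
    sex_hazard_coefficient: float = 0.0
    age_hazard_coefficient: float = 0.0
    # Optional effect modification: extra log HR for a class among males,
    # e.g. {"ARB": -0.9}; empty by default (no planted interaction).
    sex_interaction_log_hr: dict = field(default_factory=dict)

    gap_probability: float = 0.05          # per interval: a short refill gap
    gap_length_days: tuple = (30, 150)     # uniform; short of the 180-day rule
    discontinue_probability: float = 0.02  # per interval: refills stop for good
    switch_probability: float = 0.30       # given discontinuation
    addon_probability: float = 0.005       # per interval: second class added

    lipid_co_rx_probability: float = 0.02
    chronic_exclusion_probability: float = 0.01
    prior_cdt_probability: float = 0.01
    outcome_misclassification: float = 0.0  # P(event emits no outcome pair)

    def __post_init__(self):
        probs = [
            self.baseline_interval_hazard, self.gap_probability,
            self.discontinue_probability, self.switch_probability,
            self.addon_probability, self.lipid_co_rx_probability,
            self.chronic_exclusion_probability, self.prior_cdt_probability,
            self.outcome_misclassification, self.male_fraction,
            *self.baseline_prevalence.values(),
            *self.comorbidity_onset_probability.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.true_log_hr.get("BB", 0.0) != 0.0:
            raise ValueError("BB is the reference class: true_log_hr['BB'] must be 0")
        if to_day(self.study_end) <= to_day(self.study_start):
            raise ValueError("study_end must be after study_start")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "gap_length_days" in d:
            d["gap_length_days"] = tuple(d["gap_length_days"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth the estimation suite must recover."""

    true_log_hr: dict
    patients: pd.DataFrame  # per patient: class, covariates, latent event day
    flags: np.ndarray       # (n, K, 3) comorbidity-flag trajectory

    @property
    def true_hr(self) -> dict:
        return {c: float(np.exp(v)) for c, v in self.true_log_hr.items()}


# ---------------------------------------------------------------------------
# Latent mechanism
# ---------------------------------------------------------------------------


def _softmax_rows(lp: np.ndarray) -> np.ndarray:
    lp = lp - lp.max(axis=1, keepdims=True)
    e = np.exp(lp)
    return e / e.sum(axis=1, keepdims=True)


def _simulate_latent(config: SimulationConfig, rng: np.random.Generator) -> dict:
    n, K = config.n_patients, config.max_intervals
    sex_male = rng.random(n) < config.male_fraction
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)
    age_std = (age - config.age_mean) / config.age_sd
    lo = to_day(config.study_start) + 800
    hi = to_day(config.study_end) - 400
    index_day = rng.integers(lo, hi + 1, size=n)

    flags0 = np.column_stack(
        [rng.random(n) < config.baseline_prevalence[c] for c in COMORBIDITIES]
    )

    covs = {
        "sex_male": sex_male.astype(float),
        "age_std": age_std,
        "diabetes": flags0[:, 0].astype(float),
        "ra": flags0[:, 1].astype(float),
        "asthma_copd": flags0[:, 2].astype(float),
    }
    lp = np.zeros((n, len(CLASS_LABELS)))
    for j, cls in enumerate(CLASS_LABELS):
        lp[:, j] = config.class_intercepts.get(cls, 0.0)
        coefs = config.class_assignment_coefficients.get(cls, {})
        for name, beta in coefs.items():
            lp[:, j] += beta * covs[name]
    probs = _softmax_rows(lp)
    if probs.mean(axis=0).max() > 0.98:
        warnings.warn("degenerate class assignment: nearly all mass on one class",
                      stacklevel=3)
    u = rng.random(n)
    class_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    # interval loop: absorbing comorbidity-drug onset, cloglog event hazard
    flags = np.empty((n, K, 3), dtype=bool)
    cur = flags0.copy()
    onset = np.array([config.comorbidity_onset_probability[c] for c in COMORBIDITIES])
    beta = np.array([config.confounder_hazard_coefficients[c] for c in COMORBIDITIES])
    base = config.baseline_interval_hazard
    log_hr = np.array([config.true_log_hr.get(c, 0.0) for c in CLASS_LABELS])
    sex_ix = np.array(
        [config.sex_interaction_log_hr.get(c, 0.0) for c in CLASS_LABELS]
    )
    event_interval = np.full(n, -1)
    event_day = np.full(n, -1)
    alive = np.ones(n, dtype=bool)
    for k in range(K):
        if k > 0:
            cur = cur | (rng.random((n, 3)) < onset)
        flags[:, k, :] = cur
        eta = (
            log_hr[class_idx]
            + cur @ beta
            + config.sex_hazard_coefficient * covs["sex_male"]
            + config.age_hazard_coefficient * age_std
            + sex_ix[class_idx] * covs["sex_male"]
        )
        p_k = 1.0 - (1.0 - base) ** np.exp(eta)
        hit = alive & (rng.random(n) < p_k)
        within = rng.integers(0, config.interval_days, size=n)
        event_interval[hit] = k
        event_day[hit] = k * config.interval_days + within[hit]
        alive &= ~hit

    patients = pd.DataFrame(
        {
            "patient_id": [f"S{i:06d}" for i in range(n)],
            "sex": np.where(sex_male, "male", "female"),
            "age_at_index": age,
            "index_day": index_day,
            "exposure_class": [CLASS_LABELS[j] for j in class_idx],
            "diabetes0": flags0[:, 0],
            "ra0": flags0[:, 1],
            "asthma_copd0": flags0[:, 2],
            "event_interval": event_interval,
            "event_day": event_day,
        }
    )
    return {"patients": patients, "flags": flags, "class_idx": class_idx}


# ---------------------------------------------------------------------------
# Fast rendering: person-period table
# ---------------------------------------------------------------------------


def simulate_person_periods(config: SimulationConfig):
    """Person-period rows straight from the latent mechanism.

    Every patient contributes one row per 180-day interval until their event
    or the horizon; adherence is 1 and there is no protocol censoring, so
    estimates on this table isolate estimator behavior from episode plumbing.
    Returns ``(person_periods, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, rng)
    pats = latent["patients"]
    flags = latent["flags"]
    n, K, L = config.n_patients, config.max_intervals, config.interval_days

    ev_int = pats["event_interval"].to_numpy()
    ev_day = pats["event_day"].to_numpy()
    last = np.where(ev_int >= 0, ev_int, K - 1)
    blocks = []
    for k in range(K):
        m = last >= k
        if not m.any():
            break
        idx = np.flatnonzero(m)
        is_ev = ev_int[idx] == k
        stop = np.where(is_ev, np.maximum(ev_day[idx], k * L + 1), (k + 1) * L)
        blocks.append(
            pd.DataFrame(
                {
                    "patient_id": pats["patient_id"].to_numpy()[idx],
                    "k": k,
                    "start_day": k * L,
                    "stop_day": stop,
                    "exposure_class": pats["exposure_class"].to_numpy()[idx],
                    "adherence_180": 1.0,
                    "diabetes_rx": flags[idx, k, 0],
                    "ra_rx": flags[idx, k, 1],
                    "asthma_copd_rx": flags[idx, k, 2],
                    "event": is_ev,
                    "censor_reason": np.where(is_ev, "CDT_EVENT", "none"),
                    "sex": pats["sex"].to_numpy()[idx],
                    "age_at_index": pats["age_at_index"].to_numpy()[idx],
                    "index_year": [from_day(d).year for d in pats["index_day"].to_numpy()[idx]],
                }
            )
        )
    pp = pd.concat(blocks, ignore_index=True)
    pp = pp.sort_values(["patient_id", "k"], kind="mergesort").reset_index(drop=True)
    # censor_reason on the true last row of non-event patients
    last_rows = pp.groupby("patient_id")["k"].transform("max") == pp["k"]
    pp.loc[last_rows & ~pp["event"], "censor_reason"] = "MAX_FOLLOWUP"
    truth = SimulationTruth(
        true_log_hr=dict(config.true_log_hr), patients=pats, flags=flags
    )
    return pp, truth


# ---------------------------------------------------------------------------
# Full rendering: prescription database
# ---------------------------------------------------------------------------


def simulate_population(config: SimulationConfig):
    """Render the latent mechanism as a raw prescription database.

    Emits per patient: >2 years of pre-index background dispensings, index-class
    refills every ``refill_days_covered`` days with gap / permanent-stop /
    switch / add-on processes, comorbidity-drug streams following the flag
    trajectory, outcome-drug pairs after events, and (at the configured rates)
    the co-medication patterns that trigger exclusion rules.  Byte-identical
    for identical ``(seed, config)``.  Returns ``(database, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, rng)
    pats = latent["patients"]
    flags = latent["flags"]
    n, K, L = config.n_patients, config.max_intervals, config.interval_days
    refill = config.refill_days_covered
    per_refill_stop = config.discontinue_probability / max(1, L // refill)
    per_refill_gap = config.gap_probability / max(1, L // refill)
    admin_day = to_day(config.study_end)
    horizon = K * L

    other_classes = {c: [o for o in CLASS_LABELS if o != c] for c in CLASS_LABELS}
    rows_pid, rows_day, rows_atc, rows_cov = [], [], [], []

    def emit(pid, day, atc, covered):
        rows_pid.append(pid)
        rows_day.append(day)
        rows_atc.append(atc)
        rows_cov.append(covered)

    for i in range(n):
        pid = pats["patient_id"].iat[i]
        idx_day = int(pats["index_day"].iat[i])
        cls = pats["exposure_class"].iat[i]
        end_rel = min(horizon, admin_day - idx_day)

        # background co-medication guarantees registration history
        emit(pid, idx_day - 800, "N02BE01", 30)
        t = idx_day - 800 + 120
        while t < idx_day + end_rel + 150:
            if t <= admin_day:
                emit(pid, t, "N02BE01", 30)
            t += int(rng.integers(90, 150))

        # index-class refills with gaps and permanent stops
        t_rel, stopped, disc_rel = 0, False, None
        while t_rel < end_rel:
            emit(pid, idx_day + t_rel, CLASS_ATC[cls], refill)
            nxt = t_rel + refill
            if rng.random() < per_refill_stop:
                stopped, disc_rel = True, nxt
                break
            if rng.random() < per_refill_gap:
                nxt += int(rng.integers(*config.gap_length_days))
            t_rel = nxt
        if stopped and rng.random() < config.switch_probability:
            new_cls = other_classes[cls][int(rng.integers(0, 4))]
            s = disc_rel + int(rng.integers(10, 170))
            for r in range(3):
                d = idx_day + s + r * refill
                if d <= admin_day:
                    emit(pid, d, CLASS_ATC[new_cls], refill)

        # add-on: a second class while still on the index class
        on_until = disc_rel if disc_rel is not None else end_rel
        for k in range(min(K, int(np.ceil(on_until / L)))):
            if rng.random() < config.addon_probability:
                add_cls = other_classes[cls][int(rng.integers(0, 4))]
                s = k * L + int(rng.integers(5, L - 5))
                if s < on_until:
                    for r in range(3):
                        d = idx_day + s + r * refill
                        if d <= admin_day:
                            emit(pid, d, CLASS_ATC[add_cls], refill)
                break

        # comorbidity-drug streams follow the latent flag trajectory
        for ci, name in enumerate(COMORBIDITIES):
            col = flags[i, :, ci]
            if not col.any():
                continue
            first_k = int(np.flatnonzero(col)[0])
            start_rel = -400 if col[0] else first_k * L + int(rng.integers(0, 90))
            t = idx_day + start_rel
            while t < idx_day + min(end_rel, horizon):
                if t <= admin_day:
                    emit(pid, t, COMORBIDITY_ATC[name], 90)
                t += 90

        # outcome pair after the latent event
        ev = int(pats["event_day"].iat[i])
        if ev >= 0 and ev < end_rel and rng.random() >= config.outcome_misclassification:
            emit(pid, idx_day + ev, "B01AC06", 14)
            d2 = idx_day + ev + int(rng.integers(14, 90))
            if d2 <= admin_day:
                emit(pid, d2, "B01AC06", 14)

        # exclusion-triggering streams
        if rng.random() < config.lipid_co_rx_probability:
            emit(pid, idx_day + int(rng.integers(0, 300)), "C10AA05", 90)
        if rng.random() < config.chronic_exclusion_probability:
            s = idx_day - int(rng.integers(100, 600))
            emit(pid, s, "H03AA01", 90)
            emit(pid, s + 90, "H03AA01", 90)
        if rng.random() < config.prior_cdt_probability:
            emit(pid, idx_day - int(rng.integers(100, 700)), "B01AC06", 14)

    birth = [
        from_day(int(d) - int(round(a * 365.25)))
        for d, a in zip(pats["index_day"], pats["age_at_index"])
    ]
    patients_df = pd.DataFrame(
        {
            "patient_id": pats["patient_id"],
            "sex": pats["sex"],
            "birth_date": [b.isoformat() for b in birth],
        }
    )
    records_df = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "dispense_date": [from_day(d).isoformat() for d in rows_day],
            "atc_code": rows_atc,
            "days_covered": rows_cov,
        }
    )
    db = validate_database(patients_df, records_df)
    truth = SimulationTruth(
        true_log_hr=dict(config.true_log_hr), patients=pats, flags=flags
    )
    return db, truth


# ---------------------------------------------------------------------------
# Estimation bench conditions
# ---------------------------------------------------------------------------


def replication_config(seed: int, n_patients: int = 4000) -> SimulationConfig:
    """Conditions for the replicate-based parameter-recovery bench.

    Reduced sample (default 4,000 patients), a 6-interval (3-year) horizon,
    and a per-interval baseline event probability of 0.02 so each replicate
    carries roughly 500 events: enough for stable crude and weighted fits at
    this size.  Planted hazard ratios and confounding are the generator
    defaults.
    """
    return SimulationConfig(
        n_patients=n_patients, seed=seed, max_intervals=6,
        baseline_interval_hazard=0.02,
        # RA drug use is lifted from its population rate so every
        # class-by-flag cell stays populated at the reduced sample size
        # (the 5-class multinomial model needs non-empty cells)
        baseline_prevalence={"diabetes": 0.08, "ra": 0.03, "asthma_copd": 0.08},
    )


def calibration_config(seed: int, n_patients: int = 2000) -> SimulationConfig:
    """Conditions for null-calibration replicate suites (no planted
    interaction): 2,000 patients, 5 intervals, event probability 0.03 per
    interval (~250 events per replicate), comorbidity prevalences lifted so
    the propensity models always have populated cells."""
    return SimulationConfig(
        n_patients=n_patients, seed=seed, max_intervals=5,
        baseline_interval_hazard=0.03,
        baseline_prevalence={"diabetes": 0.10, "ra": 0.05, "asthma_copd": 0.10},
    )


def coverage_config(seed: int, n_patients: int = 20000) -> SimulationConfig:
    """Conditions for the single large-sample CI-coverage run.

    20,000 patients over a 9-interval (~4.4-year) horizon at the default
    event rate, mirroring the scale and cumulative event fraction of a
    community-pharmacy inception cohort.
    """
    return SimulationConfig(n_patients=n_patients, seed=seed, max_intervals=9)


# ---------------------------------------------------------------------------
# Hand-constructed eligibility fixture
# ---------------------------------------------------------------------------


def make_eligibility_fixture():
    """Tiny hand-built database exercising every inclusion/exclusion rule.

    Returns ``(database, expected, admin_end_day)`` where ``expected`` lists,
    per patient, the hand-derived eligibility decision, reason codes,
    follow-up length, censoring reason and event status.
    """
    idx = to_day("2005-06-01")
    admin_end_day = to_day("2020-12-31")
    patients, records, expected = [], [], []

    def add_patient(pid, birth="1950-06-15", sex="female"):
        patients.append({"patient_id": pid, "sex": sex, "birth_date": birth})

    def rx(pid, rel_day, atc, covered=90):
        records.append(
            {
                "patient_id": pid,
                "dispense_date": from_day(idx + rel_day).isoformat(),
                "atc_code": atc,
                "days_covered": covered,
            }
        )

    def scaffold(pid, cls="BB", n_refills=4, pre=True, post=True):
        if pre:
            rx(pid, -760, "N02BE01", 30)
        if post:
            rx(pid, 400, "N02BE01", 30)
        for r in range(n_refills):
            rx(pid, r * 90, CLASS_ATC[cls])

    def expect(pid, cls, c2, c1, reasons, followup=None, censor=None, event=False,
               had_switch=False, had_addon=False):
        expected.append(
            {
                "patient_id": pid,
                "exposure_class": cls,
                "eligible_cohort2": c2,
                "eligible_cohort1": c1,
                "reason_codes": ";".join(reasons),
                "followup_days": followup,
                "censor_reason": censor,
                "event": event,
                "had_switch": had_switch,
                "had_addon": had_addon,
            }
        )

    # P01 under 18 at index
    add_patient("P01", birth="1990-01-01")
    scaffold("P01")
    expect("P01", "BB", False, False, ["AGE"])

    # P02 pharmacy history starts <2y before index
    add_patient("P02")
    rx("P02", -300, "N02BE01", 30)
    rx("P02", 400, "N02BE01", 30)
    for r in range(4):
        rx("P02", r * 90, CLASS_ATC["BB"])
    expect("P02", "BB", False, False, ["PRE_HISTORY"])

    # P03 no records beyond one year after index
    add_patient("P03")
    rx("P03", -760, "N02BE01", 30)
    for r in range(3):
        rx("P03", r * 90, CLASS_ATC["BB"])
    expect("P03", "BB", False, False, ["POST_HISTORY"])

    # P04 only two index-class prescriptions in year one
    add_patient("P04")
    rx("P04", -760, "N02BE01", 30)
    rx("P04", 400, "N02BE01", 30)
    rx("P04", 0, CLASS_ATC["BB"])
    rx("P04", 90, CLASS_ATC["BB"])
    expect("P04", "BB", False, False, ["MIN_PRESCRIPTIONS"])

    # P05 statin within the first post-index year
    add_patient("P05")
    scaffold("P05")
    rx("P05", 200, "C10AA05")
    expect("P05", "BB", False, False, ["LIPID_CO_RX"])

    # P06 three monotherapy classes each with >=3 first-year dispensings
    add_patient("P06")
    rx("P06", -760, "N02BE01", 30)
    rx("P06", 400, "N02BE01", 30)
    for r in range(4):
        rx("P06", r * 90, CLASS_ATC["BB"])
    for r in range(3):
        rx("P06", 10 + r * 90, CLASS_ATC["ACEI"])
        rx("P06", 20 + r * 90, CLASS_ATC["CCB"])
    expect("P06", "BB", False, False, ["MULTI_CLASS"])

    # P07 two fixed-dose combination dispensings in year one
    add_patient("P07")
    scaffold("P07")
    rx("P07", 30, "C09BA02")
    rx("P07", 120, "C09BA02")
    expect("P07", "BB", False, False, ["FIXED_COMBO"])

    # P08 outcome-proxy drug in the 2-year lookback
    add_patient("P08")
    scaffold("P08")
    rx("P08", -400, "B01AA03", 14)
    expect("P08", "BB", False, False, ["PRIOR_CDT"])

    # P09 outcome-proxy drug in the 90-day blanking window
    add_patient("P09")
    scaffold("P09")
    rx("P09", 60, "B01AC06", 14)
    expect("P09", "BB", False, False, ["EARLY_CDT"])

    # P10-P14 chronic exclusion therapies (two dispensings in window)
    chronic = [
        ("P10", "C01AA05", "heart_failure"),
        ("P11", "N02CC01", "migraine"),
        ("P12", "H02AA02", "adrenal_disease"),
        ("P13", "H05BA01", "hyperparathyroidism"),
        ("P14", "H03AA01", "thyroid"),
    ]
    for pid, atc, name in chronic:
        add_patient(pid)
        scaffold(pid)
        rx(pid, -300, atc)
        rx(pid, -200, atc)
        expect(pid, "BB", False, False, [f"CHRONIC_EXCLUSION:{name}"])

    # P15-P19 one clean long-term initiator per class -> cohort 1
    for pid, cls in zip(["P15", "P16", "P17", "P18", "P19"], CLASS_LABELS):
        add_patient(pid, sex="male")
        rx(pid, -760, "N02BE01", 30)
        rx(pid, 400, "N02BE01", 30)
        for r in range(16):
            rx(pid, r * 90, CLASS_ATC[cls])
        # last refill at 1350 covers to 1440; >180-day silence ends follow-up
        expect(pid, cls, True, True, [], followup=1440, censor="DISCONTINUATION")

    # P20 sparse refills: adherent enough to stay on but <80% covered
    add_patient("P20")
    rx("P20", -760, "N02BE01", 30)
    rx("P20", 400, "N02BE01", 30)
    for rel in [0, 90, 180, 440, 700, 960, 1220]:
        rx("P20", rel, CLASS_ATC["BB"])
    # coverage 270+4*90=630 of 1310 follow-up days = 0.481
    expect("P20", "BB", True, False, ["LOW_ADHERENCE"], followup=1310,
           censor="DISCONTINUATION")

    # P21 clean initiator with a qualifying outcome pair at day 400
    add_patient("P21")
    rx("P21", -760, "N02BE01", 30)
    rx("P21", 400, "N02BE01", 30)
    for r in range(16):
        rx("P21", r * 90, CLASS_ATC["BB"])
    rx("P21", 400, "B01AC06", 14)
    rx("P21", 430, "B01AC06", 14)
    expect("P21", "BB", True, True, [], followup=400, censor="CDT_EVENT", event=True)

    # P22 add-on of a second class at day 300 -> censored, short follow-up
    add_patient("P22")
    rx("P22", -760, "N02BE01", 30)
    rx("P22", 400, "N02BE01", 30)
    for r in range(16):
        rx("P22", r * 90, CLASS_ATC["BB"])
    rx("P22", 300, CLASS_ATC["CCB"])
    expect("P22", "BB", True, False, ["SHORT_FOLLOWUP"], followup=300,
           censor="ADDON", had_addon=True)

    # P23 stops at day 450 and starts a thiazide 110 days later -> switch
    add_patient("P23")
    rx("P23", -760, "N02BE01", 30)
    rx("P23", 400, "N02BE01", 30)
    for r in range(5):
        rx("P23", r * 90, CLASS_ATC["BB"])
    rx("P23", 560, CLASS_ATC["THIAZIDE"])
    expect("P23", "BB", True, True, [], followup=450, censor="DISCONTINUATION",
           had_switch=True)

    db = validate_database(pd.DataFrame(patients), pd.DataFrame(records))
    return db, pd.DataFrame(expected), admin_end_day
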