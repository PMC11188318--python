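"""Stabilized IPTW, time-varying Cox regression, weighted Kaplan-Meier,
subgroup / interaction analysis, and sensitivity cohorts.

The exposure is the baseline monotherapy class (reference: beta-blockers).
Two 5-class multinomial logistic models are fitted on person-period rows: a
numerator model on sex, age and calendar period, and a denominator model that
adds the time-varying comorbidity-drug flags (model 1) or additionally the
interval adherence (model 2).  Each row's stabilized weight is the cumulative
product over the patient's intervals of the per-interval ratios of
numerator-to-denominator treatment probabilities for the patient's own
observed class; because the exposure is assigned once at baseline, the
history-conditioned probability of remaining on it is 1 after the first
interval, so the default weight is the first-interval ratio carried forward
(see :class:`WeightModelSpec.weighting`).

Hazard ratios come from a Cox partial likelihood on counting-process rows
(start, stop] with Efron tie handling; weighted fits use a patient-clustered
robust (sandwich) variance, crude fits the model-based variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .prescription_store import CLASS_LABELS

__all__ = [
    "WeightModelSpec",
    "EstimationError",
    "PositivityError",
    "fit_propensity_models",
    "compute_stabilized_weights",
    "HazardEstimate",
    "fit_cox",
    "estimate_km",
    "run_subgroups",
    "test_interaction",
    "build_sensitivity_cohorts",
    "truncate_members",
    "truncate_person_periods",
    "summarize_baseline",
    "add_subgroup_columns",
    "AGE_BANDS",
    "calendar_period",
]

AGE_BANDS = ((18, 39, "18-39"), (40, 69, "40-69"), (70, 200, ">=70"))

_PERIODS = ("1996-2000", "2000-2010", "2010-2020")


def calendar_period(year) -> str:
    """Three-level calendar period; boundary years belong to the later period."""
    year = np.asarray(year)
    return np.select([year < 2000, year < 2010], _PERIODS[:2], default=_PERIODS[2])


class EstimationError(RuntimeError):
    pass


class PositivityError(EstimationError):
    """Predicted probability of the observed class fell below the floor."""

    def __init__(self, message, rows):
        super().__init__(message)
        self.rows = rows


@dataclass
class WeightModelSpec:
    """Covariate specification for the stabilized-weight models.

    ``model=1``: denominator = numerator + comorbidity-drug flags;
    ``model=2`` additionally conditions on the interval adherence (used for
    the all-comers cohort, where adherence varies).
    """

    model: int = 1
    numerator_covariates: tuple = ("sex", "age", "period")
    confounders: tuple = ("diabetes_rx", "ra_rx", "asthma_copd_rx")
    truncation_percentiles: tuple | None = None
    probability_floor: float = 1e-12
    #: 'treatment_history': per-interval probabilities are conditioned on the
    #: treatment already received; with a baseline-assigned exposure every
    #: post-baseline factor is exactly 1 and the stabilized weight is the
    #: first-interval ratio carried forward (the consistent estimator).
    #: 'pooled_product': naive cumulative product of unconditional per-interval
    #: ratios (diagnostic only; inconsistent for a baseline exposure when
    #: confounders persist -- weights grow geometrically).
    weighting: str = "treatment_history"

    @property
    def denominator_covariates(self) -> tuple:
        extra = ("adherence_180",) if self.model == 2 else ()
        return self.numerator_covariates + self.confounders + extra


def _design_matrix(pp: pd.DataFrame, covariates: tuple) -> pd.DataFrame:
    X = pd.DataFrame(index=pp.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov == "sex":
            X["sex_male"] = (pp["sex"] == "male").astype(float)
        elif cov == "age":
            X["age_at_index"] = pp["age_at_index"].astype(float)
        elif cov == "period":
            period = calendar_period(pp["index_year"].to_numpy())
            for level in _PERIODS[1:]:
                col = (period == level).astype(float)
                if col.any():
                    X[f"period_{level}"] = col
        else:
            X[cov] = pp[cov].astype(float)
    # constant columns other than the intercept make the MLE singular
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    return X[keep]


def _class_codes(pp: pd.DataFrame) -> np.ndarray:
    mapping = {c: i for i, c in enumerate(CLASS_LABELS)}  # BB = 0 = reference
    return pp["exposure_class"].map(mapping).to_numpy()


def fit_propensity_models(pp: pd.DataFrame, spec: WeightModelSpec = WeightModelSpec()):
    """Fit the numerator and denominator multinomial class-membership models.

    Returns ``(numerator_result, denominator_result)`` (statsmodels MNLogit
    fits, beta-blockers as the reference category).  Raises
    :class:`EstimationError` on missing classes or non-convergence.
    """
    import statsmodels.api as sm

    present = pp["exposure_class"].unique()
    if len(present) < 2:
        raise EstimationError(
            f"propensity models need >=2 exposure classes, found {list(present)}"
        )
    y = _class_codes(pp)
    results = []
    for covs in (spec.numerator_covariates, spec.denominator_covariates):
        X = _design_matrix(pp, covs)
        if X.isna().any().any():
            bad = X.columns[X.isna().any()].tolist()
            raise EstimationError(f"missing covariate values in {bad}")
        # quasi-separation check: a binary covariate with an empty
        # class-by-level cell makes the MLE unbounded
        for col in X.columns:
            vals = X[col].to_numpy()
            if col == "const" or len(np.unique(vals)) > 2:
                continue
            cells = pd.crosstab(vals, y)
            if (cells.to_numpy() == 0).any():
                raise EstimationError(
                    f"separation: covariate {col} has an empty exposure-class "
                    "cell; the propensity model cannot converge"
                )
        model = sm.MNLogit(y, X)
        res = model.fit(method="newton", maxiter=200, disp=0)
        if not res.mle_retvals.get("converged", False) or not np.isfinite(
            res.params.to_numpy()
        ).all():
            worst = X.columns[
                int(np.nanargmax(np.abs(res.params.to_numpy()).max(axis=1)))
            ]
            raise EstimationError(
                f"propensity model did not converge (suspect covariate: {worst})"
            )
        res._rxmsm_covariates = covs
        results.append(res)
    return tuple(results)


def _observed_probability(res, pp: pd.DataFrame) -> np.ndarray:
    X = _design_matrix(pp, res._rxmsm_covariates)
    probs = np.asarray(res.predict(X))
    return probs[np.arange(len(pp)), _class_codes(pp)]


def compute_stabilized_weights(
    pp: pd.DataFrame, models, spec: WeightModelSpec = WeightModelSpec()
) -> pd.DataFrame:
    """Per-row stabilized weights.

    ``ratio_k = p_num / p_den`` for the observed class at each interval;
    ``sw_k`` is the cumulative product over the patient's intervals of the
    per-interval treatment-probability ratios.  Under the default
    ``treatment_history`` weighting the exposure is fixed at baseline, so the
    conditional probability of staying on the observed class is 1 after the
    first interval and ``sw_k`` equals the first-interval ratio throughout
    follow-up; ``pooled_product`` multiplies the raw unconditional ratios
    (diagnostic only).  Optional symmetric percentile truncation applies to
    ``sw_k``.
    """
    num_res, den_res = models
    order = pp.sort_values(["patient_id", "k"], kind="mergesort").index
    pp_sorted = pp.loc[order]
    p_num = _observed_probability(num_res, pp_sorted)
    p_den = _observed_probability(den_res, pp_sorted)
    floor = spec.probability_floor
    low = p_den < floor
    if low.any():
        rows = pp_sorted.index[low].tolist()
        raise PositivityError(
            f"{low.sum()} person-period rows have denominator probability "
            f"below {floor:g} (positivity violation)",
            rows,
        )
    ratio = p_num / p_den
    if spec.weighting == "treatment_history":
        first = ~pp_sorted["patient_id"].duplicated().to_numpy()
        per_interval = np.where(first, ratio, 1.0)
    elif spec.weighting == "pooled_product":
        per_interval = ratio
    else:
        raise ValueError(f"unknown weighting {spec.weighting!r}")
    sw = (
        pd.Series(per_interval, index=pp_sorted.index)
        .groupby(pp_sorted["patient_id"].to_numpy())
        .cumprod()
        .to_numpy()
    )
    if spec.truncation_percentiles is not None:
        lo_p, hi_p = spec.truncation_percentiles
        lo_v, hi_v = np.percentile(sw, [lo_p, hi_p])
        sw = np.clip(sw, lo_v, hi_v)
    out = pd.DataFrame(
        {
            "patient_id": pp_sorted["patient_id"].to_numpy(),
            "k": pp_sorted["k"].to_numpy(),
            "p_num": p_num,
            "p_den": p_den,
            "ratio": ratio,
            "sw": sw,
        },
        index=pp_sorted.index,
    ).loc[pp.index]
    return out


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def _cluster_robust_variance(
    X: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    inv_information: np.ndarray,
    clusters: np.ndarray,
) -> np.ndarray:
    """Lin-Wei sandwich variance for a weighted Cox fit on (start, stop] rows.

    Score residuals use the exact delayed-entry risk sets (a row is at risk at
    event time t iff start < t <= stop) with Breslow handling of tied events;
    residuals are summed within cluster before the outer product, giving a
    patient-clustered estimator for weighted, interval-split data.
    Fully vectorized: O(rows x covariates).
    """
    n, d = X.shape
    phi = np.exp(X @ beta)
    wphi = w * phi
    times = np.unique(stop[event])
    m = len(times)
    # risk interval of each row on the event-time grid: positions [a_i, b_i)
    a = np.searchsorted(times, start, side="right")
    b = np.searchsorted(times, stop, side="right")
    # aggregate S0(t) = sum w*phi over risk set, S1(t) likewise for each covariate
    diff0 = np.zeros(m + 1)
    np.add.at(diff0, a, wphi)
    np.add.at(diff0, b, -wphi)
    S0 = diff0[:-1].cumsum()
    S1 = np.zeros((m + 1, d))
    np.add.at(S1, a, X * wphi[:, None])
    np.add.at(S1, b, -(X * wphi[:, None]))
    S1 = S1[:-1].cumsum(axis=0)
    xbar = S1 / S0[:, None]
    # weighted number of events at each time
    ev_pos = np.searchsorted(times, stop[event])
    dW = np.zeros(m)
    np.add.at(dW, ev_pos, w[event])
    G0 = dW / S0
    G1 = xbar * G0[:, None]
    cG0 = np.concatenate([[0.0], G0.cumsum()])
    cG1 = np.vstack([np.zeros(d), G1.cumsum(axis=0)])
    rng0 = cG0[b] - cG0[a]
    rng1 = cG1[b] - cG1[a]
    U = -wphi[:, None] * (X * rng0[:, None] - rng1)
    idx = np.flatnonzero(event)
    U[idx] += w[idx, None] * (X[idx] - xbar[ev_pos])
    # sum residuals within cluster
    order = np.argsort(clusters, kind="stable")
    Uo = U[order]
    bounds = np.flatnonzero(
        np.r_[True, clusters[order][1:] != clusters[order][:-1]]
    )
    Ug = np.add.reduceat(Uo, bounds, axis=0)
    B = Ug.T @ Ug
    return inv_information @ B @ inv_information


@dataclass
class HazardEstimate:
    comparison: str          # e.g. "THIAZIDE vs BB"
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    weighted: bool
    n_events: int
    variance_type: str       # "model" or "robust"


def _cox_frame(pp: pd.DataFrame, weights=None) -> tuple[pd.DataFrame, list[str]]:
    df = pd.DataFrame(
        {
            "patient_id": pp["patient_id"].to_numpy(),
            "start": pp["start_day"].to_numpy(dtype=float),
            "stop": pp["stop_day"].to_numpy(dtype=float),
            "event": pp["event"].to_numpy(dtype=bool),
        }
    )
    if (df["stop"] <= df["start"]).any():
        raise EstimationError("zero-length person-period rows in Cox input")
    cols = []
    for cls in CLASS_LABELS[1:]:
        col = (pp["exposure_class"] == cls).astype(float).to_numpy()
        if col.any():
            df[f"cls_{cls}"] = col
            cols.append(f"cls_{cls}")
    if weights is not None:
        df["w"] = np.asarray(weights, dtype=float)
    return df, cols


def fit_cox(pp: pd.DataFrame, weights=None, extra_columns: dict | None = None,
            robust: bool | None = None):
    """Time-varying Cox fit of the class effects versus beta-blockers.

    Counting-process rows (start, stop]; Efron ties.  Unweighted fits report
    the model-based variance; weighted fits use the patient-clustered robust
    sandwich variance (pass ``robust=False`` to skip the sandwich when only
    point estimates are needed; coefficients are unaffected).
    ``extra_columns`` adds further numeric covariates (used by the
    interaction analysis).  Returns ``(estimates, fitter)`` with one
    :class:`HazardEstimate` per non-reference class present.
    """
    if not pp["event"].any():
        raise EstimationError("no events: Cox model cannot be fitted")
    df, cols = _cox_frame(pp, weights)
    if extra_columns:
        for name, values in extra_columns.items():
            df[name] = np.asarray(values, dtype=float)
            cols.append(name)
    weighted = weights is not None
    if robust is None:
        robust = weighted
    cph = CoxPHFitter()
    fit_kwargs = dict(
        duration_col="stop",
        event_col="event",
        entry_col="start",
        formula=" + ".join(cols),
    )
    if weighted:
        fit_kwargs.update(weights_col="w")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", category=UserWarning)
        _warnings.filterwarnings("ignore", message=".*weights are not integers.*")
        _warnings.filterwarnings("ignore", message=".*convergence.*")
        cph.fit(df.drop(columns=["patient_id"]), **fit_kwargs)

    params = cph.params_.reindex(cols)
    if robust:
        # lifelines' own sandwich ignores delayed entry and scales poorly;
        # use the exact vectorized cluster-robust estimator instead.
        V = _cluster_robust_variance(
            X=df[cols].to_numpy(dtype=float),
            start=df["start"].to_numpy(),
            stop=df["stop"].to_numpy(),
            event=df["event"].to_numpy(dtype=bool),
            w=df["w"].to_numpy() if weighted else np.ones(len(df)),
            beta=params.to_numpy(),
            inv_information=cph.variance_matrix_.reindex(
                index=cols, columns=cols
            ).to_numpy(),
            clusters=df["patient_id"].to_numpy(),
        )
        ses = pd.Series(np.sqrt(np.diag(V)), index=cols)
        cph.robust_variance_matrix_ = pd.DataFrame(V, index=cols, columns=cols)
    else:
        ses = cph.summary["se(coef)"].reindex(cols)

    n_events = int(df["event"].sum())
    out = []
    for name in cols:
        if not name.startswith("cls_"):
            continue
        coef, se = float(params[name]), float(ses[name])
        z = coef / se
        out.append(
            HazardEstimate(
                comparison=f"{name[4:]} vs BB",
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(coef - 1.959964 * se)),
                ci_high=float(np.exp(coef + 1.959964 * se)),
                p_value=float(stats.chi2.sf(z * z, 1)),
                log_hr=coef,
                se=se,
                weighted=weighted,
                n_events=n_events,
                variance_type="robust" if robust else "model",
            )
        )
    cph._rxmsm_se = ses
    return out, cph


# ---------------------------------------------------------------------------
# Weighted Kaplan-Meier
# ---------------------------------------------------------------------------


def estimate_km(pp: pd.DataFrame, weights=None, exposure_class: str | None = None):
    """(Weighted) product-limit survival curve on counting-process rows.

    Risk set at event time t: rows with start < t <= stop, so delayed entry
    from interval splitting is handled exactly.  With unit weights this equals
    the classical Kaplan-Meier on per-patient durations.
    Returns a DataFrame (day, survival), non-increasing, starting at (0, 1).
    """
    mask = (
        (pp["exposure_class"] == exposure_class).to_numpy()
        if exposure_class is not None
        else np.ones(len(pp), dtype=bool)
    )
    start = pp["start_day"].to_numpy(dtype=float)[mask]
    stop = pp["stop_day"].to_numpy(dtype=float)[mask]
    event = pp["event"].to_numpy(dtype=bool)[mask]
    w = (
        np.ones(mask.sum())
        if weights is None
        else np.asarray(weights, dtype=float)[mask]
    )
    times = np.unique(stop[event])
    days, surv = [0.0], [1.0]
    s = 1.0
    for t in times:
        at_risk = w[(start < t) & (stop >= t)].sum()
        d = w[event & (stop == t)].sum()
        if at_risk <= 0:
            break
        s *= 1.0 - d / at_risk
        days.append(float(t))
        surv.append(float(s))
    return pd.DataFrame({"day": days, "survival": surv})


# ---------------------------------------------------------------------------
# Subgroups and interaction
# ---------------------------------------------------------------------------


def run_subgroups(pp: pd.DataFrame, weights, subgroup_variable: str) -> dict:
    """Cox fit per level of a time-constant subgroup variable.

    The overall stabilized weights are reused as-is (never refitted within
    subgroups).  Levels whose subset cannot be fitted (no events, a missing
    class) are reported as ``None``.
    """
    weights = None if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for level in sorted(pp[subgroup_variable].unique(), key=str):
        m = (pp[subgroup_variable] == level).to_numpy()
        sub = pp[m]
        try:
            estimates, _ = fit_cox(sub, None if weights is None else weights[m])
        except EstimationError:
            estimates = None
        out[str(level)] = estimates
    return out


def test_interaction(pp: pd.DataFrame, weights, subgroup_variable: str) -> dict:
    """Wald p-values for exposure x subgroup product terms (robust variance).

    The model contains the class dummies, the subgroup main effects, and all
    products; one p-value per product term.
    """
    levels = sorted(pp[subgroup_variable].unique(), key=str)
    if len(levels) < 2:
        raise EstimationError(
            f"subgroup variable {subgroup_variable!r} is constant"
        )
    extra = {}
    sub_dummies = {}
    for level in levels[1:]:
        name = f"sub_{_sanitize(level)}"
        sub_dummies[name] = (pp[subgroup_variable] == level).astype(float).to_numpy()
        extra[name] = sub_dummies[name]
    for cls in CLASS_LABELS[1:]:
        cls_col = (pp["exposure_class"] == cls).astype(float).to_numpy()
        if not cls_col.any():
            continue
        for name, dummy in sub_dummies.items():
            extra[f"ix_{cls}_{name[4:]}"] = cls_col * dummy
    _, cph = fit_cox(pp, weights, extra_columns=extra)
    pvals = {}
    for term in cph._rxmsm_se.index:
        if term.startswith("ix_"):
            z = float(cph.params_[term]) / float(cph._rxmsm_se[term])
            pvals[term] = float(stats.chi2.sf(z * z, 1))
    return pvals


def _sanitize(level) -> str:
    return str(level).replace(" ", "_").replace(">=", "ge").replace("<", "lt").replace("-", "_")


# ---------------------------------------------------------------------------
# Sensitivity cohorts
# ---------------------------------------------------------------------------


def build_sensitivity_cohorts(cohort1: pd.DataFrame, cohort2: pd.DataFrame) -> dict:
    """Split each cohort by whether a switch or add-on ever occurred.

    cohort3/4: members of cohort 1/2 with neither switch nor add-on;
    cohort5/6: members with a switch or an add-on.
    """
    out = {}
    for name_clean, name_switched, base in (("cohort3", "cohort5", cohort1),
                                            ("cohort4", "cohort6", cohort2)):
        moved = (base["had_switch"] | base["had_addon"]).to_numpy()
        out[name_clean] = base[~moved].reset_index(drop=True)
        out[name_switched] = base[moved].reset_index(drop=True)
    return out


def truncate_members(members: pd.DataFrame, horizon_days: int) -> pd.DataFrame:
    """Apply a shorter follow-up horizon to a member table."""
    m = members.copy()
    over = m["followup_days"] > horizon_days
    m.loc[over, "followup_days"] = horizon_days
    m.loc[over, "event"] = False
    m.loc[over, "event_day"] = np.nan
    m.loc[over, "censor_reason"] = "MAX_FOLLOWUP"
    return m


def truncate_person_periods(pp: pd.DataFrame, horizon_days: int) -> pd.DataFrame:
    """Clip person-period rows at a shorter horizon (events beyond it censor)."""
    out = pp[pp["start_day"] < horizon_days].copy()
    clipped = out["stop_day"] > horizon_days
    out.loc[clipped, "stop_day"] = horizon_days
    out.loc[clipped, "event"] = False
    out.loc[clipped, "censor_reason"] = "MAX_FOLLOWUP"
    return out


# ---------------------------------------------------------------------------
# Baseline table
# ---------------------------------------------------------------------------


def add_subgroup_columns(pp: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Attach time-constant subgroup variables to person-period rows.

    Adds the age category, calendar period, baseline (first-interval)
    comorbidity flags, and the whole-follow-up adherence category.
    """
    pp = pp.copy()
    age = pp["age_at_index"].to_numpy()
    bands = np.select(
        [age <= hi for (_, hi, _) in AGE_BANDS],
        [lab for (_, _, lab) in AGE_BANDS],
        default=AGE_BANDS[-1][2],
    )
    pp["age_group"] = bands
    pp["period"] = calendar_period(pp["index_year"].to_numpy())
    base = pp[pp["k"] == 0][
        ["patient_id", "diabetes_rx", "ra_rx", "asthma_copd_rx"]
    ].rename(
        columns={
            "diabetes_rx": "diabetes0",
            "ra_rx": "ra0",
            "asthma_copd_rx": "asthma_copd0",
        }
    )
    pp = pp.merge(base, on="patient_id", how="left")
    if "adherence_total" in members.columns:
        adh = members[["patient_id", "adherence_total"]].copy()
        adh["adherence_group"] = np.select(
            [adh["adherence_total"] < 0.8, adh["adherence_total"] < 0.95],
            ["<0.8", "0.8-0.95"],
            default=">=0.95",
        )
        pp = pp.merge(adh[["patient_id", "adherence_group"]], on="patient_id", how="left")
    return pp


def summarize_baseline(baseline: pd.DataFrame, categorical: tuple = (
    "sex", "age_group", "diabetes0", "ra0", "asthma_copd0", "period",
), continuous: tuple = ("age_at_index",)):
    """Baseline characteristics by class with chi-square / Welch ANOVA tests.

    ``baseline`` has one row per patient with an ``exposure_class`` column.
    Returns ``(table, tests)``: the table holds count (percent) cells per
    class, the tests dict a p-value per variable (None with a notice when a
    single class is present).
    """
    classes = sorted(baseline["exposure_class"].unique(), key=CLASS_LABELS.index)
    single = len(classes) < 2
    rows, tests = [], {}
    n_by_class = baseline.groupby("exposure_class").size()
    for var in categorical:
        ct = pd.crosstab(baseline[var], baseline["exposure_class"])
        if single or ct.shape[0] < 2:
            tests[var] = None
        else:
            chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy())
            tests[var] = float(p)
        for level, row in ct.iterrows():
            cells = {"variable": var, "level": str(level)}
            for cls in classes:
                n = int(row.get(cls, 0))
                cells[cls] = f"{n} ({100 * n / n_by_class[cls]:.1f})"
            cells["p"] = tests[var]
            rows.append(cells)
    for var in continuous:
        if single:
            tests[var] = None
        else:
            import pingouin as pg

            res = pg.welch_anova(data=baseline, dv=var, between="exposure_class")
            tests[var] = float(res["p_unc"].iloc[0])
        cells = {"variable": var, "level": "mean_sd"}
        for cls in classes:
            sub = baseline.loc[baseline["exposure_class"] == cls, var]
            cells[cls] = f"{sub.mean():.1f} +/- {sub.std():.1f}"
        cells["p"] = tests[var]
        rows.append(cells)
    return pd.DataFrame(rows), tests
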