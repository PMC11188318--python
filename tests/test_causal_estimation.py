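"""Propensity models, stabilized weights, Cox fits, KM, subgroups, baseline."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import rxmsm.causal_estimation as ce
from rxmsm.causal_estimation import (
    EstimationError,
    PositivityError,
    WeightModelSpec,
    add_subgroup_columns,
    build_sensitivity_cohorts,
    calendar_period,
    compute_stabilized_weights,
    estimate_km,
    fit_cox,
    fit_propensity_models,
    run_subgroups,
    summarize_baseline,
    truncate_person_periods,
)
from rxmsm.causal_estimation import test_interaction as interaction_pvalues
from rxmsm.synthetic_data import SimulationConfig, simulate_person_periods


def test_calendar_period_boundaries():
    got = calendar_period(np.array([1996, 1999, 2000, 2009, 2010, 2020]))
    assert list(got) == [
        "1996-2000", "1996-2000", "2000-2010", "2000-2010", "2010-2020", "2010-2020",
    ]


# ---------------------------------------------------------------------------
# Propensity models
# ---------------------------------------------------------------------------


class TestPropensityModels:
    def test_recovers_assignment_coefficients(self):
        """Baseline rows from a known multinomial mechanism: fitted
        comorbidity-flag coefficients sit within 3 SEs of the planted ones."""
        cfg = SimulationConfig(n_patients=20000, seed=31, max_intervals=1)
        pp, _ = simulate_person_periods(cfg)
        _, den = fit_propensity_models(pp)
        # MNLogit equations are ordered ACEI, ARB, CCB, THIAZIDE (BB=reference)
        planted = cfg.class_assignment_coefficients
        params, bse = den.params, den.bse
        names = {"diabetes_rx": "diabetes", "ra_rx": "ra", "asthma_copd_rx": "asthma_copd"}
        for j, cls in enumerate(["ACEI", "ARB", "CCB", "THIAZIDE"]):
            for cov, planted_name in names.items():
                truth = planted[cls][planted_name]
                est, se = params.loc[cov].iloc[j], bse.loc[cov].iloc[j]
                assert abs(est - truth) < 3 * se, (cls, cov, est, truth)

    def test_noise_covariate_has_null_coefficients(self, small_pp):
        pp, _ = small_pp
        pp = pp.copy()
        rng = np.random.default_rng(8)
        pp["noise_rx"] = rng.random(len(pp)) < 0.3
        spec = WeightModelSpec(confounders=("noise_rx",))
        _, den = fit_propensity_models(pp, spec)
        est, se = den.params.loc["noise_rx"], den.bse.loc["noise_rx"]
        assert (np.abs(est) < 3.5 * se).all()

    def test_single_class_data_rejected(self, small_pp):
        pp, _ = small_pp
        only_bb = pp[pp.exposure_class == "BB"]
        with pytest.raises(EstimationError, match="classes"):
            fit_propensity_models(only_bb)


# ---------------------------------------------------------------------------
# Stabilized weights
# ---------------------------------------------------------------------------


class _StubModel:
    """Fixed predicted probabilities, for hand-computed weight checks."""

    _rxmsm_covariates = ()

    def __init__(self, probs):
        self._probs = np.asarray(probs)

    def predict(self, X):
        return self._probs


def _toy_pp():
    return pd.DataFrame(
        {
            "patient_id": ["a", "a", "b", "b"],
            "k": [0, 1, 0, 1],
            "start_day": [0, 180, 0, 180],
            "stop_day": [180, 360, 180, 360],
            "exposure_class": ["ACEI", "ACEI", "BB", "BB"],
            "sex": "male",
            "age_at_index": 60.0,
            "index_year": 2005,
            "event": [False, False, False, True],
        }
    )


class TestStabilizedWeights:
    def test_identical_models_give_unit_weights(self, small_pp):
        pp, _ = small_pp
        _, den = fit_propensity_models(pp)
        wt = compute_stabilized_weights(pp, (den, den))
        assert (wt["sw"] == 1.0).all()

    def test_hand_computed_toy_product(self):
        """Fixed probabilities; the cumulative pooled product and the
        treatment-history weights both match manual arithmetic."""
        pp = _toy_pp()
        # columns: BB, ACEI, ARB, CCB, THIAZIDE
        num = _StubModel([
            [0.2, 0.5, 0.1, 0.1, 0.1],
            [0.2, 0.4, 0.2, 0.1, 0.1],
            [0.5, 0.2, 0.1, 0.1, 0.1],
            [0.25, 0.3, 0.15, 0.15, 0.15],
        ])
        den = _StubModel([
            [0.2, 0.25, 0.2, 0.15, 0.2],
            [0.2, 0.8, 0.0, 0.0, 0.0],
            [0.4, 0.2, 0.2, 0.1, 0.1],
            [0.5, 0.2, 0.1, 0.1, 0.1],
        ])
        pooled = compute_stabilized_weights(
            pp, (num, den), WeightModelSpec(weighting="pooled_product")
        )
        # patient a (ACEI): ratios 0.5/0.25=2.0, 0.4/0.8=0.5 -> sw (2.0, 1.0)
        # patient b (BB):   ratios 0.5/0.4=1.25, 0.25/0.5=0.5 -> sw (1.25, 0.625)
        assert pooled["sw"].tolist() == pytest.approx([2.0, 1.0, 1.25, 0.625])
        hist = compute_stabilized_weights(pp, (num, den))
        # baseline ratio carried forward
        assert hist["sw"].tolist() == pytest.approx([2.0, 2.0, 1.25, 1.25])

    def test_positivity_floor_raises(self):
        pp = _toy_pp()
        num = _StubModel(np.full((4, 5), 0.2))
        den = _StubModel(
            [[0.2] * 5, [0.2, 1e-15, 0.2, 0.2, 0.2], [0.2] * 5, [0.2] * 5]
        )
        with pytest.raises(PositivityError) as exc:
            compute_stabilized_weights(pp, (num, den))
        assert len(exc.value.rows) == 1

    def test_truncation_clips_extremes(self, small_pp):
        pp, _ = small_pp
        models = fit_propensity_models(pp)
        spec = WeightModelSpec(truncation_percentiles=(10, 90))
        wt_raw = compute_stabilized_weights(pp, models)
        wt_trunc = compute_stabilized_weights(pp, models, spec)
        assert wt_trunc["sw"].max() < wt_raw["sw"].max()
        assert wt_trunc["sw"].min() > wt_raw["sw"].min()

    def test_mean_weight_near_one_without_time_varying_confounding(self):
        """Comorbidity streams present but ignored by prescribing: the fitted
        denominator flags are noise and per-interval mean weights sit at 1."""
        from rxmsm.synthetic_data import _DEFAULT_ASSIGNMENT

        assign = {
            c: {**v, "diabetes": 0.0, "ra": 0.0, "asthma_copd": 0.0}
            for c, v in _DEFAULT_ASSIGNMENT.items()
        }
        cfg = SimulationConfig(
            n_patients=4000, seed=13, max_intervals=5,
            class_assignment_coefficients=assign,
        )
        pp, _ = simulate_person_periods(cfg)
        wt = compute_stabilized_weights(pp, fit_propensity_models(pp))
        for k, grp in wt.groupby("k"):
            se = grp["sw"].std() / np.sqrt(len(grp))
            assert abs(grp["sw"].mean() - 1.0) < 3 * max(se, 1e-6), k


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


class TestCox:
    def test_unit_weights_equal_crude_to_ten_significant_figures(self, small_pp):
        pp, _ = small_pp
        crude, _ = fit_cox(pp)
        unit, _ = fit_cox(pp, np.ones(len(pp)), robust=False)
        for c, u in zip(crude, unit):
            assert u.log_hr == pytest.approx(c.log_hr, rel=1e-10)

    def test_null_simulation_cis_cover_one(self):
        cfg = SimulationConfig(
            n_patients=3000, seed=55, max_intervals=5,
            baseline_interval_hazard=0.03,
            true_log_hr={c: 0.0 for c in ["BB", "ACEI", "ARB", "CCB", "THIAZIDE"]},
        )
        pp, _ = simulate_person_periods(cfg)
        estimates, _ = fit_cox(pp)
        for e in estimates:
            assert e.ci_low < 1.0 < e.ci_high, e.comparison

    def test_no_events_rejected(self, small_pp):
        pp, _ = small_pp
        with pytest.raises(EstimationError, match="events"):
            fit_cox(pp.assign(event=False))

    def test_zero_length_rows_rejected(self, small_pp):
        pp, _ = small_pp
        bad = pp.copy()
        bad.loc[bad.index[0], "stop_day"] = bad.loc[bad.index[0], "start_day"]
        with pytest.raises(EstimationError, match="zero-length"):
            fit_cox(bad)

    def test_robust_se_matches_r_survival(self, small_pp, tmp_path):
        """Weighted patient-clustered sandwich vs R survival::coxph oracle."""
        pp, _ = small_pp
        models = fit_propensity_models(pp)
        wt = compute_stabilized_weights(pp, models)
        est, _ = fit_cox(pp, wt["sw"].to_numpy(), robust=True)
        df = pd.DataFrame(
            {
                "id": pp.patient_id,
                "start": pp.start_day,
                "stop": pp.stop_day,
                "event": pp.event.astype(int),
                "w": wt["sw"].to_numpy(),
            }
        )
        for cls in ["ACEI", "ARB", "CCB", "THIAZIDE"]:
            df[f"cls_{cls}"] = (pp.exposure_class == cls).astype(int)
        csv = tmp_path / "cox.csv"
        df.to_csv(csv, index=False)
        r_code = f"""
        suppressMessages(library(survival))
        d <- read.csv("{csv}")
        f <- coxph(Surv(start, stop, event) ~ cls_ACEI + cls_ARB + cls_CCB +
                   cls_THIAZIDE + cluster(id), data=d, weights=w,
                   ties="efron", robust=TRUE)
        cat(sprintf("%.10f %.10f\\n", coef(f), sqrt(diag(vcov(f)))))
        """
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        lines = [l.split() for l in out.stdout.strip().splitlines()]
        for e, (coef, se) in zip(est, lines):
            assert e.log_hr == pytest.approx(float(coef), abs=1e-5)
            assert e.se == pytest.approx(float(se), rel=0.02)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_events_flat_curve(self, small_pp):
        pp, _ = small_pp
        km = estimate_km(pp.assign(event=False))
        assert km["survival"].tolist() == [1.0]

    def test_unit_weights_match_lifelines(self, small_pp):
        """Per-patient durations through lifelines KM = our counting-process
        product-limit with unit weights."""
        pp, _ = small_pp
        km = estimate_km(pp, exposure_class="BB")
        sub = pp[pp.exposure_class == "BB"]
        per_patient = sub.groupby("patient_id").agg(
            T=("stop_day", "max"), E=("event", "any")
        )
        kmf = KaplanMeierFitter().fit(per_patient["T"], per_patient["E"])
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["day"])), abs=1e-10
            )

    def test_integer_weights_equal_row_replication(self):
        rng = np.random.default_rng(2)
        n = 40
        pp = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "start_day": 0,
                "stop_day": rng.integers(1, 400, n),
                "event": rng.random(n) < 0.5,
                "exposure_class": "BB",
            }
        )
        w = rng.integers(1, 4, n)
        km_w = estimate_km(pp, w)
        replicated = pp.loc[pp.index.repeat(w)].reset_index(drop=True)
        km_r = estimate_km(replicated)
        pd.testing.assert_frame_equal(km_w, km_r)

    def test_curve_monotone_from_one(self, small_pp):
        pp, _ = small_pp
        wt = compute_stabilized_weights(pp, fit_propensity_models(pp))
        km = estimate_km(pp, wt["sw"].to_numpy(), "ACEI")
        s = km["survival"].to_numpy()
        assert s[0] == 1.0 and (np.diff(s) <= 1e-12).all()


# ---------------------------------------------------------------------------
# Subgroups, interaction, sensitivity, baseline
# ---------------------------------------------------------------------------


class TestSubgroups:
    def test_whole_cohort_subgroup_equals_overall_fit(self, small_pp):
        pp, _ = small_pp
        pp = pp.assign(everyone="all")
        wt = compute_stabilized_weights(pp, fit_propensity_models(pp))
        overall, _ = fit_cox(pp, wt["sw"].to_numpy())
        groups = run_subgroups(pp, wt["sw"].to_numpy(), "everyone")
        for o, g in zip(overall, groups["all"]):
            assert g.log_hr == pytest.approx(o.log_hr, rel=1e-10)

    def test_identical_half_samples_give_equal_hrs(self, small_pp):
        pp, _ = small_pp
        doubled = pd.concat(
            [
                pp.assign(half="A"),
                pp.assign(half="B", patient_id=pp.patient_id + "_dup"),
            ],
            ignore_index=True,
        )
        groups = run_subgroups(doubled, None, "half")
        for a, b in zip(groups["A"], groups["B"]):
            assert a.log_hr == pytest.approx(b.log_hr, rel=1e-9)

    def test_planted_effect_modification_detected(self):
        """A strong sex-by-ARB hazard interaction yields subgroup estimates
        straddling the planted values and a significant interaction term."""
        cfg = SimulationConfig(
            n_patients=12000, seed=91, max_intervals=5,
            baseline_interval_hazard=0.03,
            sex_interaction_log_hr={"ARB": -0.9},
        )
        pp, truth = simulate_person_periods(cfg)
        wt = compute_stabilized_weights(pp, fit_propensity_models(pp))
        groups = run_subgroups(pp, wt["sw"].to_numpy(), "sex")
        arb = {
            lvl: next(e for e in ests if e.comparison.startswith("ARB"))
            for lvl, ests in groups.items()
        }
        assert arb["male"].log_hr < arb["female"].log_hr - 0.3
        pvals = interaction_pvalues(pp, wt["sw"].to_numpy(), "sex")
        assert pvals["ix_ARB_male"] < 0.05

    def test_constant_subgroup_variable_rejected(self, small_pp):
        pp, _ = small_pp
        with pytest.raises(EstimationError, match="constant"):
            interaction_pvalues(pp.assign(flat="x"), None, "flat")


class TestSensitivityCohorts:
    def _members(self):
        rng = np.random.default_rng(3)
        n = 50
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "followup_days": rng.integers(100, 3780, n),
                "event": rng.random(n) < 0.2,
                "event_day": np.nan,
                "censor_reason": "DISCONTINUATION",
                "had_switch": rng.random(n) < 0.3,
                "had_addon": rng.random(n) < 0.1,
            }
        )

    def test_partition_property(self):
        c1 = self._members()
        c2 = pd.concat([c1, self._members().assign(patient_id=lambda d: d.patient_id + "x")])
        sens = build_sensitivity_cohorts(c1, c2)
        assert set(sens["cohort3"].patient_id) | set(sens["cohort5"].patient_id) == set(
            c1.patient_id
        )
        assert set(sens["cohort3"].patient_id).isdisjoint(sens["cohort5"].patient_id)

    def test_no_switch_no_addon_means_cohort3_equals_cohort1(self):
        c1 = self._members().assign(had_switch=False, had_addon=False)
        sens = build_sensitivity_cohorts(c1, c1)
        assert len(sens["cohort3"]) == len(c1) and sens["cohort5"].empty

    def test_truncation_never_adds_rows(self, small_pp):
        pp, _ = small_pp
        short = truncate_person_periods(pp, 360)
        assert len(short) <= len(pp)
        assert short["stop_day"].max() <= 360
        per_patient_before = pp.groupby("patient_id").size()
        per_patient_after = short.groupby("patient_id").size()
        assert (per_patient_after <= per_patient_before[per_patient_after.index]).all()


class TestBaselineTable:
    def test_chi_square_matches_hand_computation(self):
        # 2x2 with counts [[20, 30], [40, 10]]: chi2 with Yates-free formula
        base = pd.DataFrame(
            {
                "exposure_class": ["BB"] * 50 + ["ACEI"] * 50,
                "sex": ["male"] * 20 + ["female"] * 30 + ["male"] * 40 + ["female"] * 10,
                "age_at_index": np.r_[np.random.default_rng(0).normal(60, 5, 100)],
            }
        )
        table, tests = summarize_baseline(
            base, categorical=("sex",), continuous=("age_at_index",)
        )
        from scipy.stats import chi2_contingency

        want = chi2_contingency(np.array([[30, 10], [20, 40]]))[1]
        assert tests["sex"] == pytest.approx(want)
        cell = table[(table.variable == "sex") & (table.level == "male")]["ACEI"].iloc[0]
        assert cell == "40 (80.0)"

    def test_single_class_skips_tests(self):
        base = pd.DataFrame(
            {
                "exposure_class": ["BB"] * 30,
                "sex": ["male"] * 15 + ["female"] * 15,
                "age_at_index": np.linspace(40, 80, 30),
            }
        )
        _, tests = summarize_baseline(
            base, categorical=("sex",), continuous=("age_at_index",)
        )
        assert tests["sex"] is None and tests["age_at_index"] is None

    def test_subgroup_columns(self, small_pp):
        pp, _ = small_pp
        members = pd.DataFrame(
            {
                "patient_id": pp.patient_id.unique(),
                "adherence_total": np.linspace(0.5, 1.0, pp.patient_id.nunique()),
            }
        )
        ppx = add_subgroup_columns(pp, members)
        assert set(ppx.age_group.unique()) <= {"18-39", "40-69", ">=70"}
        assert set(ppx.adherence_group.unique()) <= {"<0.8", "0.8-0.95", ">=0.95"}
        assert ppx["diabetes0"].notna().all()
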