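"""One-command pipeline: simulate -> cohorts -> episodes -> estimation -> report.

Every run serializes its configuration and a stage manifest (input/output
hashes, row counts, wall time) into the output directory, so any result table
can be reproduced from the run directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal_estimation as ce
from . import cohort_builder as cb
from . import episode_engine as ee
from . import synthetic_data as sd
from .prescription_store import (
    CodeCatalog,
    dump_config,
    read_database,
    write_database,
    write_table,
)

__all__ = ["run_pipeline", "summarize_events", "DEFAULT_CONFIG"]

log = logging.getLogger("rxmsm")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {"n_patients": 2000},
    "rules": {},
    "episode": {},
    "catalog": {},
    "analysis": {
        "weight_model": 1,
        "truncation_percentiles": None,
        "subgroups": ["sex"],
        "horizons": [1800, 3780],
    },
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def summarize_events(members: pd.DataFrame) -> dict:
    """Event count, one-decimal percentage, and mean +/- SD follow-up years."""
    n = len(members)
    events = int(members["event"].sum()) if n else 0
    years = members["followup_days"].to_numpy() / 365.25 if n else np.array([])
    return {
        "n": n,
        "n_events": events,
        "event_pct": round(100.0 * events / n, 1) if n else 0.0,
        "mean_followup_years": float(years.mean()) if n else float("nan"),
        "sd_followup_years": float(years.std(ddof=1)) if n > 1 else float("nan"),
    }


def _hr_table(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": e.comparison,
                "hr": e.hr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "log_hr": e.log_hr,
                "se": e.se,
                "weighted": e.weighted,
                "n_events": e.n_events,
                "variance_type": e.variance_type,
            }
            for e in estimates
        ]
    )


def _merge_config(user: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def run_pipeline(config: dict | None = None, out_dir="run_out", seed: int | None = None) -> dict:
    """Execute the full analysis and write the report bundle.

    In simulation mode (no ``database`` path in the config) the run also
    writes the planted-versus-estimated comparison.  Returns a dict of the
    main in-memory results.  Any stage failure propagates after the manifest
    records the completed stages.
    """
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config.yaml")
    manifest: list[dict] = []
    results: dict = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s started", name)
            try:
                value = fn()
            except Exception:
                _write_manifest()
                log.exception("stage %s failed", name)
                raise
            dt = time.perf_counter() - t0
            manifest.append({"stage": name, "seconds": round(dt, 3)})
            log.info("stage %s finished in %.2fs", name, dt)
            return value

        return wrap

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    catalog = CodeCatalog.from_dict(cfg.get("catalog") or {})
    rules = cb.EligibilityRules(**(cfg.get("rules") or {}))
    erules = ee.EpisodeRules(**(cfg.get("episode") or {}))

    truth = None
    if cfg.get("database"):
        db = stage("read_database")(lambda: read_database(cfg["database"], catalog))
    else:
        sim_cfg = sd.SimulationConfig(
            **{**(cfg.get("simulation") or {}), "seed": cfg["seed"]}
        )
        db, truth = stage("simulate")(lambda: sd.simulate_population(sim_cfg))
        write_database(db, out / "database")
    manifest[-1]["n_records"] = len(db.records)

    cohorts = stage("build_cohorts")(lambda: cb.build_cohorts(db, catalog, rules, erules))
    write_table(cohorts.attrition, out / "attrition.csv")
    write_table(cohorts.cohort1, out / "cohort1_members.csv")
    write_table(cohorts.cohort2, out / "cohort2_members.csv")
    manifest[-1]["n_cohort1"] = len(cohorts.cohort1)
    manifest[-1]["n_cohort2"] = len(cohorts.cohort2)
    results["cohorts"] = cohorts

    analysis = cfg["analysis"]
    report_rows = []
    for cohort_name, members, model_no in (
        ("cohort1", cohorts.cohort1, 1),
        ("cohort2", cohorts.cohort2, 2),
    ):
        if members.empty or members["event"].sum() == 0:
            log.warning("%s empty or event-free; skipping analysis", cohort_name)
            continue
        pp = stage(f"episodes_{cohort_name}")(
            lambda m=members: ee.build_person_period_table(
                m, db, catalog, erules, cohorts.summaries
            )
        )
        manifest[-1]["n_person_periods"] = len(pp)
        write_table(pp, out / f"person_periods_{cohort_name}.csv")
        results[f"pp_{cohort_name}"] = pp

        spec = ce.WeightModelSpec(
            model=analysis.get("weight_model", model_no) if cohort_name == "cohort1" else 2,
            truncation_percentiles=(
                tuple(analysis["truncation_percentiles"])
                if analysis.get("truncation_percentiles")
                else None
            ),
        )

        def analyze(pp=pp, members=members, spec=spec, cohort_name=cohort_name):
            crude, _ = ce.fit_cox(pp)
            if not analysis.get("iptw", True):
                return crude, None, None
            try:
                models = ce.fit_propensity_models(pp, spec)
                wt = ce.compute_stabilized_weights(pp, models, spec)
            except ce.EstimationError as err:
                log.warning("%s: IPTW unavailable (%s); crude-only", cohort_name, err)
                return crude, None, None
            weighted, _ = ce.fit_cox(pp, wt["sw"].to_numpy())
            return crude, weighted, wt

        crude, weighted, wt = stage(f"analyze_{cohort_name}")(analyze)
        if wt is None:
            hr = _hr_table(crude)
            hr.insert(0, "cohort", cohort_name)
            write_table(hr, out / f"hr_{cohort_name}.csv")
            results[f"hr_{cohort_name}"] = hr
            report_rows.append({"cohort": cohort_name, **summarize_events(members)})
            continue
        write_table(wt, out / f"weights_{cohort_name}.csv")
        hr = pd.concat([_hr_table(crude), _hr_table(weighted)], ignore_index=True)
        hr.insert(0, "cohort", cohort_name)
        write_table(hr, out / f"hr_{cohort_name}.csv")
        results[f"hr_{cohort_name}"] = hr
        results[f"weights_{cohort_name}"] = wt

        km_frames = []
        for cls in sorted(pp["exposure_class"].unique()):
            for label, w in (("crude", None), ("iptw", wt["sw"].to_numpy())):
                curve = ce.estimate_km(pp, w, cls)
                curve.insert(0, "weighting", label)
                curve.insert(0, "exposure_class", cls)
                km_frames.append(curve)
        write_table(pd.concat(km_frames, ignore_index=True), out / f"km_{cohort_name}.csv")

        ppx = ce.add_subgroup_columns(pp, members)
        sub_rows = []
        for var in analysis.get("subgroups", []):
            groups = ce.run_subgroups(ppx, wt["sw"].to_numpy(), var)
            for level, ests in groups.items():
                for e in ests or []:
                    sub_rows.append(
                        {"cohort": cohort_name, "variable": var, "level": level,
                         "comparison": e.comparison, "hr": e.hr,
                         "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p_value}
                    )
        if sub_rows:
            write_table(pd.DataFrame(sub_rows), out / f"subgroups_{cohort_name}.csv")

        baseline = ppx[ppx["k"] == 0][
            ["patient_id", "exposure_class", "sex", "age_at_index", "age_group",
             "period", "diabetes0", "ra0", "asthma_copd0"]
        ]
        table, _ = ce.summarize_baseline(baseline)
        write_table(table, out / f"baseline_{cohort_name}.csv")

        report_rows.append({"cohort": cohort_name, **summarize_events(members)})

    # sensitivity cohorts at each horizon
    sens = ce.build_sensitivity_cohorts(cohorts.cohort1, cohorts.cohort2)
    sens_rows = []
    for horizon in analysis.get("horizons", [3780]):
        for name, members in sens.items():
            m = ce.truncate_members(members, horizon)
            sens_rows.append({"sensitivity_cohort": name, "horizon_days": horizon,
                              **summarize_events(m)})
    write_table(pd.DataFrame(sens_rows), out / "sensitivity_cohorts.csv")
    results["sensitivity"] = sens

    if truth is not None and "hr_cohort1" in results:
        est = results["hr_cohort1"]
        est_w = est[est["weighted"]]
        comp_rows = []
        for _, row in est_w.iterrows():
            cls = row["comparison"].split(" ")[0]
            comp_rows.append(
                {"comparison": row["comparison"],
                 "planted_hr": truth.true_hr.get(cls),
                 "estimated_hr": row["hr"],
                 "ci_low": row["ci_low"], "ci_high": row["ci_high"]}
            )
        write_table(pd.DataFrame(comp_rows), out / "planted_vs_estimated.csv")

    events_df = pd.DataFrame(report_rows)
    write_table(events_df, out / "event_summary.csv")
    results["event_summary"] = events_df

    for f in sorted(out.glob("*.csv")):
        manifest.append({"output": f.name, "sha256": _sha256(f)})
    _write_manifest()
    return results
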