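"""End-to-end orchestration: simulate -> quantify -> change -> analyze.

Produces the standard report set (quartile characteristics table,
change-predictor coefficient table, per-endpoint hazard-ratio tables) from
either synthetic or user-supplied CSVs, with a run log capturing seed,
configuration hash, and row counts at every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, cohort, io, longitudinal, qpcr

logger = logging.getLogger("telotrack")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    outdir: str = "telotrack_out"
    seed: int = 0
    simulate: bool = True
    n_participants: int = 4576
    plates_path: str | None = None
    exam1_path: str | None = None
    exam2_path: str | None = None
    registry_path: str | None = None
    qc_policy: str = "leave_one_out_2sd"
    anchor_bp: float = qpcr.DEFAULT_ANCHOR_BP
    calibrate_age: bool = True
    endpoints: tuple[str, ...] = tuple(association.ENDPOINTS)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_inputs(
    plates: pd.DataFrame | None = None,
    exams: pd.DataFrame | None = None,
    registry: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Schema and invariant checks; report-only.

    Returns ``{"failures": [...], "warnings": [...]}``.  Failures are
    violations of hard invariants (negative Ct, nonpositive telomere length,
    unknown enums); warnings flag implausible but processable values (e.g. an
    inter-examination gap far from ~9-10 years).
    """
    failures: list[str] = []
    warnings: list[str] = []
    if plates is not None:
        bad = plates["ct"] <= 0
        if bad.any():
            failures.append(f"{int(bad.sum())} wells with nonpositive Ct")
        roles = set(plates["role"]) - {r.value for r in qpcr.Role}
        if roles:
            failures.append(f"unknown well roles: {sorted(roles)}")
        assays = set(plates["assay"]) - {a.value for a in qpcr.Assay}
        if assays:
            failures.append(f"unknown assays: {sorted(assays)}")
    if exams is not None:
        bad = exams["tl_bp"] <= 0
        if bad.any():
            failures.append(f"{int(bad.sum())} exam records with nonpositive telomere length")
        if (exams["age"] <= 0).any():
            failures.append("exam records with nonpositive age")
        both = exams.pivot_table(index="participant_id", columns="exam_id",
                                 values="exam_date", aggfunc="first")
        if {"exam1", "exam2"} <= set(both.columns):
            gap = (pd.to_datetime(both["exam2"]) - pd.to_datetime(both["exam1"])).dt.days / 365.25
            odd = ((gap < 5) | (gap > 15)).fillna(False)
            if odd.any():
                warnings.append(
                    f"{int(odd.sum())} participants with inter-examination gap outside 5-15 years"
                )
    if registry is not None:
        types = set(registry["event_type"]) - {"diagnosis", "death", "emigration"}
        if types:
            failures.append(f"unknown registry event types: {sorted(types)}")
        nocode = registry[(registry["event_type"] == "diagnosis") & (registry["icd_code"] == "")]
        if len(nocode):
            failures.append(f"{len(nocode)} diagnosis events without an ICD code")
    return {"failures": failures, "warnings": warnings}


def _characteristics_table(exam: pd.DataFrame, label: str) -> pd.DataFrame:
    """Quartile characteristics with trend tests (one row per covariate)."""
    q = longitudinal.quartilize(exam["tl_bp"].to_numpy(float), "largest_first")
    rows = []
    covs = {
        "age": exam["age"].to_numpy(float),
        "male": (exam["sex"].astype(str).str.lower() == "male").astype(float).to_numpy(),
        "current_smoking": exam["current_smoking"].to_numpy(float),
        "tobacco_g_day": exam["tobacco_g_day"].to_numpy(float),
        "bmi": exam["bmi"].to_numpy(float),
        "physical_inactivity": (exam["exercise_h_week"].to_numpy(float) < 4).astype(float),
        "heavy_alcohol": pd.Series(
            [
                association.classify_heavy_alcohol(s, g) if pd.notna(g) else float("nan")
                for s, g in zip(exam["sex"], exam["alcohol_g_week"])
            ]
        ).astype(float).to_numpy(),
    }
    for name, vals in covs.items():
        res = association.trend_test_quartiles(vals, q)
        medians = [float(pd.Series(vals[q == k]).median()) for k in (1, 2, 3, 4)]
        rows.append(
            {
                "examination": label,
                "covariate": name,
                "q1_median": medians[0],
                "q2_median": medians[1],
                "q3_median": medians[2],
                "q4_median": medians[3],
                "trend_estimate": res["estimate"],
                "trend_p": res["p_value"],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``config.outdir``.

    Stages: (1) synthetic data generation or CSV ingest, (2) optional plate
    quantification, (3) age recalibration and change statistics, (4) trend
    tests, change-predictor regressions, and per-endpoint Cox models.
    Returns the in-memory report dict; every table is also written as CSV.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config_sha256": config.digest(), "stages": {}}

    try:
        if config.simulate:
            gcfg = cohort.GeneratorConfig(
                n_participants=config.n_participants, seed=config.seed,
                anchor_bp=config.anchor_bp,
            )
            tables = cohort.generate_cohort(gcfg)
            exam1, exam2 = tables["exam1"], tables["exam2"]
            registry = cohort.simulate_registry(tables["truth"], exam2, gcfg)
            io.write_csv(exam1, outdir / "exam1.csv")
            io.write_csv(exam2, outdir / "exam2.csv")
            io.write_csv(registry, outdir / "registry.csv")
            plates = None
        else:
            exam1 = io.read_exams(config.exam1_path)
            exam2 = io.read_exams(config.exam2_path)
            registry = io.read_registry(config.registry_path)
            plates = io.read_plates(config.plates_path) if config.plates_path else None
    except FileNotFoundError as exc:
        raise RuntimeError(f"stage=ingest: {exc}") from exc
    log["stages"]["ingest"] = {"exam1": len(exam1), "exam2": len(exam2), "registry": len(registry)}

    report = validate_inputs(plates=plates, exams=pd.concat([exam1, exam2]), registry=registry)
    if report["failures"]:
        raise RuntimeError(f"stage=validate: {len(report['failures'])} hard failures: "
                           + "; ".join(report["failures"]))
    log["stages"]["validate"] = report

    if plates is not None:
        quant, precision = qpcr.quantify_plate_set(
            plates, qc_policy=config.qc_policy, anchor_bp=config.anchor_bp
        )
        io.write_csv(quant, outdir / "quant.csv")
        log["stages"]["quantify"] = {
            "samples": len(quant),
            "ok": int((quant["qc_status"] == "ok").sum()),
        }

    change = longitudinal.build_change_table(exam1, exam2, calibrate_age=config.calibrate_age)
    io.write_csv(change, outdir / "change.csv")
    summ = longitudinal.change_summary(change["change_bp_10y"])
    log["stages"]["change"] = dataclasses.asdict(summ)

    char = pd.concat(
        [_characteristics_table(exam1, "exam1"), _characteristics_table(exam2, "exam2")],
        ignore_index=True,
    )
    io.write_csv(char, outdir / "table1_characteristics.csv")

    predictors = association.build_predictor_table(exam1, exam2)
    aligned = change.set_index("participant_id").loc[predictors["participant_id"]]
    coef_uni = association.fit_change_predictors(
        aligned["change_bp_10y"].to_numpy(), predictors, "univariable",
        anchor_bp=config.anchor_bp)
    coef_multi = association.fit_change_predictors(
        aligned["change_bp_10y"].to_numpy(), predictors, "multivariable",
        anchor_bp=config.anchor_bp)
    coef = pd.concat(
        [coef_uni.assign(model="univariable"), coef_multi.assign(model="multivariable")],
        ignore_index=True,
    )
    io.write_csv(coef, outdir / "table2_change_predictors.csv")

    base = exam2.merge(change[["participant_id", "change_quartile"]], on="participant_id")
    cox_rows = []
    for name in config.endpoints:
        definition = association.ENDPOINTS[name]
        fu = association.build_followup(base, registry, definition)
        adjust = association._adjustment_matrix(fu)
        for model, adj in (("unadjusted", None), ("adjusted", adjust)):
            fit = association.fit_cox_quartiles(fu, "change_quartile", adjust=adj)
            tbl = fit["table"].assign(endpoint=name, model=model, trend_p=fit["trend_p"])
            cox_rows.append(tbl)
        log["stages"].setdefault("followup", {})[name] = {
            "n": len(fu),
            "events": int(fu["event_indicator"].sum()),
            "prevalent_excluded": fu.attrs.get("n_prevalent_excluded", 0),
        }
    cox = pd.concat(cox_rows, ignore_index=True)
    io.write_csv(cox, outdir / "table3_cox_quartiles.csv")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    logger.info("pipeline complete: %s", outdir)
    return {
        "exam1": exam1, "exam2": exam2, "registry": registry, "change": change,
        "characteristics": char, "change_predictors": coef, "cox": cox, "log": log,
    }
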