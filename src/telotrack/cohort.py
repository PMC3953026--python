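"""Synthetic two-examination cohort, qPCR plate, and registry generator.

Emulates the statistical structure a repeat-measurement telomere study
assumes, so that the full pipeline (plate quantification, 10-year change,
trend tests, proportional-hazards models) runs without access to individual-
level cohort data:

* cross-sectional true telomere length declines ~20 bp per year of age and
  age explains ~8% of measured variance;
* true annual attrition averages -19.3 bp/year, independent (by default) of
  every lifestyle variable;
* lifestyle (smoking, tobacco, weight/BMI, exercise, alcohol) is confounded
  with age, which induces the classic cross-sectional lifestyle-telomere
  associations without any causal effect on attrition;
* mortality hazard after the second examination rises with age and with
  shorter true telomere length (Gompertz); disease endpoints carry concrete
  ICD-8/ICD-10 codes; a small fraction emigrates.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .qpcr import DEFAULT_ANCHOR_BP, Assay, Role

__all__ = ["GeneratorConfig", "generate_cohort", "synthesize_plate_cts", "simulate_registry"]

TL_FLOOR_BP = 200.0  # positivity floor so log2(TL/anchor) is always defined

# Representative 3-character diagnosis categories per endpoint; every code
# lies inside the endpoint's inclusive extraction range.
ENDPOINT_CODES: dict[str, dict[str, list[str]]] = {
    "cancer": {"ICD10": ["C18", "C34", "C50", "C61", "C67", "D05"], "ICD8": []},
    "copd": {"ICD10": ["J41", "J42", "J43", "J44"], "ICD8": ["491", "492"]},
    "dm2": {"ICD10": ["E10", "E11", "E14"], "ICD8": ["249", "250"]},
    "icvd": {"ICD10": ["I61", "I63", "I64", "I66", "G45"], "ICD8": ["431", "433", "436", "438"]},
    "ihd": {"ICD10": ["I20", "I21", "I24", "I25"], "ICD8": ["410", "411", "414"]},
}

# Annual first-event rates at the reference age (70 y at second examination),
# sized so incident counts over ~8 years of follow-up resemble a general-
# population cohort of this age range.
DISEASE_RATES: dict[str, float] = {
    "cancer": 0.016,
    "copd": 0.010,
    "dm2": 0.007,
    "icvd": 0.007,
    "ihd": 0.016,
}


@dataclass
class GeneratorConfig:
    n_participants: int = 4576
    seed: int = 0
    age_min: float = 40.0
    age_max: float = 80.0
    tl_intercept_bp: float = 5600.0
    tl_age_slope_bp_per_year: float = -20.0
    between_person_sd_bp: float = 700.0
    measurement_sd_bp: float = 500.0
    mean_attrition_bp_per_year: float = -19.3
    attrition_sd_bp_per_year: float = 5.0
    lifestyle_effect_on_attrition: float = 0.0  # bp/year per inactivity flag; 0 = null
    exam2_batch_offset_bp: float = 300.0
    exam_gap_mean_years: float = 9.3
    exam_gap_sd_years: float = 0.43
    male_fraction: float = 0.43
    missing_rate: float = 0.005
    # lifestyle-age confounding (per-year-of-age gradients)
    smoking_prob_at_60: float = 0.38
    smoking_prob_age_slope: float = 0.006
    weight_mean_at_60_kg: float = 75.0
    weight_age_slope_kg: float = 0.25
    weight_sd_kg: float = 12.0
    exercise_mean_at_60_h: float = 6.0
    exercise_age_slope_h: float = -0.08
    exercise_sd_h: float = 3.0
    alcohol_mean_g_week: float = 130.0
    alcohol_sd_g_week: float = 90.0
    # mortality model (Gompertz; reference: age 70 at exam 2, true TL 4300 bp)
    mortality_baseline_hazard: float = 0.016
    mortality_gompertz_shape: float = 0.09
    mortality_age_log_hr: float = 0.09
    mortality_tl_log_hr_per_kbp: float = 0.25
    emigration_fraction: float = 39.0 / 4576.0
    disease_prevalence_window_years: float = 15.0
    # plate synthesis
    wells_sd_ct: float = 0.05
    plate_shift_sd: float = 0.005
    plate_shift_mode: Literal["multiplicative", "additive"] = "multiplicative"
    samples_per_plate: int = 92
    calibrator_ct_tel: float = 13.0
    calibrator_ct_alb: float = 15.0
    internal_control_tl_bp: float = 2577.0
    anchor_bp: float = DEFAULT_ANCHOR_BP

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be > 0")
        if self.exam_gap_mean_years <= 0:
            raise ValueError("exam gap must be > 0")
        for name in ("between_person_sd_bp", "measurement_sd_bp",
                     "attrition_sd_bp_per_year", "exam_gap_sd_years", "wells_sd_ct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _exam_frame(cfg, pid, exam_id, dates, age, sex, smoke, tobacco, weight,
                height, alcohol, exercise, tl, rng):
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "exam_id": exam_id,
            "exam_date": dates,
            "age": age,
            "sex": np.where(sex == 1, "male", "female"),
            "current_smoking": smoke.astype(float),
            "tobacco_g_day": tobacco,
            "weight_kg": weight,
            "height_m": height,
            "bmi": weight / height**2,
            "alcohol_g_week": alcohol,
            "exercise_h_week": exercise,
            "tl_bp": tl,
        }
    )
    if cfg.missing_rate > 0:
        for col in ("current_smoking", "tobacco_g_day", "weight_kg",
                    "alcohol_g_week", "exercise_h_week"):
            mask = rng.random(len(df)) < cfg.missing_rate
            df.loc[mask, col] = np.nan
        df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    return df


def generate_cohort(config: GeneratorConfig | None = None) -> dict[str, pd.DataFrame]:
    """Generate exam-1 and exam-2 tables plus the latent truth table.

    Returns ``{"exam1": ..., "exam2": ..., "truth": ...}``.  The truth table
    carries the noiseless telomere lengths and per-person attrition rates used
    by parameter-recovery tests; the exam tables carry the measured values
    (true + Gaussian measurement error, exam-2 shifted by the configured
    batch offset emulating a storage/isolation drift).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    pid = np.array([f"P{i:06d}" for i in range(n)])

    age1 = rng.uniform(cfg.age_min, cfg.age_max, n)
    sex = (rng.random(n) < cfg.male_fraction).astype(int)
    gap = np.clip(rng.normal(cfg.exam_gap_mean_years, cfg.exam_gap_sd_years, n), 7.0, 12.0)
    age2 = age1 + gap

    base1 = pd.Timestamp("1991-09-01")
    d1 = base1 + pd.to_timedelta(np.floor(rng.uniform(0, 1000, n)), unit="D")
    d2 = d1 + pd.to_timedelta(np.round(gap * 365.25), unit="D")

    person = rng.normal(0.0, cfg.between_person_sd_bp, n)
    true1 = np.maximum(
        cfg.tl_intercept_bp + cfg.tl_age_slope_bp_per_year * age1 + person, TL_FLOOR_BP
    )

    # lifestyle, confounded with age only
    def smoke_prob(age):
        return np.clip(cfg.smoking_prob_at_60 + cfg.smoking_prob_age_slope * (age - 60), 0.02, 0.95)

    smoke1 = (rng.random(n) < smoke_prob(age1)).astype(int)
    tobacco1 = np.where(smoke1 == 1, np.clip(rng.normal(16, 7, n), 1, None), 0.0)
    height = np.clip(rng.normal(1.67 + 0.12 * sex, 0.07, n), 1.40, 2.10)
    weight1 = np.clip(
        rng.normal(cfg.weight_mean_at_60_kg + cfg.weight_age_slope_kg * (age1 - 60) + 6 * sex,
                   cfg.weight_sd_kg, n), 38, None)
    exercise1 = np.clip(
        rng.normal(cfg.exercise_mean_at_60_h + cfg.exercise_age_slope_h * (age1 - 60),
                   cfg.exercise_sd_h, n), 0, None)
    alcohol1 = np.clip(
        rng.normal(cfg.alcohol_mean_g_week + 40 * sex, cfg.alcohol_sd_g_week, n), 0, None)

    inactive1 = (exercise1 < 4).astype(float)
    attrition = (
        rng.normal(cfg.mean_attrition_bp_per_year, cfg.attrition_sd_bp_per_year, n)
        + cfg.lifestyle_effect_on_attrition * inactive1
    )
    true2 = np.maximum(true1 + attrition * gap, TL_FLOOR_BP)

    meas1 = np.maximum(true1 + rng.normal(0, cfg.measurement_sd_bp, n), TL_FLOOR_BP)
    meas2 = np.maximum(
        true2 + rng.normal(0, cfg.measurement_sd_bp, n) + cfg.exam2_batch_offset_bp, TL_FLOOR_BP
    )

    # exam-2 lifestyle: persistence plus continued age drift
    quit = (rng.random(n) < 0.25) & (smoke1 == 1)
    start = (rng.random(n) < 0.02) & (smoke1 == 0)
    smoke2 = np.where(quit, 0, np.where(start, 1, smoke1))
    tobacco2 = np.where(smoke2 == 1, np.clip(tobacco1 + rng.normal(0, 3, n), 1, None), 0.0)
    tobacco2 = np.where((smoke2 == 1) & (tobacco1 == 0), np.clip(rng.normal(14, 6, n), 1, None), tobacco2)
    weight2 = np.clip(weight1 + cfg.weight_age_slope_kg * gap + rng.normal(0, 4, n), 38, None)
    exercise2 = np.clip(exercise1 + cfg.exercise_age_slope_h * gap + rng.normal(0, 1.5, n), 0, None)
    alcohol2 = np.clip(alcohol1 + rng.normal(0, 40, n), 0, None)

    exam1 = _exam_frame(cfg, pid, "exam1", d1, age1, sex, smoke1, tobacco1,
                        weight1, height, alcohol1, exercise1, meas1, rng)
    exam2 = _exam_frame(cfg, pid, "exam2", d2, age2, sex, smoke2, tobacco2,
                        weight2, height, alcohol2, exercise2, meas2, rng)
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "true_tl_exam1_bp": true1,
            "true_tl_exam2_bp": true2,
            "true_attrition_bp_per_year": attrition,
            "gap_years": gap,
            "inactive_exam1": inactive1,
        }
    )
    return {"exam1": exam1, "exam2": exam2, "truth": truth}


def synthesize_plate_cts(
    samples: pd.DataFrame,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    tl_column: str = "tl_bp",
    id_column: str = "participant_id",
    plate_prefix: str = "PL",
) -> pd.DataFrame:
    """Emit a well-level Ct table whose quantification recovers ``tl_column``.

    Inverse of the delta-delta-Ct pipeline: the albumin Ct is drawn around 15
    cycles, the telomere Ct is placed so that
    ``Ct_alb - Ct_tel - delta_Ct_calibrator = log2(TL / anchor_bp)``, then a
    per-plate effect (multiplicative on the Ct scale by default, matching what
    the calibrator-ratio normalization removes exactly) and per-well Gaussian
    noise are applied.  Participants get quadruplicate wells per assay;
    calibrator and internal control get triplicates on every plate.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tl = np.asarray(samples[tl_column], dtype=float)
    if np.any(~np.isfinite(tl)) or np.any(tl <= 0):
        raise ValueError("telomere lengths must be finite and positive")
    ids = np.asarray(samples[id_column], dtype=object)

    delta_ct_cal = cfg.calibrator_ct_alb - cfg.calibrator_ct_tel
    n_plates = int(np.ceil(len(ids) / cfg.samples_per_plate))
    rows: list[dict] = []

    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p:04d}"
        if cfg.plate_shift_mode == "multiplicative":
            shift_tel = float(np.exp(rng.normal(0, cfg.plate_shift_sd)))
            shift_alb = float(np.exp(rng.normal(0, cfg.plate_shift_sd)))
            tel_fn = lambda ct: ct * shift_tel  # noqa: E731
            alb_fn = lambda ct: ct * shift_alb  # noqa: E731
        else:
            shift_tel = float(rng.normal(0, cfg.plate_shift_sd * 15.0))
            shift_alb = float(rng.normal(0, cfg.plate_shift_sd * 15.0))
            tel_fn = lambda ct: ct + shift_tel  # noqa: E731
            alb_fn = lambda ct: ct + shift_alb  # noqa: E731

        def emit(sample_id, role, tl_bp, n_rep):
            ideal_alb = cfg.calibrator_ct_alb
            ideal_tel = ideal_alb - (np.log2(tl_bp / cfg.anchor_bp) + delta_ct_cal)
            for assay, ideal, fn in (
                (Assay.TELOMERE, ideal_tel, tel_fn),
                (Assay.ALBUMIN, ideal_alb, alb_fn),
            ):
                noise = rng.normal(0, cfg.wells_sd_ct, n_rep) if cfg.wells_sd_ct > 0 else np.zeros(n_rep)
                for k in range(n_rep):
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "sample_id": sample_id,
                            "role": role.value,
                            "assay": assay.value,
                            "ct": fn(ideal) + noise[k],
                            "primer_dimer": False,
                        }
                    )

        emit("K562", Role.CALIBRATOR, cfg.anchor_bp, 3)
        emit("NTERA-2", Role.INTERNAL_CONTROL, cfg.internal_control_tl_bp, 3)
        lo, hi = p * cfg.samples_per_plate, min((p + 1) * cfg.samples_per_plate, len(ids))
        for i in range(lo, hi):
            emit(ids[i], Role.PARTICIPANT, tl[i], 4)

    return pd.DataFrame(rows)


def _gompertz_times(rng, n, baseline, shape, log_hr):
    """Event times (years) for hazard baseline*exp(shape*t)*exp(log_hr)."""
    e = rng.exponential(1.0, n)
    a = baseline * np.exp(log_hr)
    return np.log1p(shape * e / a) / shape


def simulate_registry(
    truth: pd.DataFrame,
    exam2: pd.DataFrame,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate dated death, diagnosis, and emigration events.

    Death follows a Gompertz hazard from the second examination with
    log-hazard linear in attained age and in (-true TL / 1000); disease first-
    event times use constant endpoint-specific hazards with an age gradient,
    started ``disease_prevalence_window_years`` before the second examination
    so a realistic fraction is prevalent (and later excluded).  Diagnosis
    events before 1994 carry ICD-8 codes where the endpoint has an ICD-8 code
    set, ICD-10 otherwise.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    t = truth.merge(exam2[["participant_id", "exam_date", "age"]], on="participant_id")
    n = len(t)
    d2 = pd.to_datetime(t["exam_date"]).to_numpy()
    age2 = t["age"].to_numpy(dtype=float)
    tl2 = t["true_tl_exam2_bp"].to_numpy(dtype=float)

    rows: list[dict] = []

    log_hr = (
        cfg.mortality_age_log_hr * (age2 - 70.0)
        + cfg.mortality_tl_log_hr_per_kbp * (-(tl2 - 4300.0) / 1000.0)
    )
    death_years = _gompertz_times(
        rng, n, cfg.mortality_baseline_hazard, cfg.mortality_gompertz_shape, log_hr
    )
    death_dates = d2 + (death_years * 365.25).round().astype("timedelta64[D]")

    emigrates = rng.random(n) < cfg.emigration_fraction
    emi_years = rng.uniform(0.0, 9.0, n)
    emi_dates = d2 + (emi_years * 365.25).round().astype("timedelta64[D]")
    # an emigrant leaves the registries: no death observed after emigration
    emigrates &= emi_years < death_years

    icd10_switch = np.datetime64("1994-01-01")
    for name, rate in DISEASE_RATES.items():
        start = d2 - np.timedelta64(int(cfg.disease_prevalence_window_years * 365.25), "D")
        times = rng.exponential(1.0, n) / (rate * np.exp(0.05 * (age2 - 70.0)))
        has_event = times < cfg.disease_prevalence_window_years + 40.0
        ev_dates = start + (times * 365.25).round().astype("timedelta64[D]")
        codes10 = ENDPOINT_CODES[name]["ICD10"]
        codes8 = ENDPOINT_CODES[name]["ICD8"]
        for i in np.flatnonzero(has_event):
            if death_years[i] * 365.25 < (ev_dates[i] - d2[i]) / np.timedelta64(1, "D"):
                continue  # died before the diagnosis would occur
            if emigrates[i] and ev_dates[i] > emi_dates[i]:
                continue
            use8 = bool(codes8) and ev_dates[i] < icd10_switch
            codes = codes8 if use8 else codes10
            rows.append(
                {
                    "participant_id": t["participant_id"].iloc[i],
                    "event_date": pd.Timestamp(ev_dates[i]),
                    "event_type": "diagnosis",
                    "icd_version": "ICD8" if use8 else "ICD10",
                    "icd_code": codes[rng.integers(len(codes))],
                }
            )

    for i in range(n):
        if emigrates[i]:
            rows.append(
                {
                    "participant_id": t["participant_id"].iloc[i],
                    "event_date": pd.Timestamp(emi_dates[i]),
                    "event_type": "emigration",
                    "icd_version": "",
                    "icd_code": "",
                }
            )
        else:
            rows.append(
                {
                    "participant_id": t["participant_id"].iloc[i],
                    "event_date": pd.Timestamp(death_dates[i]),
                    "event_type": "death",
                    "icd_version": "",
                    "icd_code": "",
                }
            )

    out = pd.DataFrame(rows).sort_values(["participant_id", "event_date"], kind="stable")
    return out.reset_index(drop=True)
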