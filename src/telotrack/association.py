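"""Cross-sectional trend tests, change-predictor regressions, ICD endpoint
extraction, follow-up construction, and proportional-hazards analyses.

The analytical contrast at the heart of the package: lifestyle variables
(smoking, BMI, inactivity) show strong monotone gradients across
cross-sectional telomere-length quartiles — yet, because those gradients are
driven by age confounding, the same variables show null associations with
within-person telomere change and change quartiles show null hazard ratios
for mortality and morbidity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .qpcr import DEFAULT_ANCHOR_BP

__all__ = [
    "EndpointDefinition",
    "ENDPOINTS",
    "ALCOHOL_G_PER_UNIT",
    "classify_heavy_alcohol",
    "classify_physical_inactivity",
    "impute_covariates",
    "trend_test_quartiles",
    "fit_change_predictors",
    "extract_endpoint_events",
    "build_followup",
    "fit_cox_quartiles",
    "ph_diagnostic",
]

ALCOHOL_G_PER_UNIT = 12.0  # one unit of alcohol = 12 g
HEAVY_ALCOHOL_G_WEEK = {"female": 87.5, "male": 175.0}
INACTIVITY_THRESHOLD_H_WEEK = 4.0


# --------------------------------------------------------------------------
# covariate definitions

def classify_heavy_alcohol(sex: str, g_per_week: float) -> bool:
    """Heavy intake: strictly above 87.5 g/week (women) or 175 g/week (men)."""
    if g_per_week < 0:
        raise ValueError("alcohol intake cannot be negative")
    try:
        threshold = HEAVY_ALCOHOL_G_WEEK[str(sex).lower()]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}") from None
    return g_per_week > threshold


def classify_physical_inactivity(exercise_h_week: float) -> bool:
    """Inactive: less than 4 hours of weekly exercise."""
    if exercise_h_week < 0:
        raise ValueError("exercise hours cannot be negative")
    return exercise_h_week < INACTIVITY_THRESHOLD_H_WEEK


def impute_covariates(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("tobacco_g_day", "weight_kg", "alcohol_g_week", "exercise_h_week"),
    categorical: tuple[str, ...] = ("current_smoking",),
) -> pd.DataFrame:
    """Single-pass imputation for multivariable models.

    Missing continuous covariates are replaced by the prediction of a least-
    squares fit of that covariate on age and sex among complete cases;
    missing categorical covariates get an explicit ``"missing"`` level.
    ``<col>_imputed`` boolean columns flag every filled cell.
    """
    out = cohort.copy()
    male = (out["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    age = out["age"].to_numpy(float)
    design = np.column_stack([np.ones(len(out)), age, male])
    for col in continuous:
        if col not in out.columns:
            continue
        y = out[col].to_numpy(float)
        miss = ~np.isfinite(y)
        if not miss.any():
            out[f"{col}_imputed"] = False
            continue
        if (~miss).sum() == 0:
            raise ValueError(f"covariate {col!r} has no complete cases")
        beta, *_ = np.linalg.lstsq(design[~miss], y[~miss], rcond=None)
        y[miss] = design[miss] @ beta
        out[col] = y
        out[f"{col}_imputed"] = miss
    for col in categorical:
        if col not in out.columns:
            continue
        vals = out[col]
        miss = vals.isna().to_numpy()
        out[col] = vals.astype(object).where(~miss, "missing")
        out[f"{col}_imputed"] = miss
    return out


# --------------------------------------------------------------------------
# trend tests

def _cochran_armitage(successes: np.ndarray, totals: np.ndarray, scores: np.ndarray):
    """Two-sided Cochran-Armitage score test for trend in proportions."""
    n = totals.sum()
    pbar = successes.sum() / n
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    num = np.sum(scores * (successes - totals * pbar))
    den = pbar * (1 - pbar) * (np.sum(totals * scores**2) - np.sum(totals * scores) ** 2 / n)
    if den <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(den)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def trend_test_quartiles(covariate, quartile_labels) -> dict[str, float]:
    """Two-sided test for monotone trend across quartiles 1-4.

    Continuous covariates: OLS slope on the quartile index.  Binary (0/1)
    covariates: Cochran-Armitage score test for linear trend in proportions.
    Returns ``{"estimate", "p_value"}``; constant covariates give estimate 0
    and p = 1.  Missing covariate values are dropped pairwise.
    """
    y = np.asarray(covariate, dtype=float)
    q = np.asarray(quartile_labels, dtype=float)
    ok = np.isfinite(y) & np.isfinite(q)
    y, q = y[ok], q[ok]
    if np.unique(q).size < 2:
        raise ValueError("need at least two populated quartiles")
    if np.ptp(y) == 0:
        return {"estimate": 0.0, "p_value": 1.0}
    uniq = np.unique(y)
    if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
        levels = np.unique(q)
        succ = np.array([y[q == lv].sum() for lv in levels])
        tot = np.array([(q == lv).sum() for lv in levels])
        z, p = _cochran_armitage(succ, tot, levels)
        return {"estimate": z, "p_value": p}
    model = sm.OLS(y, sm.add_constant(q)).fit()
    return {"estimate": float(model.params[1]), "p_value": float(model.pvalues[1])}


# --------------------------------------------------------------------------
# change-predictor regressions

CHANGE_PREDICTOR_TERMS = [
    "baseline_tl_bp",
    "age_baseline",
    "tobacco_baseline_g_day",
    "tobacco_between_g_day",
    "weight_baseline_kg",
    "weight_change_pct",
    "alcohol_baseline_units_day",
    "alcohol_between_units_day",
    "activity_baseline_h_week",
    "activity_between_h_week",
]

LIFESTYLE_TERMS = CHANGE_PREDICTOR_TERMS[2:]


def build_predictor_table(exam1: pd.DataFrame, exam2: pd.DataFrame) -> pd.DataFrame:
    """Assemble the standard predictor set from the two examinations.

    "Between examinations" exposures are the mean of the two examinations'
    reports.  Alcohol is converted from g/week to 12-g units per day.
    """
    e1 = exam1.set_index("participant_id")
    e2 = exam2.set_index("participant_id")
    common = e1.index.intersection(e2.index)
    e1, e2 = e1.loc[common], e2.loc[common]
    g_day = 7.0 * ALCOHOL_G_PER_UNIT
    return pd.DataFrame(
        {
            "participant_id": common,
            "baseline_tl_bp": e1["tl_bp"].to_numpy(float),
            "age_baseline": e1["age"].to_numpy(float),
            "tobacco_baseline_g_day": e1["tobacco_g_day"].to_numpy(float),
            "tobacco_between_g_day": (e1["tobacco_g_day"].to_numpy(float)
                                      + e2["tobacco_g_day"].to_numpy(float)) / 2,
            "weight_baseline_kg": e1["weight_kg"].to_numpy(float),
            "weight_change_pct": (e2["weight_kg"].to_numpy(float) - e1["weight_kg"].to_numpy(float))
            / e1["weight_kg"].to_numpy(float) * 100.0,
            "alcohol_baseline_units_day": e1["alcohol_g_week"].to_numpy(float) / g_day,
            "alcohol_between_units_day": (e1["alcohol_g_week"].to_numpy(float)
                                          + e2["alcohol_g_week"].to_numpy(float)) / 2 / g_day,
            "activity_baseline_h_week": e1["exercise_h_week"].to_numpy(float),
            "activity_between_h_week": (e1["exercise_h_week"].to_numpy(float)
                                        + e2["exercise_h_week"].to_numpy(float)) / 2,
        }
    ).reset_index(drop=True)


def _check_design(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        for j, col in enumerate(X.columns):
            reduced = np.delete(arr, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"collinear design: term {col!r} is redundant")
        raise ValueError("collinear design")


def fit_change_predictors(
    change,
    predictors: pd.DataFrame,
    mode: str = "univariable",
    anchor_bp: float = DEFAULT_ANCHOR_BP,
) -> pd.DataFrame:
    """Linear models of 10-year telomere change on the standard predictors.

    ``univariable`` fits one predictor at a time; ``multivariable`` fits all
    jointly.  Rows with a missing outcome or (for the multivariable fit)
    any missing predictor are dropped.  The baseline-TL coefficient is also
    reported on the T/S-ratio scale (``baseline_ts_ratio`` row) by scaling
    the basepair coefficient by ``anchor_bp``, since the two regressors are
    exactly proportional.  Returns a table of beta, 95% CI, and two-sided p.
    """
    if mode not in ("univariable", "multivariable"):
        raise ValueError(f"unknown mode {mode!r}")
    y_all = np.asarray(change, dtype=float)
    terms = [t for t in CHANGE_PREDICTOR_TERMS if t in predictors.columns]
    rows = []

    def one_fit(X: pd.DataFrame):
        mask = np.isfinite(y_all) & np.isfinite(X.to_numpy(float)).all(axis=1)
        if mask.sum() <= X.shape[1] + 1:
            raise ValueError("not enough complete cases")
        Xc = X.loc[mask]
        _check_design(Xc)
        return sm.OLS(y_all[mask], sm.add_constant(Xc.to_numpy(float))).fit(), mask

    if mode == "univariable":
        fits = {t: one_fit(predictors[[t]]) for t in terms}
        for t in terms:
            res, mask = fits[t]
            ci = res.conf_int()
            rows.append((t, int(mask.sum()), res.params[1], ci[1][0], ci[1][1], res.pvalues[1]))
    else:
        res, mask = one_fit(predictors[terms])
        ci = res.conf_int()
        for j, t in enumerate(terms, start=1):
            rows.append((t, int(mask.sum()), res.params[j], ci[j][0], ci[j][1], res.pvalues[j]))

    out = pd.DataFrame(rows, columns=["term", "n", "beta", "ci_low", "ci_high", "p_value"])
    if "baseline_tl_bp" in set(out["term"]):
        base = out[out["term"] == "baseline_tl_bp"].iloc[0]
        ts_row = pd.DataFrame(
            [{
                "term": "baseline_ts_ratio",
                "n": base["n"],
                "beta": base["beta"] * anchor_bp,
                "ci_low": base["ci_low"] * anchor_bp,
                "ci_high": base["ci_high"] * anchor_bp,
                "p_value": base["p_value"],
            }]
        )
        out = pd.concat([out.iloc[:1], ts_row, out.iloc[1:]], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# endpoints

@dataclass(frozen=True)
class EndpointDefinition:
    """ICD-coded endpoint: inclusive 3-character category ranges per ICD
    revision, plus the registry censoring date for that endpoint."""

    name: str
    icd8_ranges: tuple[tuple[int, int], ...]
    icd10_ranges: tuple[tuple[str, str], ...]
    censor_date: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2011-05-10"))


ENDPOINTS: dict[str, EndpointDefinition] = {
    "all_cause_mortality": EndpointDefinition(
        "all_cause_mortality", (), (), pd.Timestamp("2011-06-07")
    ),
    "cancer": EndpointDefinition(
        "cancer", (), (("C00", "D09"),), pd.Timestamp("2009-12-31")
    ),
    "copd": EndpointDefinition(
        "copd", ((491, 492),), (("J41", "J44"),), pd.Timestamp("2011-05-10")
    ),
    "dm2": EndpointDefinition(
        "dm2", ((249, 250),), (("E10", "E14"),), pd.Timestamp("2011-05-10")
    ),
    "icvd": EndpointDefinition(
        "icvd", ((431, 438),), (("I61", "I66"), ("G45", "G45")), pd.Timestamp("2011-05-10")
    ),
    "ihd": EndpointDefinition(
        "ihd", ((410, 414),), (("I20", "I25"),), pd.Timestamp("2011-05-10")
    ),
}

_ICD10_RE = re.compile(r"^[A-Z]\d\d")
_ICD8_RE = re.compile(r"^\d{3}")


def _icd_category(code: str, version: str) -> str | None:
    code = str(code).strip().upper().replace(".", "")
    if version == "ICD10":
        m = _ICD10_RE.match(code)
    elif version == "ICD8":
        m = _ICD8_RE.match(code)
    else:
        return None
    return m.group(0) if m else None


def code_matches(code: str, version: str, definition: EndpointDefinition) -> bool:
    """Whether a diagnosis code's 3-character category falls in the endpoint's
    inclusive ranges for its ICD revision (subcodes inherit the category)."""
    cat = _icd_category(code, version)
    if cat is None:
        raise ValueError(f"unparseable {version} code: {code!r}")
    if version == "ICD8":
        v = int(cat)
        return any(lo <= v <= hi for lo, hi in definition.icd8_ranges)
    return any(lo <= cat <= hi for lo, hi in definition.icd10_ranges)


def extract_endpoint_events(
    registry: pd.DataFrame, definition: EndpointDefinition
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Earliest matching diagnosis date per participant for one endpoint.

    Unparseable codes are skipped and returned in a rejects table rather than
    aborting the extraction.  Order-independent and idempotent: output is
    sorted by participant and depends only on the set of input rows.
    """
    diag = registry[registry["event_type"] == "diagnosis"]
    keep, rejects = [], []
    for row in diag.itertuples(index=False):
        try:
            if code_matches(row.icd_code, row.icd_version, definition):
                keep.append(row)
        except ValueError as exc:
            rejects.append({**row._asdict(), "reason": str(exc)})
    if keep:
        matched = pd.DataFrame(keep)
        matched["event_date"] = pd.to_datetime(matched["event_date"])
        first = (
            matched.sort_values(["participant_id", "event_date"], kind="stable")
            .groupby("participant_id", as_index=False)
            .first()[["participant_id", "event_date"]]
        )
    else:
        first = pd.DataFrame(columns=["participant_id", "event_date"])
    return first.sort_values("participant_id").reset_index(drop=True), pd.DataFrame(rejects)


def build_followup(
    cohort: pd.DataFrame,
    registry: pd.DataFrame,
    definition: EndpointDefinition,
) -> pd.DataFrame:
    """Per-participant follow-up interval for one endpoint.

    Entry is the second-examination (blood sampling) date.  Exit is the
    earliest of: endpoint diagnosis (or death, for all-cause mortality),
    death (as censoring for disease endpoints), emigration, or the
    endpoint's registry censoring date.  Participants whose first matching
    diagnosis predates entry are excluded as prevalent cases.

    ``cohort`` needs ``participant_id`` and ``exam_date`` (exam-2) columns;
    extra columns are carried through as covariates.
    """
    entry = pd.to_datetime(cohort["exam_date"])
    out = cohort.copy()
    out["entry_date"] = entry.to_numpy()

    deaths = registry[registry["event_type"] == "death"].set_index("participant_id")["event_date"]
    emi = registry[registry["event_type"] == "emigration"].set_index("participant_id")["event_date"]
    out["death_date"] = pd.to_datetime(out["participant_id"].map(deaths))
    out["emigration_date"] = pd.to_datetime(out["participant_id"].map(emi))

    if definition.name == "all_cause_mortality":
        out["event_date"] = out["death_date"]
    else:
        events, _ = extract_endpoint_events(registry, definition)
        ev = events.set_index("participant_id")["event_date"]
        out["event_date"] = pd.to_datetime(out["participant_id"].map(ev))

    prevalent = out["event_date"].notna() & (out["event_date"] <= out["entry_date"])
    out = out[~prevalent].copy()

    candidates = [out["event_date"], out["emigration_date"]]
    if definition.name != "all_cause_mortality":
        candidates.append(out["death_date"])
    candidates.append(pd.Series(definition.censor_date, index=out.index))
    exit_date = pd.concat(candidates, axis=1).min(axis=1)
    out["exit_date"] = exit_date
    out["event_indicator"] = out["event_date"].notna() & (out["event_date"] == exit_date)
    out["followup_years"] = (out["exit_date"] - out["entry_date"]).dt.days / 365.25
    bad = out["followup_years"] < 0
    if bad.any():
        raise AssertionError(
            f"{int(bad.sum())} participants exit before entry for {definition.name}"
        )
    out.loc[out["followup_years"] == 0, "followup_years"] = 0.5 / 365.25
    out.attrs["n_prevalent_excluded"] = int(prevalent.sum())
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# proportional hazards

ADJUSTMENT_COVARIATES = [
    "age", "male", "current_smoking_yes", "tobacco_g_day", "bmi",
    "heavy_alcohol", "physical_inactivity",
]


def _adjustment_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Standard multivariable adjustment set from exam-level covariates."""
    imp = impute_covariates(df)
    smoking = imp["current_smoking"]
    X = pd.DataFrame(index=imp.index)
    X["age"] = imp["age"].astype(float)
    X["male"] = (imp["sex"].astype(str).str.lower() == "male").astype(float)
    X["current_smoking_yes"] = (smoking == 1.0).astype(float)
    X["current_smoking_missing"] = (smoking == "missing").astype(float)
    X["tobacco_g_day"] = imp["tobacco_g_day"].astype(float)
    X["bmi"] = (imp["weight_kg"] / imp["height_m"] ** 2).astype(float)
    X["heavy_alcohol"] = [
        float(classify_heavy_alcohol(s, g))
        for s, g in zip(imp["sex"], imp["alcohol_g_week"].astype(float))
    ]
    X["physical_inactivity"] = [
        float(classify_physical_inactivity(h)) for h in imp["exercise_h_week"].astype(float)
    ]
    if X["current_smoking_missing"].sum() == 0:
        X = X.drop(columns="current_smoking_missing")
    return X


def fit_cox_quartiles(
    followup: pd.DataFrame,
    quartile_column: str = "change_quartile",
    adjust: pd.DataFrame | None = None,
) -> dict:
    """Proportional-hazards model over quartiles with a trend test.

    Quartile 1 is the reference (HR fixed at 1.00); the remaining quartiles
    enter as indicators.  The trend p comes from a second model with the
    ordinal quartile score as a single covariate.  Ties are handled by
    lifelines' default Efron approximation.  Returns
    ``{"table": DataFrame, "trend_p": float, "trend_log_hr": float}``.
    """
    if followup["event_indicator"].sum() == 0:
        raise ValueError("no events in follow-up table")
    base = pd.DataFrame(
        {
            "T": followup["followup_years"].to_numpy(float),
            "E": followup["event_indicator"].to_numpy(bool).astype(int),
        }
    )
    q = followup[quartile_column].to_numpy(int)
    dummies = pd.DataFrame({f"q{k}": (q == k).astype(float) for k in (2, 3, 4)})
    X = pd.concat([base, dummies.set_index(base.index)], axis=1)
    if adjust is not None:
        X = pd.concat([X, adjust.set_index(base.index).astype(float)], axis=1)

    cph = CoxPHFitter()
    cph.fit(X, duration_col="T", event_col="E")
    summ = cph.summary
    rows = [{"quartile": 1, "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
             "n": int((q == 1).sum()), "events": int(base["E"][q == 1].sum())}]
    for k in (2, 3, 4):
        s = summ.loc[f"q{k}"]
        rows.append(
            {
                "quartile": k,
                "hr": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef lower 95%"])),
                "ci_high": float(np.exp(s["coef upper 95%"])),
                "n": int((q == k).sum()),
                "events": int(base["E"][q == k].sum()),
            }
        )

    Xt = base.copy()
    Xt["quartile_score"] = q.astype(float)
    if adjust is not None:
        Xt = pd.concat([Xt, adjust.set_index(base.index).astype(float)], axis=1)
    cph_t = CoxPHFitter()
    cph_t.fit(Xt, duration_col="T", event_col="E")
    st = cph_t.summary.loc["quartile_score"]
    return {
        "table": pd.DataFrame(rows),
        "trend_p": float(st["p"]),
        "trend_log_hr": float(st["coef"]),
    }


def ph_diagnostic(
    followup: pd.DataFrame,
    group_column: str,
    survival_range: tuple[float, float] = (0.10, 0.90),
) -> dict:
    """Log-minus-log survival curves for a visual/automated parallelism check.

    Returns per-group tables of (ln t, -ln(-ln S(t))) and a distance
    statistic: the maximum over the shared time range, across group pairs, of
    the absolute deviation of the curve difference from its own median —
    near zero when hazards are proportional (curves parallel).  Curves are
    restricted to ``survival_range`` because the transform's sampling noise
    diverges as S(t) approaches 0 or 1 (d/dS = 1/(S ln S)).
    """
    lo_s, hi_s = survival_range
    curves: dict = {}
    for g, grp in followup.groupby(group_column):
        km = KaplanMeierFitter()
        km.fit(grp["followup_years"], grp["event_indicator"].astype(bool))
        sf = km.survival_function_.iloc[:, 0]
        sf = sf[(sf > lo_s) & (sf < hi_s)]
        t = sf.index.to_numpy(float)
        keep = t > 0
        if keep.sum() == 0:
            curves[g] = pd.DataFrame(columns=["ln_t", "neg_ln_neg_ln_s"])
            continue
        curves[g] = pd.DataFrame(
            {"ln_t": np.log(t[keep]), "neg_ln_neg_ln_s": -np.log(-np.log(sf.to_numpy()[keep]))}
        )
    keys = [k for k in curves if len(curves[k])]
    dist = 0.0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = curves[keys[i]], curves[keys[j]]
            lo = max(a["ln_t"].min(), b["ln_t"].min())
            hi = min(a["ln_t"].max(), b["ln_t"].max())
            if hi <= lo:
                continue
            grid = np.linspace(lo, hi, 200)
            fa = np.interp(grid, a["ln_t"], a["neg_ln_neg_ln_s"])
            fb = np.interp(grid, b["ln_t"], b["neg_ln_neg_ln_s"])
            diff = fa - fb
            dist = max(dist, float(np.max(np.abs(diff - np.median(diff)))))
    return {"curves": curves, "distance": dist}
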