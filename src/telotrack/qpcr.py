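"""Absolute leukocyte telomere length from monochrome multiplex qPCR plates.

The assay amplifies the telomere repeat and the single-copy albumin gene in
the same well.  Per participant, replicate Ct values are QC-filtered and
averaged, normalized across plates against a calibrator DNA (K562) run on
every plate, and converted through the delta-delta-Ct formula to a T/S ratio
and an absolute telomere length in basepairs anchored at the calibrator's
5,290 bp:

    delta_Ct_X   = Ct_alb(X, calibrated) - Ct_tel(X, calibrated)
    delta_delta  = delta_Ct_X - delta_Ct_calibrator
    absTL (bp)   = 2**delta_delta * anchor_bp

Plate normalization is multiplicative on the Ct scale: every Ct on plate P is
scaled by factor = (global calibrator mean Ct) / (plate-P calibrator mean Ct),
computed per assay, so that the calibrator itself always quantifies to
exactly anchor_bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_ANCHOR_BP = 5290.0

__all__ = [
    "DEFAULT_ANCHOR_BP",
    "Role",
    "Assay",
    "QcPolicy",
    "WellMeasurement",
    "ReplicateSummary",
    "PlateCalibration",
    "QuantResult",
    "AssayPrecision",
    "qc_replicates",
    "plate_normalization",
    "calibrate_ct",
    "quantify_sample",
    "assay_cv",
    "quantify_plate_set",
]


class Role(str, Enum):
    PARTICIPANT = "participant"
    CALIBRATOR = "calibrator"
    INTERNAL_CONTROL = "internal_control"


class Assay(str, Enum):
    TELOMERE = "telomere"
    ALBUMIN = "albumin"


class QcPolicy(str, Enum):
    """Replicate-outlier exclusion rule.

    LITERAL_2SD excludes a well iff it lies outside the replicate set's own
    mean +/- 2 sample SD.  For a quadruplicate this rule is provably vacuous:
    the largest attainable |z| with the n-1 sample SD is (n-1)/sqrt(n) = 1.5.
    LEAVE_ONE_OUT_2SD (default) judges each well against the mean +/- 2 SD of
    the *other* replicates and does exclude gross outliers.
    """

    LITERAL_2SD = "literal_2sd"
    LEAVE_ONE_OUT_2SD = "leave_one_out_2sd"


@dataclass(frozen=True)
class WellMeasurement:
    """One qPCR well readout."""

    plate_id: str
    sample_id: str
    role: Role
    assay: Assay
    ct: float
    primer_dimer: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be finite and positive, got {self.ct}")


@dataclass
class ReplicateSummary:
    """Replicate set after outlier QC."""

    sample_id: str
    assay: Assay
    valid_cts: list[float]
    excluded_cts: list[float]
    mean_ct: float
    n_valid: int
    rerun: bool = False


@dataclass
class PlateCalibration:
    """Per-plate multiplicative normalization factors, one per assay."""

    plate_id: str
    ct_cal_tel_plate: float
    ct_cal_alb_plate: float
    ct_cal_tel_global: float
    ct_cal_alb_global: float
    factor_tel: float = field(init=False)
    factor_alb: float = field(init=False)

    def __post_init__(self) -> None:
        for name, v in (
            ("plate telomere", self.ct_cal_tel_plate),
            ("plate albumin", self.ct_cal_alb_plate),
            ("global telomere", self.ct_cal_tel_global),
            ("global albumin", self.ct_cal_alb_global),
        ):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"invalid calibrator Ct ({name}): {v}")
        self.factor_tel = self.ct_cal_tel_global / self.ct_cal_tel_plate
        self.factor_alb = self.ct_cal_alb_global / self.ct_cal_alb_plate


@dataclass
class QuantResult:
    sample_id: str
    ct_tel_calibrated: float
    ct_alb_calibrated: float
    delta_ct: float
    delta_delta_ct: float
    ts_ratio: float
    abs_tl_bp: float
    qc_status: str  # ok | rerun_needed | failed
    plate_id: str | None = None


@dataclass
class AssayPrecision:
    """Coefficient of variation: CV% = 100 * SD / mean (sample SD)."""

    label: str
    mean_value: float
    sd_value: float
    cv_percent: float


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def qc_replicates(
    cts: Sequence[float],
    policy: QcPolicy | str = QcPolicy.LEAVE_ONE_OUT_2SD,
    min_valid: int = 2,
    sample_id: str = "",
    assay: Assay = Assay.TELOMERE,
) -> ReplicateSummary:
    """Exclude outlier replicate wells and average the survivors.

    Under ``literal_2sd`` a well is excluded iff it lies outside the full
    replicate set's mean +/- 2 sample SD (a rule that can never fire for a
    quadruplicate).  Under ``leave_one_out_2sd`` each well is compared with
    the mean +/- 2 sample SD of the remaining replicates; wells with fewer
    than two comparators are kept.  The summary is flagged for rerun when
    fewer than ``min_valid`` wells survive.
    """
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite Ct in replicates")
    policy = QcPolicy(policy)

    if arr.size == 1:
        keep = np.array([True])
    elif policy is QcPolicy.LITERAL_2SD:
        mean, sd = arr.mean(), _sample_sd(arr)
        keep = np.abs(arr - mean) <= 2.0 * sd
    else:
        keep = np.ones(arr.size, dtype=bool)
        for i in range(arr.size):
            others = np.delete(arr, i)
            if others.size < 2:
                continue
            m, s = others.mean(), _sample_sd(others)
            if abs(arr[i] - m) > 2.0 * s:
                keep[i] = False

    valid = arr[keep]
    summary = ReplicateSummary(
        sample_id=sample_id,
        assay=Assay(assay),
        valid_cts=valid.tolist(),
        excluded_cts=arr[~keep].tolist(),
        mean_ct=float(valid.mean()) if valid.size else float("nan"),
        n_valid=int(valid.size),
    )
    summary.rerun = summary.n_valid < min_valid
    return summary


def plate_normalization(
    plate_calibrator: dict[Assay, ReplicateSummary],
    global_calibrator_ct: dict[Assay, float],
    plate_id: str = "",
) -> PlateCalibration:
    """Normalization factors (global calibrator Ct / plate calibrator Ct)."""
    try:
        tel_plate = plate_calibrator[Assay.TELOMERE].mean_ct
        alb_plate = plate_calibrator[Assay.ALBUMIN].mean_ct
    except KeyError as exc:
        raise ValueError(f"plate {plate_id!r} missing calibrator assay {exc}") from exc
    return PlateCalibration(
        plate_id=plate_id,
        ct_cal_tel_plate=tel_plate,
        ct_cal_alb_plate=alb_plate,
        ct_cal_tel_global=global_calibrator_ct[Assay.TELOMERE],
        ct_cal_alb_global=global_calibrator_ct[Assay.ALBUMIN],
    )


def calibrate_ct(raw_mean_ct: float, factor: float) -> float:
    """Apply the multiplicative plate normalization to a mean Ct."""
    if factor <= 0:
        raise ValueError(f"normalization factor must be > 0, got {factor}")
    return raw_mean_ct * factor


def quantify_sample(
    ct_tel_cal: float,
    ct_alb_cal: float,
    calibrator_delta_ct: float,
    anchor_bp: float = DEFAULT_ANCHOR_BP,
    sample_id: str = "",
    qc_status: str = "ok",
    plate_id: str | None = None,
) -> QuantResult:
    """Delta-delta-Ct quantification of one sample against the calibrator."""
    if anchor_bp <= 0:
        raise ValueError("anchor_bp must be > 0")
    delta_ct = ct_alb_cal - ct_tel_cal
    ddct = delta_ct - calibrator_delta_ct
    ts = 2.0**ddct
    return QuantResult(
        sample_id=sample_id,
        ct_tel_calibrated=ct_tel_cal,
        ct_alb_calibrated=ct_alb_cal,
        delta_ct=delta_ct,
        delta_delta_ct=ddct,
        ts_ratio=ts,
        abs_tl_bp=ts * anchor_bp,
        qc_status=qc_status,
        plate_id=plate_id,
    )


def assay_cv(values: Iterable[float], label: str = "") -> AssayPrecision:
    """Coefficient of variation of repeated measurements, as a percent."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least two values")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = _sample_sd(arr)
    return AssayPrecision(label=label, mean_value=mean, sd_value=sd, cv_percent=100.0 * sd / mean)


_WELL_COLUMNS = ["plate_id", "sample_id", "role", "assay", "ct", "primer_dimer"]


def _plate_summaries(
    plate_df: pd.DataFrame, policy: QcPolicy, min_valid: int
) -> dict[tuple[str, Assay], ReplicateSummary]:
    out: dict[tuple[str, Assay], ReplicateSummary] = {}
    for (sid, assay), grp in plate_df.groupby(["sample_id", "assay"], sort=False):
        out[(sid, Assay(assay))] = qc_replicates(
            grp["ct"].to_numpy(), policy=policy, min_valid=min_valid,
            sample_id=sid, assay=Assay(assay),
        )
    return out


def quantify_plate_set(
    wells: pd.DataFrame,
    qc_policy: QcPolicy | str = QcPolicy.LEAVE_ONE_OUT_2SD,
    min_valid: int = 2,
    anchor_bp: float = DEFAULT_ANCHOR_BP,
    global_calibrator_ct: dict[Assay, float] | None = None,
) -> tuple[pd.DataFrame, list[AssayPrecision]]:
    """Quantify every participant sample on a multi-plate well table.

    Pipeline per plate: drop primer-dimer wells, QC replicates per sample and
    assay, compute plate and global calibrator means, normalize, calibrate,
    and apply the delta-delta-Ct formula.  A sample measured on several plates
    (reruns) keeps the result from the latest plate, in input order, on which
    it passed QC.  Returns the per-sample result table plus a precision
    report: inter-assay CVs across plates of the internal control (telomere
    Ct and absolute TL) and the range of intra-assay (within-replicate)
    participant CVs per assay.

    Plates lacking calibrator wells for either assay have all their samples
    marked ``failed``.

    ``global_calibrator_ct`` pins the study-wide calibrator mean Ct per assay
    (e.g. when quantifying a rerun plate against an already-established
    reference); by default it is the mean over all valid calibrator wells in
    ``wells``.  With a pinned reference, a Ct scale shift confined to one
    plate cancels exactly.
    """
    df = wells.copy()
    missing = [c for c in _WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    policy = QcPolicy(qc_policy)
    df = df[~df["primer_dimer"].astype(bool)]
    if df.empty:
        raise ValueError("no usable wells after primer-dimer exclusion")

    plate_ids = list(dict.fromkeys(df["plate_id"]))

    # Calibrator replicate means per plate (QC'd like any replicate set), and
    # the global calibrator mean per assay over all valid calibrator wells.
    cal = df[df["role"] == Role.CALIBRATOR.value]
    plate_cal: dict[str, dict[Assay, ReplicateSummary]] = {}
    global_valid: dict[Assay, list[float]] = {Assay.TELOMERE: [], Assay.ALBUMIN: []}
    for pid, pgrp in cal.groupby("plate_id", sort=False):
        per_assay: dict[Assay, ReplicateSummary] = {}
        for assay, agrp in pgrp.groupby("assay", sort=False):
            summ = qc_replicates(
                agrp["ct"].to_numpy(), policy=policy, min_valid=min_valid,
                sample_id=str(agrp["sample_id"].iloc[0]), assay=Assay(assay),
            )
            per_assay[Assay(assay)] = summ
            global_valid[Assay(assay)].extend(summ.valid_cts)
        plate_cal[pid] = per_assay
    if global_calibrator_ct is not None:
        global_cal = {Assay(a): float(v) for a, v in global_calibrator_ct.items()}
    else:
        if not any(global_valid.values()):
            raise ValueError("no calibrator wells in plate set")
        global_cal = {a: float(np.mean(v)) for a, v in global_valid.items() if v}
    calibrator_delta_ct = global_cal[Assay.ALBUMIN] - global_cal[Assay.TELOMERE]

    results: dict[str, QuantResult] = {}
    control_tl: list[float] = []
    control_ct_tel: list[float] = []
    intra_cv: dict[Assay, list[float]] = {Assay.TELOMERE: [], Assay.ALBUMIN: []}

    for pid in plate_ids:
        plate_df = df[(df["plate_id"] == pid) & (df["role"] != Role.CALIBRATOR.value)]
        cal_ok = (
            pid in plate_cal
            and Assay.TELOMERE in plate_cal[pid]
            and Assay.ALBUMIN in plate_cal[pid]
        )
        calibration = (
            plate_normalization(plate_cal[pid], global_cal, plate_id=pid) if cal_ok else None
        )
        summaries = _plate_summaries(plate_df, policy, min_valid)
        sample_ids = list(dict.fromkeys(plate_df["sample_id"]))
        roles = plate_df.drop_duplicates("sample_id").set_index("sample_id")["role"]
        for sid in sample_ids:
            tel = summaries.get((sid, Assay.TELOMERE))
            alb = summaries.get((sid, Assay.ALBUMIN))
            if calibration is None or tel is None or alb is None:
                status = "failed"
                res = QuantResult(sid, math.nan, math.nan, math.nan, math.nan,
                                  math.nan, math.nan, status, plate_id=pid)
            else:
                status = "rerun_needed" if (tel.rerun or alb.rerun) else "ok"
                res = quantify_sample(
                    calibrate_ct(tel.mean_ct, calibration.factor_tel),
                    calibrate_ct(alb.mean_ct, calibration.factor_alb),
                    calibrator_delta_ct,
                    anchor_bp=anchor_bp,
                    sample_id=sid,
                    qc_status=status,
                    plate_id=pid,
                )
                if roles.get(sid) == Role.PARTICIPANT.value:
                    for assay, summ in ((Assay.TELOMERE, tel), (Assay.ALBUMIN, alb)):
                        if summ.n_valid >= 2 and summ.mean_ct != 0:
                            intra_cv[assay].append(
                                assay_cv(summ.valid_cts, label=f"{sid}:{assay.value}").cv_percent
                            )
                if roles.get(sid) == Role.INTERNAL_CONTROL.value and status == "ok":
                    control_tl.append(res.abs_tl_bp)
                    control_ct_tel.append(res.ct_tel_calibrated)
            # latest non-failed wins; a failed result never overwrites an ok one
            prev = results.get(sid)
            if prev is None or res.qc_status == "ok" or prev.qc_status != "ok":
                results[sid] = res

    roles_all = df.drop_duplicates("sample_id").set_index("sample_id")["role"].to_dict()
    rows = [
        r for sid, r in results.items()
        if roles_all.get(sid) == Role.PARTICIPANT.value
    ]
    out = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plate_id": r.plate_id,
                "ct_tel_calibrated": r.ct_tel_calibrated,
                "ct_alb_calibrated": r.ct_alb_calibrated,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "ts_ratio": r.ts_ratio,
                "abs_tl_bp": r.abs_tl_bp,
                "qc_status": r.qc_status,
            }
            for r in rows
        ]
    )

    precision: list[AssayPrecision] = []
    if len(control_ct_tel) >= 2:
        precision.append(assay_cv(control_ct_tel, label="inter_assay_ct_tel_internal_control"))
    if len(control_tl) >= 2:
        precision.append(assay_cv(control_tl, label="inter_assay_abs_tl_internal_control"))
    for assay, cvs in intra_cv.items():
        if cvs:
            arr = np.asarray(cvs)
            precision.append(
                AssayPrecision(
                    label=f"intra_assay_ct_{assay.value}_range",
                    mean_value=float(arr.mean()),
                    sd_value=float(arr.max()),  # max CV observed
                    cv_percent=float(arr.max()),
                )
            )
    return out, precision
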