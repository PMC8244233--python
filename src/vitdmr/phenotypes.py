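"""Phenotype derivation: anthropometric indices, disease classification, vitamin-D groups.

Implements the measurement and diagnostic conventions of the study
population (middle-aged and elderly Chinese adults):

* repeated anthropometric / blood-pressure readings averaged with a
  "two closest of three" rule;
* HOMA-IR, BMI and waist-hip ratio;
* metabolic syndrome (MS) by the joint interim statement with Asian waist
  cutoffs: at least 3 of 5 component abnormalities;
* type 2 diabetes (T2D) by fasting glucose, OGTT, medication or prior
  diagnosis;
* clinical vitamin-D status categories and cohort-specific quintiles.

Boundary semantics follow the diagnostic criteria exactly: thresholds
written ">=" are inclusive (WC 85/80 cm, TG 1.7, BP 130/85, FBG 5.6, OGTT
11.1, FBG 7.0) and the low-HDL criterion is a strict "<" (1.0 men / 1.3
women).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: 1 uIU/mL insulin = 6.945 pmol/L (used to convert reported pmol/L values
#: to the uIU/mL the HOMA-IR formula needs).
INSULIN_PMOL_PER_UIU = 6.945

VITD_CATEGORY_BOUNDS = {
    "severe_deficiency": (0.0, 25.0),
    "deficiency": (25.0, 50.0),
    "insufficiency": (50.0, 75.0),
    "sufficiency": (75.0, float("inf")),
}

#: Quintile labels ordered from highest 25(OH)D concentration (the reference
#: group) to lowest.
QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


class MissingFieldError(ValueError):
    """A record lacks a field required for classification."""


def average_repeated(measurements: Sequence[float], tolerance: float) -> float:
    """Average repeated readings, per the measurement protocol.

    Two readings whose difference is within ``tolerance`` (1 cm for
    circumferences, 1 kg for weight, 10 mmHg for blood pressure) are simply
    averaged.  If the first two disagree by more than the tolerance a third
    reading is required, and the mean of the two closest readings is
    returned.  When the third reading is exactly equidistant from the first
    two, it is averaged with the earlier of them (a deterministic,
    documented tie-break).
    """
    readings = [float(m) for m in measurements]
    if len(readings) < 2:
        raise ValueError("at least two readings are required")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    r1, r2 = readings[0], readings[1]
    if len(readings) == 2:
        if abs(r1 - r2) > tolerance:
            raise ValueError(
                f"first two readings differ by {abs(r1 - r2):g} > tolerance "
                f"{tolerance:g}; a third reading is required"
            )
        return (r1 + r2) / 2.0
    if len(readings) != 3:
        raise ValueError("supply exactly two or three readings")
    r3 = readings[2]
    # Candidate pairs in tie-break preference order: earlier readings first.
    pairs = [(r1, r2), (r1, r3), (r2, r3)]
    diffs = [abs(a - b) for a, b in pairs]
    best = pairs[int(np.argmin(diffs))]
    return (best[0] + best[1]) / 2.0


def homa_ir(fbg: float, insulin: float) -> float:
    """HOMA-IR = fasting glucose (mmol/L) x fasting insulin (uIU/mL) / 22.5."""
    if fbg <= 0 or insulin <= 0:
        raise ValueError("FBG and insulin must be strictly positive")
    return fbg * insulin / 22.5


def insulin_pmol_to_uiu(insulin_pmol_l: float) -> float:
    """Convert insulin from pmol/L to uIU/mL."""
    return insulin_pmol_l / INSULIN_PMOL_PER_UIU


def bmi(weight: float, height: float) -> float:
    """Body mass index: weight (kg) / height (m) squared."""
    if height <= 0 or weight <= 0:
        raise ValueError("weight and height must be strictly positive")
    return weight / height**2


def whr(wc: float, hc: float) -> float:
    """Waist-hip ratio from circumferences in cm."""
    if wc <= 0 or hc <= 0:
        raise ValueError("waist and hip circumference must be strictly positive")
    return wc / hc


@dataclass(frozen=True)
class MsComponentFlags:
    """The five metabolic-syndrome component abnormalities plus the diagnosis."""

    central_obesity: bool
    high_tg: bool
    low_hdl: bool
    high_bp: bool
    high_glucose: bool

    @property
    def n_abnormal(self) -> int:
        return sum(
            (self.central_obesity, self.high_tg, self.low_hdl, self.high_bp, self.high_glucose)
        )

    @property
    def ms_case(self) -> bool:
        return self.n_abnormal >= 3


def _require(record, fields) -> None:
    for name in fields:
        value = record.get(name) if hasattr(record, "get") else getattr(record, name, None)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingFieldError(f"record is unclassifiable: missing field {name!r}")


def classify_ms(record) -> MsComponentFlags:
    """Metabolic-syndrome component flags for one participant.

    ``record`` is any mapping (dict, Series, dataclass) with fields ``sex``
    ("male"/"female"), ``wc_cm``, ``tg_mmol_l``, ``hdl_mmol_l``, ``sbp_mmhg``,
    ``dbp_mmhg``, ``fbg_mmol_l`` and the medication flags
    ``med_tg_lowering``, ``med_hdl_raising``, ``med_antihypertensive``,
    ``med_antidiabetic``.  Medication implies the corresponding component
    abnormal even when the measured value is normal, exactly as the criteria
    read.
    """
    _require(
        record,
        [
            "sex", "wc_cm", "tg_mmol_l", "hdl_mmol_l", "sbp_mmhg", "dbp_mmhg",
            "fbg_mmol_l", "med_tg_lowering", "med_hdl_raising",
            "med_antihypertensive", "med_antidiabetic",
        ],
    )
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    sex = get("sex")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    wc_cut = 85.0 if sex == "male" else 80.0
    hdl_cut = 1.0 if sex == "male" else 1.3
    return MsComponentFlags(
        central_obesity=get("wc_cm") >= wc_cut,
        high_tg=get("tg_mmol_l") >= 1.7 or bool(get("med_tg_lowering")),
        low_hdl=get("hdl_mmol_l") < hdl_cut or bool(get("med_hdl_raising")),
        high_bp=get("sbp_mmhg") >= 130.0
        or get("dbp_mmhg") >= 85.0
        or bool(get("med_antihypertensive")),
        high_glucose=get("fbg_mmol_l") >= 5.6 or bool(get("med_antidiabetic")),
    )


def classify_t2d(record) -> bool:
    """Type 2 diabetes: FBG >= 7.0 mmol/L, OGTT 2h >= 11.1 mmol/L, anti-diabetic
    medication, or a prior physician diagnosis.  A missing OGTT never makes a
    record unclassifiable (the test is not universally administered)."""
    _require(record, ["fbg_mmol_l"])
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k, None)
    if get("fbg_mmol_l") >= 7.0:
        return True
    ogtt = get("ogtt_2h_mmol_l")
    if ogtt is not None and not (isinstance(ogtt, float) and np.isnan(ogtt)) and ogtt >= 11.1:
        return True
    return bool(get("med_antidiabetic")) or bool(get("prior_t2d_diagnosis"))


def abnormal_bp(record, med_rule: str = "include") -> tuple[bool, bool]:
    """Abnormal systolic / diastolic blood pressure as binary outcomes.

    SBP >= 130 mmHg and DBP >= 85 mmHg mirror the blood-pressure component of
    the MS criteria.  Whether antihypertensive medication alone makes both
    outcomes abnormal is configurable (``med_rule`` "include" applies the
    medication clause to both outcomes, "exclude" uses pure thresholds).
    """
    if med_rule not in ("include", "exclude"):
        raise ValueError("med_rule must be 'include' or 'exclude'")
    _require(record, ["sbp_mmhg", "dbp_mmhg"] + (["med_antihypertensive"] if med_rule == "include" else []))
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    med = bool(get("med_antihypertensive")) if med_rule == "include" else False
    return (get("sbp_mmhg") >= 130.0 or med, get("dbp_mmhg") >= 85.0 or med)


def vitd_category(vitd: float) -> str:
    """Clinical vitamin-D status category for a 25(OH)D concentration in nmol/L.

    Half-open intervals partition the positive axis: [0, 25) severe
    deficiency, [25, 50) deficiency, [50, 75) insufficiency, [75, inf)
    sufficiency.
    """
    if not np.isfinite(vitd) or vitd <= 0:
        raise ValueError(f"25(OH)D must be a positive concentration, got {vitd!r}")
    for label, (lo, hi) in VITD_CATEGORY_BOUNDS.items():
        if lo <= vitd < hi:
            return label
    raise AssertionError("unreachable: categories partition (0, inf)")


def vitd_quintiles(vitd: pd.Series) -> pd.Series:
    """Cohort-specific 25(OH)D quintiles, labelled Q1 (highest) .. Q5 (lowest).

    Boundaries are the empirical 20/40/60/80th percentiles; a value lying
    exactly on a boundary is assigned to the lower-concentration quintile.
    """
    values = pd.Series(vitd, dtype=float)
    if values.isna().any():
        raise ValueError("25(OH)D values must be non-missing for quintile assignment")
    if (values <= 0).any():
        raise ValueError("25(OH)D values must be positive")
    cuts = np.quantile(values.to_numpy(), [0.2, 0.4, 0.6, 0.8])
    # side="left": idx counts cutpoints strictly below v, so a value lying
    # exactly on a boundary stays in the lower-concentration group.
    idx = np.searchsorted(cuts, values.to_numpy(), side="left")
    labels = np.array(QUINTILE_LABELS[::-1])[idx]  # 0 lowest conc -> Q5
    return pd.Series(pd.Categorical(labels, categories=list(QUINTILE_LABELS), ordered=True),
                     index=values.index, name="vitd_quintile")


def phenotype_cohort(cohort: pd.DataFrame, bp_med_rule: str = "include") -> pd.DataFrame:
    """Derive all analysis variables for a cohort table.

    Adds columns ``bmi``, ``whr``, ``homa_ir``, ``ms_case``, ``n_ms_components``,
    ``t2d_case``, ``abnormal_sbp``, ``abnormal_dbp``, ``vitd_category`` and
    ``vitd_quintile``.  Rows with missing required fields get missing (NA)
    classifications and are listed in ``result.attrs['unclassifiable_rows']``
    rather than silently dropped.
    """
    out = cohort.copy()
    out["bmi"] = out["weight_kg"] / out["height_m"] ** 2
    out["whr"] = out["wc_cm"] / out["hc_cm"]
    out["homa_ir"] = out["fbg_mmol_l"] * out["insulin_uiu_ml"] / 22.5

    ms, n_comp, t2d, asbp, adbp = [], [], [], [], []
    unclassifiable = []
    for idx, row in out.iterrows():
        rec = row.to_dict()
        try:
            flags = classify_ms(rec)
            ms.append(flags.ms_case)
            n_comp.append(flags.n_abnormal)
        except MissingFieldError:
            ms.append(pd.NA)
            n_comp.append(pd.NA)
            unclassifiable.append(idx)
        try:
            t2d.append(classify_t2d(rec))
        except MissingFieldError:
            t2d.append(pd.NA)
            if idx not in unclassifiable:
                unclassifiable.append(idx)
        try:
            a_s, a_d = abnormal_bp(rec, med_rule=bp_med_rule)
            asbp.append(a_s)
            adbp.append(a_d)
        except MissingFieldError:
            asbp.append(pd.NA)
            adbp.append(pd.NA)
            if idx not in unclassifiable:
                unclassifiable.append(idx)

    out["ms_case"] = pd.array(ms, dtype="boolean")
    out["n_ms_components"] = pd.array(n_comp, dtype="Int64")
    out["t2d_case"] = pd.array(t2d, dtype="boolean")
    out["abnormal_sbp"] = pd.array(asbp, dtype="boolean")
    out["abnormal_dbp"] = pd.array(adbp, dtype="boolean")
    out["vitd_category"] = [vitd_category(v) for v in out["vitd_nmol_l"]]
    out["vitd_quintile"] = vitd_quintiles(out["vitd_nmol_l"])
    out.attrs["unclassifiable_rows"] = unclassifiable
    out.attrs["bp_med_rule"] = bp_med_rule
    return out
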