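"""Observational association of serum 25(OH)D with disease outcomes.

Adjusted logistic odds ratios of MS / T2D / abnormal blood pressure for
the exposure coded three ways — per 10 or 25 nmol/L decrease, cohort
quintiles (reference = highest concentration), and clinical vitamin-D
categories (reference = sufficiency) — plus per-quintile descriptive
comparisons (mean +/- SD with ANOVA, median (IQR) with Kruskal-Wallis,
percentages with the chi-square test).

Covariate presets mirror the adjustment sets of the study: MS models
adjust for age, BMI, WHR, income, smoking, alcohol, physical activity and
family history of MS; T2D models drop smoking and use family history of
diabetes.  Both are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vitdmr.phenotypes import QUINTILE_LABELS, VITD_CATEGORY_BOUNDS
from vitdmr.regression import AssociationEstimate, build_design, logistic_fit

COVARIATE_PRESETS: dict[str, tuple[str, ...]] = {
    "ms_case": (
        "age_years", "bmi", "whr", "income_band", "smoking_status",
        "alcohol_status", "physical_activity", "family_history_ms",
    ),
    "t2d_case": (
        "age_years", "bmi", "whr", "income_band",
        "alcohol_status", "physical_activity", "family_history_t2d",
    ),
}
# Blood-pressure outcomes use the full (MS-style) adjustment set.
COVARIATE_PRESETS["abnormal_sbp"] = COVARIATE_PRESETS["ms_case"]
COVARIATE_PRESETS["abnormal_dbp"] = COVARIATE_PRESETS["ms_case"]

#: Category labels ordered from the reference (highest concentration) down.
CATEGORY_ORDER = ("sufficiency", "insufficiency", "deficiency", "severe_deficiency")


def covariates_for(outcome: str) -> tuple[str, ...]:
    """Default adjustment set for an outcome (empty for unknown outcomes)."""
    return COVARIATE_PRESETS.get(outcome, ())


@dataclass
class LevelEstimate:
    """One exposure level's odds ratio against the reference level."""

    level: str
    n: int
    cases: int
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    estimable: bool = True
    is_reference: bool = False

    @property
    def case_percent(self) -> float:
        return 100.0 * self.cases / self.n if self.n else float("nan")


@dataclass
class ObservationalResult:
    """Adjusted observational ORs for one outcome and exposure coding."""

    outcome: str
    exposure_coding: str  # per10_decrease | per25_decrease | quintile | clinical_category
    levels: list[LevelEstimate]
    reference_level: str | None
    adjusted_for: tuple[str, ...]
    n: int
    trend: AssociationEstimate | None = None  # per-nmol/L coefficient (trend codings)
    scale: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": self.outcome,
                "exposure_coding": self.exposure_coding,
                "level": lv.level,
                "n": lv.n,
                "cases": lv.cases,
                "case_percent": lv.case_percent,
                "odds_ratio": lv.odds_ratio,
                "ci_lo": lv.ci95[0],
                "ci_hi": lv.ci95[1],
                "p": lv.p,
                "reference": lv.is_reference,
                "estimable": lv.estimable,
            }
            for lv in self.levels
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Observational association: {self.outcome} ~ 25(OH)D "
            f"[{self.exposure_coding}], n = {self.n}",
            f"Adjusted for: {', '.join(self.adjusted_for) if self.adjusted_for else '(none)'}",
        ]
        for lv in self.levels:
            if lv.is_reference:
                lines.append(f"  {lv.level:<20} {lv.cases}/{lv.n} ({lv.case_percent:.1f}%)  OR 1.00 (reference)")
            elif not lv.estimable:
                lines.append(f"  {lv.level:<20} inestimable (empty level)")
            else:
                lo, hi = lv.ci95
                lines.append(
                    f"  {lv.level:<20} {lv.cases}/{lv.n} ({lv.case_percent:.1f}%)  "
                    f"OR {lv.odds_ratio:.2f} ({lo:.2f}-{hi:.2f})  p = {lv.p:.4f}"
                )
        return "\n".join(lines)


def _prepare(cohort: pd.DataFrame, outcome: str, covariates) -> tuple[pd.DataFrame, tuple[str, ...]]:
    adj = tuple(covariates) if covariates is not None else covariates_for(outcome)
    needed = [outcome, "vitd_nmol_l", *adj]
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks columns {missing}")
    frame = cohort.dropna(subset=needed).copy()
    return frame, adj


def trend_or(
    cohort: pd.DataFrame,
    outcome: str,
    scale: float = 25.0,
    covariates: Sequence[str] | None = None,
) -> ObservationalResult:
    """Adjusted OR per ``scale`` nmol/L *decrease* in 25(OH)D.

    Fits outcome ~ 25(OH)D + covariates by logistic regression and reports
    OR = exp(-scale * coefficient), with the CI pushed through the same
    monotone map (endpoints re-ordered).
    """
    frame, adj = _prepare(cohort, outcome, covariates)
    y = frame[outcome].astype(float).to_numpy()
    X = build_design(frame, ["vitd_nmol_l", *adj])
    fit = logistic_fit(y, X, adjusted_for=adj)
    est = fit.estimate("vitd_nmol_l", role="beta_XY", label="vitd_nmol_l")
    or_point = float(np.exp(-scale * est.beta))
    lo, hi = sorted(float(np.exp(-scale * c)) for c in est.ci95)
    level = LevelEstimate(
        level=f"per_{scale:g}_nmol_l_decrease",
        n=len(frame),
        cases=int(y.sum()),
        odds_ratio=or_point,
        ci95=(lo, hi),
        p=est.p,
    )
    return ObservationalResult(
        outcome=outcome,
        exposure_coding=f"per{scale:g}_decrease",
        levels=[level],
        reference_level=None,
        adjusted_for=adj,
        n=len(frame),
        trend=est,
        scale=scale,
    )


def categorical_or(
    cohort: pd.DataFrame,
    outcome: str,
    coding: str = "quintile",
    covariates: Sequence[str] | None = None,
) -> ObservationalResult:
    """Adjusted ORs across 25(OH)D quintiles or clinical categories.

    The reference is the highest-concentration level (Q1 for quintiles,
    sufficiency for clinical categories) with OR fixed at exactly 1 and no
    CI.  An empty level is reported as inestimable; the fit proceeds on the
    remaining levels.
    """
    if coding == "quintile":
        column, order = "vitd_quintile", list(QUINTILE_LABELS)
    elif coding == "clinical_category":
        column, order = "vitd_category", list(CATEGORY_ORDER)
    else:
        raise ValueError("coding must be 'quintile' or 'clinical_category'")
    frame, adj = _prepare(cohort, outcome, covariates)
    if column not in frame.columns:
        raise KeyError(f"cohort lacks derived column {column!r}; run phenotyping first")
    y = frame[outcome].astype(float).to_numpy()
    labels = frame[column].astype(str)
    present = [lv for lv in order if (labels == lv).any()]
    if len(present) < 2:
        raise ValueError(f"need at least two populated exposure levels, have {present}")
    reference = present[0]

    indicators = {f"_lvl_{lv}": (labels == lv).astype(float) for lv in present[1:]}
    design_frame = frame.assign(**indicators)
    X = build_design(design_frame, [*indicators.keys(), *adj])
    fit = logistic_fit(y, X, adjusted_for=adj)

    levels = []
    for lv in order:
        mask = labels == lv
        n_lv = int(mask.sum())
        cases = int(y[mask].sum()) if n_lv else 0
        if lv == reference:
            levels.append(
                LevelEstimate(lv, n_lv, cases, 1.0, (float("nan"), float("nan")),
                              float("nan"), is_reference=True)
            )
        elif n_lv == 0:
            levels.append(
                LevelEstimate(lv, 0, 0, float("nan"), (float("nan"), float("nan")),
                              float("nan"), estimable=False)
            )
        else:
            est = fit.estimate(f"_lvl_{lv}", role="beta_XY", label=lv)
            levels.append(
                LevelEstimate(lv, n_lv, cases, est.odds_ratio, est.or_ci95, est.p)
            )
    return ObservationalResult(
        outcome=outcome,
        exposure_coding=coding,
        levels=levels,
        reference_level=reference,
        adjusted_for=adj,
        n=len(frame),
    )


#: Descriptive variables: approximately normal -> mean +/- SD with ANOVA;
#: skewed -> median (IQR) with Kruskal-Wallis; categorical -> % with chi-square.
NORMAL_VARS = ("age_years", "bmi", "wc_cm")
SKEWED_VARS = ("fbg_mmol_l", "insulin_uiu_ml", "homa_ir", "tg_mmol_l", "hdl_mmol_l")
CATEGORICAL_VARS = ("sex", "smoking_status", "alcohol_status", "physical_activity")


def quintile_descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-quintile descriptive table with group-comparison p-values.

    One row per variable; columns ``Q1`` .. ``Q5`` (Q1 = highest 25(OH)D)
    hold formatted summaries, ``p`` the ANOVA / Kruskal-Wallis / chi-square
    p-value and ``test`` which test produced it.  A quintile with fewer
    than 2 observations reports its dispersion as missing.
    """
    if "vitd_quintile" not in cohort.columns:
        raise KeyError("cohort lacks 'vitd_quintile'; run phenotyping first")
    groups = {q: cohort[cohort["vitd_quintile"].astype(str) == q] for q in QUINTILE_LABELS}
    rows = []

    rows.append(
        {"variable": "n", **{q: str(len(g)) for q, g in groups.items()}, "p": np.nan, "test": ""}
    )
    for var in NORMAL_VARS:
        if var not in cohort.columns:
            continue
        cells, samples = {}, []
        for q, g in groups.items():
            vals = g[var].dropna().to_numpy(dtype=float)
            samples.append(vals)
            if len(vals) >= 2:
                cells[q] = f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f}"
            elif len(vals) == 1:
                cells[q] = f"{vals.mean():.2f} +/- NA"
            else:
                cells[q] = "NA"
        valid = [s for s in samples if len(s) >= 2]
        if len(valid) >= 2:
            if all(np.allclose(s, valid[0][0]) for s in valid):
                p = 1.0  # identical groups: F = 0
            else:
                p = float(stats.f_oneway(*valid).pvalue)
        else:
            p = np.nan
        rows.append({"variable": var, **cells, "p": p, "test": "anova"})
    for var in SKEWED_VARS:
        if var not in cohort.columns:
            continue
        cells, samples = {}, []
        for q, g in groups.items():
            vals = g[var].dropna().to_numpy(dtype=float)
            samples.append(vals)
            if len(vals) >= 2:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cells[q] = f"{med:.2f} ({q3 - q1:.2f})"
            elif len(vals) == 1:
                cells[q] = f"{vals[0]:.2f} (NA)"
            else:
                cells[q] = "NA"
        valid = [s for s in samples if len(s) >= 1]
        try:
            p = float(stats.kruskal(*valid).pvalue) if len(valid) >= 2 else np.nan
        except ValueError:  # all values identical
            p = 1.0
        rows.append({"variable": var, **cells, "p": p, "test": "kruskal-wallis"})
    for var in CATEGORICAL_VARS:
        if var not in cohort.columns:
            continue
        col = cohort[var]
        levels = sorted(col.dropna().astype(str).unique())
        table = np.array(
            [[int((groups[q][var].astype(str) == lv).sum()) for q in QUINTILE_LABELS] for lv in levels]
        )
        cells = {}
        for j, q in enumerate(QUINTILE_LABELS):
            total = table[:, j].sum()
            if total:
                parts = [f"{lv}: {100 * table[i, j] / total:.1f}%" for i, lv in enumerate(levels)]
                cells[q] = "; ".join(parts)
            else:
                cells[q] = "NA"
        keep = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if keep.shape[0] >= 2 and keep.shape[1] >= 2:
            p = float(stats.chi2_contingency(keep).pvalue)
        else:
            p = np.nan
        rows.append({"variable": var, **cells, "p": p, "test": "chi-square"})
    return pd.DataFrame(rows, columns=["variable", *QUINTILE_LABELS, "p", "test"])
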