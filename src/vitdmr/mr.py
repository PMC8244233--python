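"""One-sample Mendelian randomization estimators.

The causal machinery of the analysis:

* :func:`f_statistic` — Cragg-Donald instrument strength, F = R^2 (n-2)/(1-R^2),
  with the conventional F > 10 adequacy flag;
* :func:`wald_ratio` — per-SNP causal estimate beta_ZY / beta_ZX with a
  two-term delta-method standard error;
* :func:`ivw_pool` — fixed-effect inverse-variance weighted pooling of Wald
  ratios;
* :func:`egger_regression` — MR-Egger: weighted regression of SNP-outcome on
  SNP-exposure effects whose intercept tests directional pleiotropy;
* :func:`grs_iv_wald` — Wald-type GRS estimator
  OR_IV = exp(ln(OR_GRS-outcome) / beta_GRS-VD), rescaled to a per-25-nmol/L
  decrease in 25(OH)D;
* :func:`two_stage_estimate` — two-stage regression sensitivity estimator
  (linear first stage for fitted 25(OH)D, logistic second stage).

:class:`OneSampleMR` wraps the estimators into a model object fitted to a
phenotyped cohort; :meth:`OneSampleMR.fit` returns a
:class:`OneSampleMRResults` carrying every estimate with its uncertainty and
a ``summary()`` table.

Known limitation (documented, by design): the one-sample covariance between
beta_ZX and beta_ZY is ignored in the Wald-ratio delta method, and the
Wald-type CI treats beta_GRS-VD as fixed; the two-stage estimator provides
the alternative uncertainty assessment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from vitdmr.genetics import GRS_PANELS, SnpPanel, compute_grs, default_panel, oriented_genotypes
from vitdmr.regression import (
    Z_95,
    AssociationEstimate,
    build_design,
    linear_fit,
    logistic_fit,
)

F_USABLE_THRESHOLD = 10.0


@dataclass(frozen=True)
class InstrumentStrength:
    """Cragg-Donald F statistic of an instrument (SNP or GRS)."""

    r_squared: float
    n: int
    f_statistic: float

    @property
    def usable_instrument(self) -> bool:
        return self.f_statistic > F_USABLE_THRESHOLD


def f_statistic(r_squared: float, n: int) -> InstrumentStrength:
    """Instrument strength F = R^2 (n - 2) / (1 - R^2)."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError(f"r_squared must be in [0, 1), got {r_squared!r}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    f = r_squared * (n - 2) / (1.0 - r_squared)
    return InstrumentStrength(r_squared=float(r_squared), n=int(n), f_statistic=float(f))


@dataclass(frozen=True)
class WaldRatioResult:
    """Per-SNP causal estimate beta_ZY / beta_ZX with delta-method uncertainty."""

    snp: str
    beta_iv: float
    se_iv: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta_iv - Z_95 * self.se_iv, self.beta_iv + Z_95 * self.se_iv)

    @property
    def variance_weight(self) -> float:
        return 1.0 / self.se_iv**2


def wald_ratio(beta_zy: AssociationEstimate, beta_zx: AssociationEstimate) -> WaldRatioResult:
    """Wald ratio beta_IV = beta_ZY / beta_ZX.

    The standard error is the two-term delta method,
    se_IV = sqrt(se_ZY^2 / beta_ZX^2 + beta_ZY^2 se_ZX^2 / beta_ZX^4),
    ignoring the one-sample covariance between numerator and denominator.
    """
    if beta_zy.label and beta_zx.label and beta_zy.label != beta_zx.label:
        raise ValueError(
            f"mismatched instruments: beta_ZY is for {beta_zy.label!r}, "
            f"beta_ZX for {beta_zx.label!r}"
        )
    bzx, bzy = beta_zx.beta, beta_zy.beta
    if bzx == 0:
        raise ZeroDivisionError("beta_ZX is zero: the Wald ratio is undefined")
    se = math.sqrt(beta_zy.se**2 / bzx**2 + bzy**2 * beta_zx.se**2 / bzx**4)
    return WaldRatioResult(snp=beta_zx.label or beta_zy.label, beta_iv=bzy / bzx, se_iv=se)


@dataclass(frozen=True)
class IvwResult:
    """Fixed-effect inverse-variance weighted pooled causal estimate."""

    pooled_beta: float
    pooled_se: float
    n_snps: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.pooled_beta - Z_95 * self.pooled_se, self.pooled_beta + Z_95 * self.pooled_se)

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.pooled_beta) / self.pooled_se))


def ivw_pool(ratios: Sequence[WaldRatioResult]) -> IvwResult:
    """Fixed-effect IVW meta-analysis of Wald ratios.

    pooled beta = sum(w_j beta_j) / sum(w_j) with w_j = 1 / var(beta_j);
    pooled se = 1 / sqrt(sum w_j).
    """
    if not ratios:
        raise ValueError("cannot pool an empty list of Wald ratios")
    weights = np.array([r.variance_weight for r in ratios])
    betas = np.array([r.beta_iv for r in ratios])
    if not np.all(np.isfinite(weights)) or not np.all(np.isfinite(betas)):
        raise ValueError("non-finite Wald ratio or variance in IVW pooling")
    total = weights.sum()
    return IvwResult(
        pooled_beta=float((weights * betas).sum() / total),
        pooled_se=float(1.0 / math.sqrt(total)),
        n_snps=len(ratios),
    )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger regression: intercept tests directional pleiotropy."""

    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    slope: float = float("nan")
    slope_se: float = float("nan")
    n_snps: int = 0
    defined: bool = True


def egger_regression(
    beta_zx: Sequence[float],
    beta_zy: Sequence[float],
    se_zy: Sequence[float],
) -> EggerResult:
    """Weighted MR-Egger regression of beta_ZY on beta_ZX.

    Weights are 1/se_ZY^2; the intercept estimates the average directional
    pleiotropic effect and its two-sided p-value uses a t reference with
    n_snps - 2 degrees of freedom.  All beta_ZX must be oriented to the same
    exposure direction (positive); fewer than 3 SNPs leave the regression
    undefined.
    """
    bzx = np.asarray(beta_zx, dtype=float)
    bzy = np.asarray(beta_zy, dtype=float)
    se = np.asarray(se_zy, dtype=float)
    if not (len(bzx) == len(bzy) == len(se)):
        raise ValueError("beta_zx, beta_zy and se_zy must have equal length")
    if len(bzx) < 3:
        return EggerResult(defined=False, n_snps=len(bzx))
    if np.any(bzx <= 0):
        raise ValueError(
            "all beta_ZX must be positive after orientation to a common "
            "exposure-increasing direction"
        )
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("se_zy must be positive and finite")
    X = sm.add_constant(bzx)
    res = sm.WLS(bzy, X, weights=1.0 / se**2).fit()
    # statsmodels WLS p-values already use the t reference with n-2 df.
    return EggerResult(
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        intercept_p=float(res.pvalues[0]),
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        n_snps=len(bzx),
    )


@dataclass(frozen=True)
class GrsIvResult:
    """Causal odds ratio for the exposure instrumented by a GRS panel."""

    grs_panel: str
    outcome: str
    estimator: str  # "wald_type" | "two_stage"
    or_zy: float
    or_zy_ci95: tuple[float, float]
    or_zy_p: float
    beta_grs_vd: float
    scale: float
    direction: str
    or_iv: float
    ci95: tuple[float, float]
    p: float
    instrument: InstrumentStrength | None = None

    @property
    def weak_instrument(self) -> bool:
        return self.instrument is not None and not self.instrument.usable_instrument


def grs_iv_wald(
    or_zy: float | AssociationEstimate,
    beta_grs_vd: float,
    scale: float = 25.0,
    direction: str = "decrease",
    or_zy_ci: tuple[float, float] | None = None,
    grs_panel: str = "",
    outcome: str = "",
    instrument: InstrumentStrength | None = None,
) -> GrsIvResult:
    """Wald-type GRS estimator OR_IV = exp(ln(OR_ZY) / beta_GRS-VD), rescaled.

    ``or_zy`` is the odds ratio of the outcome per unit higher GRS,
    ``beta_grs_vd`` the 25(OH)D change (nmol/L) per unit higher GRS.  The
    reported odds ratio is per ``scale`` nmol/L *decrease* (or increase) in
    25(OH)D.  The CI is the same monotone map applied to the CI of
    ln(OR_ZY); ``beta_grs_vd`` is treated as fixed.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if isinstance(or_zy, AssociationEstimate):
        est = or_zy
        point = est.odds_ratio
        ci = est.or_ci95
        p = est.p
        grs_panel = grs_panel or est.label
    else:
        point = float(or_zy)
        ci = or_zy_ci
        p = float("nan")
    if point <= 0:
        raise ValueError(f"or_zy must be positive, got {point}")
    if beta_grs_vd == 0 or not np.isfinite(beta_grs_vd):
        raise ValueError("beta_grs_vd must be finite and non-zero")
    sign = -1.0 if direction == "decrease" else 1.0
    transform = lambda o: float(np.exp(sign * scale * np.log(o) / beta_grs_vd))
    or_iv = transform(point)
    if ci is not None:
        mapped = sorted(transform(c) for c in ci)
        iv_ci = (mapped[0], mapped[1])
    else:
        iv_ci = (float("nan"), float("nan"))
    return GrsIvResult(
        grs_panel=grs_panel,
        outcome=outcome,
        estimator="wald_type",
        or_zy=point,
        or_zy_ci95=ci if ci is not None else (float("nan"), float("nan")),
        or_zy_p=p,
        beta_grs_vd=float(beta_grs_vd),
        scale=float(scale),
        direction=direction,
        or_iv=or_iv,
        ci95=iv_ci,
        p=p,
        instrument=instrument,
    )


def _incremental_r_squared(vitd, cohort, grs, covariates) -> float:
    """R^2 the GRS adds to the covariate-only model for the exposure.

    With no covariates this is the simple regression R^2 of 25(OH)D on the
    score (matching the single-regressor n-2 form of the F statistic).
    """
    frame = cohort.assign(_grs=grs)
    X_full = build_design(frame, ["_grs", *covariates])
    r2_full = linear_fit(vitd, X_full).r_squared
    if not covariates:
        return r2_full
    X_cov = build_design(frame, list(covariates))
    r2_cov = linear_fit(vitd, X_cov).r_squared
    return r2_full - r2_cov


def two_stage_estimate(
    cohort: pd.DataFrame,
    panel: SnpPanel | Iterable,
    outcome: str,
    covariates: Sequence[str] = (),
    scale: float = 25.0,
    direction: str = "decrease",
    orientation: str = "vitd_decreasing",
    exposure: str = "vitd_nmol_l",
    grs_panel_name: str = "",
) -> GrsIvResult:
    """Two-stage regression estimator of the causal odds ratio.

    Stage 1 regresses 25(OH)D on the GRS (plus covariates) to obtain fitted
    exposure values; stage 2 is a logistic regression of the outcome on the
    fitted exposure (plus covariates).  The reported OR per ``scale`` nmol/L
    decrease is exp(-scale * stage-2 coefficient).  An instrument with
    F <= 10 yields a prominent weak-instrument flag on the result, not an
    error.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    grs = compute_grs(cohort, panel, orientation)
    if grs.isna().any():
        raise ValueError("GRS is missing for some participants; cannot run the two-stage fit")
    vitd = cohort[exposure].to_numpy(dtype=float)
    y = cohort[outcome].to_numpy(dtype=float)

    frame = cohort.assign(_grs=grs)
    X1 = build_design(frame, ["_grs", *covariates])
    stage1 = linear_fit(vitd, X1, adjusted_for=tuple(covariates))
    fitted = stage1.fitted

    frame2 = cohort.assign(_fitted_vitd=fitted)
    X2 = build_design(frame2, ["_fitted_vitd", *covariates])
    stage2 = logistic_fit(y, X2, adjusted_for=tuple(covariates))
    coef = float(stage2.params["_fitted_vitd"])
    se = float(stage2.bse["_fitted_vitd"])

    strength = f_statistic(_incremental_r_squared(vitd, cohort, grs, covariates), len(y))

    sign = -1.0 if direction == "decrease" else 1.0
    or_iv = float(np.exp(sign * scale * coef))
    lo, hi = sorted(
        float(np.exp(sign * scale * c)) for c in (coef - Z_95 * se, coef + Z_95 * se)
    )
    p = float(2 * stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    # Per-unit-GRS outcome association implied by the two stages, for the
    # result to be comparable with the Wald-type route.
    beta_grs_vd = float(stage1.params["_grs"])
    or_zy = float(np.exp(coef * beta_grs_vd))
    return GrsIvResult(
        grs_panel=grs_panel_name,
        outcome=outcome,
        estimator="two_stage",
        or_zy=or_zy,
        or_zy_ci95=(float("nan"), float("nan")),
        or_zy_p=float("nan"),
        beta_grs_vd=beta_grs_vd,
        scale=float(scale),
        direction=direction,
        or_iv=or_iv,
        ci95=(lo, hi),
        p=p,
        instrument=strength,
    )


@dataclass
class SnpAssociation:
    """Everything estimated for one SNP: both MR arrows plus diagnostics."""

    rsid: str
    beta_zx: AssociationEstimate
    beta_zy: AssociationEstimate
    strength: InstrumentStrength
    wald: WaldRatioResult


class OneSampleMR:
    """One-sample MR of an exposure on a binary outcome within one cohort.

    Parameters
    ----------
    cohort : DataFrame
        Phenotyped cohort table with ``snp_<rsid>`` genotype columns, the
        exposure column and the binary outcome column.
    outcome : str
        Name of the binary outcome column (e.g. ``ms_case``, ``t2d_case``,
        ``abnormal_sbp``, ``abnormal_dbp`` or the simulated ``outcome``).
    panel : SnpPanel, optional
        Instrument SNPs with orientations and GRS weights; defaults to the
        four-SNP vitamin-D panel with unit weights.
    covariates : sequence of str
        Covariate columns entering both regressions of every estimator.
    orientation : str
        Analysis orientation for GRS scoring; the default
        ``vitd_decreasing`` reports causal ORs per 25 nmol/L *decrease*.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        outcome: str,
        panel: SnpPanel | None = None,
        covariates: Sequence[str] = (),
        orientation: str = "vitd_decreasing",
        grs_panels: Sequence[str] = GRS_PANELS,
        exposure: str = "vitd_nmol_l",
        scale: float = 25.0,
    ) -> None:
        self.panel = panel if panel is not None else default_panel()
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.orientation = orientation
        self.grs_panels = tuple(grs_panels)
        self.exposure = exposure
        self.scale = scale

        required = [exposure, outcome, *[s.column for s in self.panel], *self.covariates]
        missing = [c for c in required if c not in cohort.columns]
        if missing:
            raise KeyError(f"cohort lacks required columns: {missing}")
        usable = cohort.dropna(subset=required)
        self.n_dropped = len(cohort) - len(usable)
        self.cohort = usable

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs) -> "OneSampleMR":
        return cls(data, outcome, **kwargs)

    def fit(self) -> "OneSampleMRResults":
        cohort = self.cohort
        vitd = cohort[self.exposure].to_numpy(dtype=float)
        y = cohort[self.outcome].to_numpy(dtype=float)
        warnings_list: list[str] = []

        snp_assocs: list[SnpAssociation] = []
        for snp in self.panel:
            # Per-SNP arrows are estimated on the 25(OH)D-increasing
            # orientation so all beta_ZX share a sign, as MR-Egger requires.
            g = oriented_genotypes(cohort[snp.column].astype(float), snp, "vitd_increasing")
            frame = cohort.assign(_g=g)
            X = build_design(frame, ["_g", *self.covariates])
            zx = linear_fit(vitd, X, adjusted_for=self.covariates).estimate(
                "_g", role="beta_ZX", label=snp.rsid
            )
            zy = logistic_fit(y, X, adjusted_for=self.covariates).estimate(
                "_g", role="beta_ZY", label=snp.rsid
            )
            r2 = linear_fit(vitd, build_design(frame, ["_g"])).r_squared
            strength = f_statistic(r2, len(vitd))
            if not strength.usable_instrument:
                warnings_list.append(
                    f"weak instrument: {snp.rsid} F = {strength.f_statistic:.2f} <= 10"
                )
            snp_assocs.append(
                SnpAssociation(snp.rsid, zx, zy, strength, wald_ratio(zy, zx))
            )

        ivw = ivw_pool([a.wald for a in snp_assocs]) if snp_assocs else None
        egger: EggerResult
        bzx = np.array([a.beta_zx.beta for a in snp_assocs])
        if np.any(bzx <= 0):
            egger = EggerResult(defined=False, n_snps=len(snp_assocs))
            warnings_list.append(
                "MR-Egger undefined: an estimated beta_ZX is non-positive after "
                "orientation (sampling noise on a weak instrument)"
            )
        else:
            egger = egger_regression(
                bzx,
                [a.beta_zy.beta for a in snp_assocs],
                [a.beta_zy.se for a in snp_assocs],
            )

        grs_results: dict[str, dict[str, GrsIvResult]] = {}
        for panel_name in self.grs_panels:
            sub = self.panel.subset(panel_name)
            if len(sub) == 0:
                continue
            grs = compute_grs(cohort, sub, self.orientation)
            frame = cohort.assign(_grs=grs)
            X = build_design(frame, ["_grs", *self.covariates])
            or_zy = logistic_fit(y, X, adjusted_for=self.covariates).estimate(
                "_grs", role="beta_ZY", label=panel_name
            )
            beta_grs_vd = linear_fit(vitd, X, adjusted_for=self.covariates).estimate(
                "_grs", role="beta_GRS_VD", label=panel_name
            )
            strength = f_statistic(
                _incremental_r_squared(vitd, cohort, grs, self.covariates), len(y)
            )
            if not strength.usable_instrument:
                warnings_list.append(
                    f"weak instrument: GRS_{panel_name} F = {strength.f_statistic:.2f} <= 10"
                )
            direction = "decrease" if self.orientation == "vitd_decreasing" else "increase"
            wald_type = grs_iv_wald(
                or_zy,
                beta_grs_vd.beta,
                scale=self.scale,
                direction=direction,
                outcome=self.outcome,
                grs_panel=panel_name,
                instrument=strength,
            )
            two_stage = two_stage_estimate(
                cohort,
                sub,
                self.outcome,
                covariates=self.covariates,
                scale=self.scale,
                direction=direction,
                orientation=self.orientation,
                exposure=self.exposure,
                grs_panel_name=panel_name,
            )
            grs_results[panel_name] = {"wald_type": wald_type, "two_stage": two_stage}

        return OneSampleMRResults(
            model=self,
            snp_associations=snp_assocs,
            ivw=ivw,
            egger=egger,
            grs_results=grs_results,
            warnings=warnings_list,
        )


@dataclass
class OneSampleMRResults:
    """Fitted one-sample MR analysis: per-SNP, pooled and GRS-based estimates."""

    model: OneSampleMR
    snp_associations: list[SnpAssociation]
    ivw: IvwResult | None
    egger: EggerResult
    grs_results: dict[str, dict[str, GrsIvResult]]
    warnings: list[str] = field(default_factory=list)

    def snp_frame(self) -> pd.DataFrame:
        """Per-SNP estimates as a tidy table (Fig.-2-style scatter data)."""
        rows = []
        for a in self.snp_associations:
            rows.append(
                {
                    "rsid": a.rsid,
                    "beta_zx": a.beta_zx.beta,
                    "se_zx": a.beta_zx.se,
                    "beta_zy": a.beta_zy.beta,
                    "se_zy": a.beta_zy.se,
                    "or_zy": a.beta_zy.odds_ratio,
                    "f_statistic": a.strength.f_statistic,
                    "r_squared": a.strength.r_squared,
                    "wald_ratio": a.wald.beta_iv,
                    "wald_se": a.wald.se_iv,
                }
            )
        return pd.DataFrame(rows)

    def grs_frame(self) -> pd.DataFrame:
        """Table-4-style rows: OR_ZY and OR_IV per GRS panel and estimator."""
        rows = []
        for panel_name, by_est in self.grs_results.items():
            for est_name, r in by_est.items():
                rows.append(
                    {
                        "grs_panel": panel_name,
                        "outcome": r.outcome,
                        "estimator": est_name,
                        "or_zy_per_unit_grs": r.or_zy,
                        "or_zy_lo": r.or_zy_ci95[0],
                        "or_zy_hi": r.or_zy_ci95[1],
                        "or_zy_p": r.or_zy_p,
                        "beta_grs_vd": r.beta_grs_vd,
                        "or_iv": r.or_iv,
                        "or_iv_lo": r.ci95[0],
                        "or_iv_hi": r.ci95[1],
                        "or_iv_p": r.p,
                        "scale_nmol_l": r.scale,
                        "direction": r.direction,
                        "f_statistic": r.instrument.f_statistic if r.instrument else float("nan"),
                        "weak_instrument": r.weak_instrument,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "One-sample Mendelian randomization",
            "==================================",
            f"Outcome: {m.outcome}    n = {len(m.cohort)}    "
            f"exposure: {m.exposure} (per {m.scale:g} nmol/L "
            f"{'decrease' if m.orientation == 'vitd_decreasing' else 'increase'})",
            f"Covariates: {', '.join(m.covariates) if m.covariates else '(none)'}",
            "",
            "Per-SNP instruments (oriented 25(OH)D-increasing)",
            f"{'rsid':<12}{'beta_ZX':>9}{'se':>8}{'beta_ZY':>9}{'se':>8}{'F':>8}{'Wald ratio':>12}",
        ]
        for a in self.snp_associations:
            lines.append(
                f"{a.rsid:<12}{a.beta_zx.beta:>9.3f}{a.beta_zx.se:>8.3f}"
                f"{a.beta_zy.beta:>9.4f}{a.beta_zy.se:>8.4f}"
                f"{a.strength.f_statistic:>8.1f}{a.wald.beta_iv:>12.4f}"
            )
        if self.ivw:
            lo, hi = self.ivw.ci95
            lines += [
                "",
                f"IVW pooled beta_IV: {self.ivw.pooled_beta:.4f} "
                f"(95% CI {lo:.4f} to {hi:.4f}; p = {self.ivw.p:.3f})",
            ]
        if self.egger.defined:
            lines.append(
                f"MR-Egger intercept: {self.egger.intercept:.4f} "
                f"(se {self.egger.intercept_se:.4f}; p = {self.egger.intercept_p:.3f}); "
                f"slope {self.egger.slope:.4f}"
            )
        else:
            lines.append("MR-Egger: undefined")
        lines += ["", "GRS instruments"]
        for panel_name, by_est in self.grs_results.items():
            for est_name, r in by_est.items():
                lo, hi = r.ci95
                f_txt = f"F = {r.instrument.f_statistic:.1f}" if r.instrument else ""
                weak = "  [WEAK INSTRUMENT]" if r.weak_instrument else ""
                lines.append(
                    f"  GRS_{panel_name:<11} {est_name:<10} "
                    f"OR_IV per {r.scale:g} nmol/L {r.direction}: "
                    f"{r.or_iv:.3f} ({lo:.3f}-{hi:.3f})  {f_txt}{weak}"
                )
        if self.warnings:
            lines += ["", "Warnings:"] + [f"  - {w}" for w in self.warnings]
        return "\n".join(lines)
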