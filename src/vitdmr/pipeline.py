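"""End-to-end orchestration: simulate -> phenotype -> observational -> MR.

A single config file (YAML) drives the whole run; every numeric output is
fully determined by the config and the seed.  Each run writes a manifest
recording the config digest, seed, artifact paths, stage warnings (weak
instruments, value clipping, separation) and the analysis conventions in
force (GRS orientation, blood-pressure medication rule, CI convention), so
results are self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

import vitdmr
from vitdmr.genetics import (
    SnpDefinition,
    SnpPanel,
    allele_frequency,
    compute_grs,
    default_panel,
    hwe_test,
)
from vitdmr.mr import OneSampleMR
from vitdmr.observational import categorical_or, quintile_descriptives, trend_or
from vitdmr.phenotypes import phenotype_cohort
from vitdmr.simulate import SimulationConfig, generate_cohort, write_cohort_csv

logger = logging.getLogger(__name__)

#: Columns a cohort CSV must provide for the full analysis.
REQUIRED_COHORT_COLUMNS = [
    "id", "vitd_nmol_l", "fbg_mmol_l", "insulin_uiu_ml", "tg_mmol_l",
    "hdl_mmol_l", "sbp_mmhg", "dbp_mmhg", "weight_kg", "height_m", "wc_cm",
    "hc_cm", "age_years", "sex", "income_band", "smoking_status",
    "alcohol_status", "physical_activity", "family_history_ms",
    "family_history_t2d", "med_tg_lowering", "med_hdl_raising",
    "med_antihypertensive", "med_antidiabetic", "prior_t2d_diagnosis",
]

#: Adjustment set of the MR models (one set for all outcomes).
MR_COVARIATES = (
    "age_years", "bmi", "whr", "income_band", "smoking_status",
    "alcohol_status", "physical_activity", "family_history_t2d",
)


class PanelEntry(BaseModel):
    rsid: str
    gene: str = ""
    functional_class: str = Field(alias="class")
    effect_allele_orientation: str = "vitd_increasing"
    weight: float = 1.0

    model_config = {"populate_by_name": True}


class AnalysisConfig(BaseModel):
    orientation: str = "vitd_decreasing"
    bp_med_rule: str = "include"
    outcomes: list[str] = Field(
        default_factory=lambda: ["ms_case", "t2d_case", "abnormal_sbp", "abnormal_dbp"]
    )
    scale_nmol_l: float = 25.0
    mr_covariates: list[str] = Field(default_factory=lambda: list(MR_COVARIATES))


class PipelineConfig(BaseModel):
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    panel: Optional[list[PanelEntry]] = None

    def snp_panel(self) -> SnpPanel:
        if self.panel is None:
            return default_panel()
        return SnpPanel(
            [
                SnpDefinition(
                    rsid=e.rsid,
                    gene=e.gene,
                    functional_class=e.functional_class,
                    effect_allele_orientation=e.effect_allele_orientation,
                    grs_weight=e.weight,
                )
                for e in self.panel
            ]
        )

    def digest(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_digest: str
    seed: int
    package_version: str
    artifacts: dict[str, str] = dataclass_field(default_factory=dict)
    warnings: list[str] = dataclass_field(default_factory=list)
    conventions: dict[str, str] = dataclass_field(default_factory=dict)
    partial: bool = False
    failed_stage: str | None = None

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Requires all documented analysis columns plus at least one
    ``snp_<rsid>`` genotype column; genotype values outside {0, 1, 2} are
    rejected naming the offending row and column.  Unknown columns are
    preserved.  An empty file is an error, not an empty cohort.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cohort file {path} is empty or malformed: {exc}") from exc
    if table.empty:
        raise ValueError(f"cohort file {path} contains a header but no rows")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required columns: {missing}")
    snp_cols = [c for c in table.columns if c.startswith("snp_")]
    if not snp_cols:
        raise ValueError(f"cohort file {path} has no snp_<rsid> genotype columns")
    for col in snp_cols:
        values = table[col]
        bad = values.dropna()[~values.dropna().isin([0, 1, 2])]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(
                f"invalid genotype in {path}: column {col!r}, row {row}, "
                f"value {bad.iloc[0]!r} (must be 0, 1 or 2)"
            )
    for col in ["vitd_nmol_l", "fbg_mmol_l", "insulin_uiu_ml", "tg_mmol_l",
                "hdl_mmol_l", "wc_cm", "weight_kg", "height_m"]:
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().sum() > table[col].isna().sum():
            raise ValueError(f"non-numeric values in column {col!r} of {path}")
        if (numeric.dropna() <= 0).any():
            raise ValueError(f"non-positive values in column {col!r} of {path}")
    return table


def write_results(results: pd.DataFrame, path) -> None:
    """Write a results table as CSV (round-trippable with ``pd.read_csv``)."""
    results.to_csv(path, index=False)


def snp_qc_table(cohort: pd.DataFrame, panel: SnpPanel) -> pd.DataFrame:
    """Allele frequencies and HWE tests for every panel SNP."""
    rows = []
    for snp in panel:
        g = cohort[snp.column].astype(int)
        counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        hwe = hwe_test(counts)
        rows.append(
            {
                "rsid": snp.rsid,
                "gene": snp.gene,
                "functional_class": snp.functional_class,
                "n0": counts[0], "n1": counts[1], "n2": counts[2],
                "allele_freq": allele_frequency(counts),
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig | str | Path,
    outdir,
    seed: int | None = None,
    export_latent: bool = False,
    bp_med_rule: str | None = None,
    orientation: str | None = None,
) -> RunManifest:
    """Run simulate -> phenotype -> observational -> MR and write all artifacts."""
    if not isinstance(config, PipelineConfig):
        config = load_pipeline_config(config)
    if seed is not None:
        config = config.model_copy(deep=True)
        config.simulation.seed = seed
    if bp_med_rule is not None:
        config.analysis.bp_med_rule = bp_med_rule
    if orientation is not None:
        config.analysis.orientation = orientation
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = config.snp_panel()
    analysis = config.analysis

    manifest = RunManifest(
        config_digest=config.digest(),
        seed=config.simulation.seed,
        package_version=vitdmr.__version__,
        conventions={
            "orientation": analysis.orientation,
            "bp_med_rule": analysis.bp_med_rule,
            "ci_convention": "Wald, beta +/- 1.96 se on the link scale",
            "grs_weights": "external configuration input; equal weights are a testing default",
            "wald_ratio_se": "two-term delta method, one-sample beta_ZX/beta_ZY covariance ignored",
            "egger_reference": "t distribution with n_snps - 2 df",
        },
    )

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:
            manifest.partial = True
            manifest.failed_stage = stage
            manifest.warnings.append(f"[{stage}] failed: {exc}")
            manifest.write(outdir / "manifest.json")
            raise PipelineStageError(stage, exc) from exc

    def _simulate():
        cohort = generate_cohort(config.simulation)
        path = outdir / "cohort.csv"
        write_cohort_csv(cohort, path, export_latent=export_latent)
        if cohort.attrs.get("n_vitd_truncated"):
            manifest.warnings.append(
                f"[simulate] truncated {cohort.attrs['n_vitd_truncated']} 25(OH)D values at 1 nmol/L"
            )
        for name, count in cohort.attrs.get("n_clipped", {}).items():
            manifest.warnings.append(f"[simulate] clipped {count} values of {name}")
        manifest.artifacts["cohort"] = str(path)
        if not export_latent:
            cohort = cohort.drop(columns=["latent_confounder"])
        return cohort

    cohort = _run("simulate", _simulate)

    def _phenotype():
        pheno = phenotype_cohort(cohort, bp_med_rule=analysis.bp_med_rule)
        for panel_name in ("synthesis", "metabolism", "combined"):
            pheno[f"grs_{panel_name}"] = compute_grs(
                pheno, panel.subset(panel_name), analysis.orientation
            )
        path = outdir / "cohort_phenotyped.csv"
        pheno.to_csv(path, index=False)
        manifest.artifacts["cohort_phenotyped"] = str(path)
        if pheno.attrs["unclassifiable_rows"]:
            manifest.warnings.append(
                f"[phenotype] {len(pheno.attrs['unclassifiable_rows'])} unclassifiable rows"
            )
        return pheno

    pheno = _run("phenotype", _phenotype)

    def _descriptives():
        table = quintile_descriptives(pheno)
        path = outdir / "table2_descriptives.csv"
        write_results(table, path)
        manifest.artifacts["table2_descriptives"] = str(path)

    _run("descriptives", _descriptives)

    def _observational():
        frames = []
        for outcome in ("ms_case", "t2d_case"):
            pheno_num = pheno.assign(
                **{outcome: pheno[outcome].to_numpy(dtype="float64", na_value=np.nan)}
            )
            for scale in (10.0, 25.0):
                frames.append(trend_or(pheno_num, outcome, scale=scale).to_frame())
            for coding in ("quintile", "clinical_category"):
                frames.append(categorical_or(pheno_num, outcome, coding=coding).to_frame())
        path = outdir / "table3_observational.csv"
        write_results(pd.concat(frames, ignore_index=True), path)
        manifest.artifacts["table3_observational"] = str(path)

    _run("observational", _observational)

    def _mr():
        qc = snp_qc_table(pheno, panel)
        snp_frames, grs_frames, scatter_frames = [], [], []
        for outcome in analysis.outcomes:
            data = pheno.assign(
                **{outcome: pheno[outcome].to_numpy(dtype="float64", na_value=np.nan)}
            )
            model = OneSampleMR(
                data,
                outcome,
                panel=panel,
                covariates=tuple(analysis.mr_covariates),
                orientation=analysis.orientation,
                scale=analysis.scale_nmol_l,
            )
            results = model.fit()
            manifest.warnings.extend(f"[mr:{outcome}] {w}" for w in results.warnings)
            sf = results.snp_frame().merge(qc[["rsid", "allele_freq", "hwe_p"]], on="rsid")
            sf.insert(0, "outcome", outcome)
            snp_frames.append(sf)
            gf = results.grs_frame()
            grs_frames.append(gf)
            scatter = results.snp_frame()[["rsid", "beta_zx", "se_zx", "beta_zy", "se_zy"]].copy()
            scatter.insert(0, "outcome", outcome)
            # Through-origin IVW slopes: ln OR_ZY on beta_ZX, weights 1/se_ZY^2.
            w = 1.0 / scatter["se_zy"] ** 2
            scatter["ivw_slope_all"] = (w * scatter["beta_zx"] * scatter["beta_zy"]).sum() / (
                w * scatter["beta_zx"] ** 2
            ).sum()
            synth = scatter["rsid"].isin(panel.subset("synthesis").rsids)
            ws, bs, ys = w[synth], scatter.loc[synth, "beta_zx"], scatter.loc[synth, "beta_zy"]
            scatter["ivw_slope_synthesis"] = (ws * bs * ys).sum() / (ws * bs**2).sum()
            scatter_frames.append(scatter)
        snp_path = outdir / "snp_associations.csv"
        write_results(pd.concat(snp_frames, ignore_index=True), snp_path)
        manifest.artifacts["snp_associations"] = str(snp_path)
        mr_path = outdir / "mr_results.csv"
        write_results(pd.concat(grs_frames, ignore_index=True), mr_path)
        manifest.artifacts["mr_results"] = str(mr_path)
        scatter_path = outdir / "fig2_scatter.csv"
        write_results(pd.concat(scatter_frames, ignore_index=True), scatter_path)
        manifest.artifacts["fig2_scatter"] = str(scatter_path)

    _run("mr", _mr)

    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest.artifacts), outdir)
    return manifest
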