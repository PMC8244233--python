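"""Instrument handling: SNP panels, allele-frequency and HWE checks, genetic risk scores.

The instruments are four SNPs in vitamin-D pathway genes: two synthesis
variants (*DHCR7/NADSYN1* rs12785878, *CYP2R1* rs10741657), one transport
variant (*GC* rs2282679) and one catabolism variant (*CYP24A1* rs6013897).
Genotypes are additive 0/1/2 effect-allele counts; a genetic risk score
(GRS) is the weighted sum of counts with externally supplied weights on the
nmol/L scale.

Orientation convention
----------------------
Each ``SnpDefinition`` records which direction its counted allele moves
25(OH)D (``vitd_increasing`` or ``vitd_decreasing``).  Scoring re-orients
all SNPs to a single analysis direction (default 25(OH)D-*decreasing*, so a
higher GRS means genetically lower vitamin D and causal odds ratios are
naturally reported per 25 nmol/L decrease).  Flipping the stored coding of
any SNP (g -> 2-g together with its orientation tag) therefore leaves every
downstream estimate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FUNCTIONAL_CLASSES = ("synthesis", "transport", "catabolism")
ORIENTATIONS = ("vitd_increasing", "vitd_decreasing")

#: Panel membership of the composite scores: the "metabolism" score pools the
#: transport and catabolism variants; "combined" uses all four.
GRS_PANELS = ("synthesis", "metabolism", "combined")


@dataclass(frozen=True)
class SnpDefinition:
    """One instrument SNP: identity, pathway class, orientation and GRS weight.

    ``grs_weight`` is the external per-allele effect on 25(OH)D (nmol/L scale)
    taken from a prior study; it must be positive, with direction carried by
    ``effect_allele_orientation``.
    """

    rsid: str
    gene: str
    functional_class: str
    effect_allele_orientation: str = "vitd_increasing"
    grs_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"functional_class must be one of {FUNCTIONAL_CLASSES}, "
                f"got {self.functional_class!r}"
            )
        if self.effect_allele_orientation not in ORIENTATIONS:
            raise ValueError(
                f"effect_allele_orientation must be one of {ORIENTATIONS}, "
                f"got {self.effect_allele_orientation!r}"
            )
        if not np.isfinite(self.grs_weight) or self.grs_weight <= 0:
            raise ValueError(
                f"grs_weight must be finite and > 0 (orientation carries the "
                f"sign); got {self.grs_weight!r} for {self.rsid}"
            )

    @property
    def column(self) -> str:
        """Cohort CSV column holding this SNP's 0/1/2 counts."""
        return f"snp_{self.rsid}"

    @property
    def in_metabolism_panel(self) -> bool:
        return self.functional_class in ("transport", "catabolism")


@dataclass
class SnpPanel:
    """An ordered collection of instrument SNPs with unique rsids."""

    snps: Sequence[SnpDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"duplicate rsids in panel: {rsids}")

    def __iter__(self):
        return iter(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def subset(self, panel: str) -> "SnpPanel":
        """Return the synthesis / metabolism / combined sub-panel."""
        if panel == "combined":
            return SnpPanel(list(self.snps))
        if panel == "synthesis":
            return SnpPanel([s for s in self.snps if s.functional_class == "synthesis"])
        if panel == "metabolism":
            return SnpPanel([s for s in self.snps if s.in_metabolism_panel])
        raise ValueError(f"unknown GRS panel {panel!r}; expected one of {GRS_PANELS}")

    def get(self, rsid: str) -> SnpDefinition:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)


def default_panel(weights: dict[str, float] | None = None) -> SnpPanel:
    """The four-SNP vitamin-D instrument panel.

    GRS weights are a required configuration input in a real analysis (they
    come from an external study, not from the analysis cohort).  When
    ``weights`` is omitted, equal weights of 1.0 are used — a documented
    default intended for testing and simulation only.
    """
    w = {
        "rs12785878": 1.0,
        "rs10741657": 1.0,
        "rs2282679": 1.0,
        "rs6013897": 1.0,
    }
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise ValueError(f"unknown rsids in weights: {sorted(unknown)}")
        w.update(weights)
    return SnpPanel(
        [
            SnpDefinition("rs12785878", "DHCR7/NADSYN1", "synthesis", "vitd_increasing", w["rs12785878"]),
            SnpDefinition("rs10741657", "CYP2R1", "synthesis", "vitd_increasing", w["rs10741657"]),
            SnpDefinition("rs2282679", "GC", "transport", "vitd_increasing", w["rs2282679"]),
            SnpDefinition("rs6013897", "CYP24A1", "catabolism", "vitd_increasing", w["rs6013897"]),
        ]
    )


def allele_frequency(genotype_counts: tuple[int, int, int]) -> float:
    """Effect-allele frequency from genotype counts (n0, n1, n2)."""
    n0, n1, n2 = genotype_counts
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("cannot estimate allele frequency from zero genotypes")
    return (2 * n2 + n1) / (2 * total)


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness-of-fit of genotype counts against HWE proportions."""

    chi2: float
    p: float
    defined: bool = True


def hwe_test(genotype_counts: tuple[int, int, int]) -> HweResult:
    """1-df chi-square test of Hardy-Weinberg equilibrium.

    Expected counts use the estimated allele frequency.  A monomorphic
    marker (expected heterozygote count 0) leaves the statistic undefined
    and is reported as such rather than as a number.
    """
    n0, n1, n2 = genotype_counts
    total = n0 + n1 + n2
    if total < 1:
        raise ValueError("need at least one genotype for an HWE test")
    p = allele_frequency(genotype_counts)
    q = 1.0 - p
    expected = np.array([q * q, 2 * p * q, p * p]) * total
    if expected[1] == 0:
        return HweResult(chi2=float("nan"), p=float("nan"), defined=False)
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def oriented_genotypes(
    genotypes: "pd.Series | np.ndarray",
    snp: SnpDefinition,
    orientation: str = "vitd_decreasing",
) -> "pd.Series | np.ndarray":
    """Re-code 0/1/2 counts so the counted allele matches ``orientation``."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if snp.effect_allele_orientation == orientation:
        return genotypes
    return 2 - genotypes


def compute_grs(
    genotypes: pd.DataFrame,
    panel: SnpPanel | Iterable[SnpDefinition],
    orientation: str = "vitd_decreasing",
) -> pd.Series:
    """Weighted additive genetic risk score, oriented to ``orientation``.

    ``genotypes`` must contain one ``snp_<rsid>`` column of 0/1/2 counts per
    panel SNP.  A missing genotype makes the score missing for that person —
    there is no silent zero-fill.
    """
    snps = list(panel)
    if not snps:
        raise ValueError("empty SNP panel")
    score = pd.Series(0.0, index=genotypes.index)
    missing = pd.Series(False, index=genotypes.index)
    for snp in snps:
        if snp.column not in genotypes.columns:
            raise KeyError(f"cohort table lacks genotype column {snp.column!r}")
        g = genotypes[snp.column]
        bad = g.dropna()[~g.dropna().isin([0, 1, 2])]
        if len(bad):
            raise ValueError(
                f"genotypes for {snp.rsid} must be 0/1/2; offending values "
                f"{bad.unique().tolist()} at rows {bad.index[:5].tolist()}"
            )
        missing |= g.isna()
        score = score + snp.grs_weight * oriented_genotypes(g.astype(float), snp, orientation)
    score[missing] = np.nan
    return score


def read_panel(path) -> SnpPanel:
    """Read a SNP panel from TSV with columns rsid, gene, class, effect_allele_orientation, weight."""
    table = pd.read_csv(path, sep="\t")
    required = {"rsid", "gene", "class", "effect_allele_orientation", "weight"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SNP panel file {path} lacks columns {sorted(missing)}")
    return SnpPanel(
        [
            SnpDefinition(
                rsid=row["rsid"],
                gene=row["gene"],
                functional_class=row["class"],
                effect_allele_orientation=row["effect_allele_orientation"],
                grs_weight=float(row["weight"]),
            )
            for _, row in table.iterrows()
        ]
    )


def write_panel(panel: SnpPanel, path) -> None:
    pd.DataFrame(
        {
            "rsid": [s.rsid for s in panel],
            "gene": [s.gene for s in panel],
            "class": [s.functional_class for s in panel],
            "effect_allele_orientation": [s.effect_allele_orientation for s in panel],
            "weight": [s.grs_weight for s in panel],
        }
    ).to_csv(path, sep="\t", index=False)
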