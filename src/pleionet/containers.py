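"""Shared in-memory containers used across the pipeline stages.

The pipeline passes a small number of tabular objects between stages:
genotypes (lines x SNPs dosage matrix with SNP coordinates), raw
multi-environment phenotypes, BLUP tables, per-SNP summary statistics,
and clumped QTL regions.  Tables are pandas DataFrames with fixed column
names; thin dataclasses wrap them where extra state (truth ledgers,
variance components, grand means) travels alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Fixed column order of the summary-statistics table written to TSV.
SUMSTATS_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "MAF", "BETA", "SE", "Z", "P", "N"]


class ParameterError(ValueError):
    """Invalid user-supplied parameter or infeasible parameter combination."""


@dataclass
class GenotypeMatrix:
    """Lines x SNPs dosage matrix for an inbred panel.

    Dosages are counts of the alternate allele in {0, 2} (homozygous lines;
    heterozygotes never occur), stored as float with NaN marking missing
    calls.  ``snps`` carries 1-based coordinates and alleles with columns
    ``chrom``, ``pos``, ``id``, ``ref``, ``alt``.
    """

    dosages: np.ndarray
    lines: list[str]
    snps: pd.DataFrame
    subpop: np.ndarray | None = None  # per-line subpopulation label (simulation truth)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D lines x SNPs array")
        if self.dosages.shape[0] != len(self.lines):
            raise ParameterError("row count does not match number of line IDs")
        if self.dosages.shape[1] != len(self.snps):
            raise ParameterError("column count does not match SNP table length")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            lines=list(self.lines),
            snps=self.snps.iloc[index].reset_index(drop=True),
            subpop=self.subpop,
        )

    def subset_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            lines=[self.lines[i] for i in index],
            snps=self.snps,
            subpop=None if self.subpop is None else self.subpop[index],
        )


@dataclass
class RawPhenotypeTable:
    """Long-format line x trait x environment x replicate observations.

    ``data`` columns: ``line``, ``env``, ``rep``, ``trait``, ``value``.
    ``truth`` (simulation only) records causal SNPs, effects, variance
    components and the true genetic-correlation matrix.
    """

    data: pd.DataFrame
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        required = {"line", "env", "rep", "trait", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"phenotype table missing columns: {sorted(missing)}")

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())


@dataclass
class VarianceComponents:
    """Variance decomposition of a multi-environment trial.

    V_g: genetic (line) variance; V_ge: genotype-by-environment variance;
    V_e: residual error variance; L: number of environments (sites);
    R: number of replicates per environment.
    """

    V_g: float
    V_ge: float
    V_e: float
    L: int
    R: int

    def __post_init__(self) -> None:
        if min(self.V_g, self.V_ge, self.V_e) < 0:
            raise ParameterError("variance components must be non-negative")
        if self.L < 1 or self.R < 1:
            raise ParameterError("L and R must be >= 1")


@dataclass
class BLUPTable:
    """Predicted genotypic value per line x trait.

    ``values`` is indexed by line with one column per trait (grand mean plus
    shrunken line deviation); ``grand_means`` maps trait -> grand mean.
    """

    values: pd.DataFrame
    grand_means: dict[str, float] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait: str) -> pd.Series:
        return self.values[trait]


@dataclass
class QCReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_missing - self.n_removed_maf


@dataclass
class LDScoreTable:
    """Per-SNP LD scores: l_i = sum of r2 to SNPs within a window (self included)."""

    table: pd.DataFrame  # columns: ID, L2
    M: int
    window_bp: int

    def aligned_scores(self, snp_ids: pd.Series) -> np.ndarray:
        s = self.table.set_index("ID")["L2"]
        return s.reindex(snp_ids).to_numpy()


@dataclass
class CrossTraitFit:
    """Cross-trait LD-score regression fit.

    slope estimates sqrt(N1*N2)*rho_g/M; the intercept estimates
    rho*N_s/sqrt(N1*N2) (phenotypic correlation x sample overlap).
    """

    rho_g: float
    slope: float
    intercept: float
    N1: float
    N2: float
    r_g: float
    slope_se: float
    intercept_se: float
    r_g_se: float
    h2_1: float
    h2_2: float
    n_snps: int
    n_dropped: int = 0


@dataclass
class MtagResult:
    """Joint multi-trait estimates per SNP x trait.

    ``tables`` maps trait -> summary-statistics DataFrame in the standard
    dialect (joint BETA/SE/Z/P); ``omega`` is the TxT per-SNP genetic
    covariance, ``sigma_overlap`` the TxT sampling-correlation structure
    whose off-diagonal entries encode sample overlap.
    """

    tables: dict[str, pd.DataFrame]
    omega: np.ndarray
    sigma_overlap: np.ndarray
    traits: list[str]


@dataclass
class QTLRegion:
    """A clumped association peak: lead SNP plus members in LD with it."""

    id: str
    trait: str
    chrom: str
    start: int
    end: int
    lead_id: str
    lead_pos: int
    lead_p: float
    member_ids: list[str]
    member_index: np.ndarray  # column indices into the genotype matrix

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class CandidateGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    distance_bp: int
    traits: list[str]
    snp_ids: list[str]


@dataclass
class NetworkEdge:
    """Inter-LD edge between two QTL regions (symmetric in a/b).

    inter_ld = 0.5 * (LD(Q1,Q2)/PmaxLD(Q1) + LD(Q1,Q2)/PmaxLD(Q2)) where
    LD(Q1,Q2) is the mean r2 over all cross-region SNP pairs and PmaxLD(Qk)
    the maximum pairwise r2 among members of Qk.
    """

    qtl_a: str
    qtl_b: str
    cross_ld: float
    pmax_a: float
    pmax_b: float
    inter_ld: float
    single_snp_flag: bool = False


def validate_sumstats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics dialect used between pipeline stages."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ParameterError(f"summary statistics missing columns: {missing}")
    ok = stats["SE"].to_numpy() > 0
    if not np.all(ok[np.isfinite(stats["SE"].to_numpy())]):
        raise ParameterError("summary statistics contain non-positive SE")
    return stats
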