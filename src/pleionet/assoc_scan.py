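"""Genotype QC, population structure (PCA, kinship), LD utilities and the GWAS scan.

The scan regresses line BLUP values on SNP dosage plus structure covariates
(principal components), reporting per-SNP effect, standard error,
Z = beta/SE and a two-sided p-value.  Two models are available:

* ``ols`` — ordinary least squares with the covariates projected out once
  (fast, fully vectorized over SNPs);
* ``mlm`` — a single-variance-component mixed model in the EMMAX style: the
  kinship matrix K is spectrally decomposed once, the variance ratio
  delta = V_e/V_g is REML-optimized under the null (no SNP), and each SNP
  is then tested by GLS in the rotated basis.

LD is composite r2: the squared Pearson correlation of dosage vectors,
which is the appropriate measure for unphased homozygous inbreds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats

from .containers import (GenotypeMatrix, ParameterError, QCReport, SUMSTATS_COLUMNS,
                         BLUPTable, validate_sumstats)

#: Genome-wide significance threshold used throughout the pipeline
#: (multiple-testing-corrected constant; see docs/methods.md).
SIGNIFICANCE_THRESHOLD = 5.61e-6


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_genotypes(geno: GenotypeMatrix, max_missing: float = 0.20,
                 min_maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with missing rate above ``max_missing`` or MAF below ``min_maf``.

    MAF is computed on non-missing calls.  The missingness rule is applied
    first; the MAF rule counts only SNPs that passed it, so the report
    satisfies kept + removed_missing + removed_maf = input.
    """
    miss = geno.missing_rate()
    maf = geno.maf()
    fail_missing = miss > max_missing
    fail_maf = (~fail_missing) & ((maf < min_maf) | ~np.isfinite(maf))
    keep = ~(fail_missing | fail_maf)
    if not keep.any():
        raise ParameterError("QC removed every SNP")
    report = QCReport(n_input=geno.n_snps,
                      n_removed_missing=int(fail_missing.sum()),
                      n_removed_maf=int(fail_maf.sum()))
    return geno.subset_snps(np.where(keep)[0]), report


def _imputed_centered(geno: GenotypeMatrix, scale: bool = False) -> np.ndarray:
    """Mean-imputed, column-centered dosages (optionally frequency-scaled)."""
    X = geno.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= col_mean
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    return X


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def pca(geno: GenotypeMatrix, k: int, scale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered dosage matrix.

    Returns (scores of shape n_lines x k, fraction of variance explained per
    component).  Signs are fixed so each component's largest-magnitude SNP
    loading is positive.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    if k >= min(geno.n_lines, geno.n_snps):
        raise ParameterError("k must be < min(n_lines, n_snps)")
    X = _imputed_centered(geno, scale=scale)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U, s = U * flip, s
    var = s**2
    frac = var / var.sum()
    scores = U[:, :k] * s[:k]
    return scores, frac[:k]


def kinship(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = ZZ' / (2 * sum p(1-p)).

    Z is the dosage matrix centered at twice the alternate-allele frequency;
    zero-variance SNPs are excluded.  For fully homozygous lines the
    diagonal is close to 2 (inbreeding coefficient ~1).
    """
    p = geno.alt_freq()
    keep = (p > 0) & (p < 1)
    X = _imputed_centered(geno.subset_snps(np.where(keep)[0]))
    denom = 2.0 * np.sum(p[keep] * (1 - p[keep]))
    return (X @ X.T) / denom


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(geno: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Composite LD: squared Pearson correlation of two dosage columns."""
    x = geno.dosages[:, snp_i]
    y = geno.dosages[:, snp_j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero-variance SNP in LD computation")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(geno: GenotypeMatrix, cols: np.ndarray | None = None) -> np.ndarray:
    """Pairwise r2 matrix over the given SNP columns (mean-imputed)."""
    sub = geno if cols is None else geno.subset_snps(np.asarray(cols))
    X = _imputed_centered(sub)
    sd = X.std(axis=0)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[zero, :] = np.nan
    r[:, zero] = np.nan
    return r**2


def ld_decay(geno: GenotypeMatrix, max_dist: int = 600_000,
             bin_width: int = 10_000) -> pd.DataFrame:
    """Mean r2 by physical distance bin, within-chromosome pairs only.

    Returns a DataFrame (bin_start, bin_end, mean_r2, n_pairs); bins with no
    pairs are reported with NaN mean, not zero.  No pair beyond ``max_dist``
    contributes.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ParameterError("max_dist and bin_width must be positive")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom, sub in geno.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            continue
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        r2 = ld_matrix(geno, idx)
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist <= max_dist) & np.isfinite(r2[iu, ju])
        b = np.minimum((dist[ok] - 1) // bin_width, n_bins - 1).astype(int)
        np.add.at(sums, b, r2[iu, ju][ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width + 1,
        "bin_end": np.minimum((np.arange(n_bins) + 1) * bin_width, max_dist),
        "mean_r2": mean,
        "n_pairs": counts,
    })


def ld_decay_by_subgroup(geno: GenotypeMatrix, max_dist: int = 600_000,
                         bin_width: int = 10_000) -> dict[int, pd.DataFrame]:
    """Per-subpopulation LD decay curves (requires simulation subpop labels)."""
    if geno.subpop is None:
        raise ParameterError("genotype matrix carries no subpopulation labels")
    out = {}
    for s in np.unique(geno.subpop):
        sub = geno.subset_lines(np.where(geno.subpop == s)[0])
        out[int(s)] = ld_decay(sub, max_dist=max_dist, bin_width=bin_width)
    return out


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def _align(geno: GenotypeMatrix, blup: BLUPTable, trait: str) -> tuple[np.ndarray, np.ndarray]:
    y = blup.trait_vector(trait)
    if not set(geno.lines) <= set(y.index):
        missing = sorted(set(geno.lines) - set(y.index))[:5]
        raise ParameterError(f"lines missing from BLUP table, e.g. {missing}")
    return np.asarray(y.reindex(geno.lines), dtype=float), geno.dosages


def _ols_scan(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP OLS of y on dosage with covariates C projected out."""
    n, p = C.shape
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    xtx = np.einsum("ij,ij->j", X_r, X_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (X_r.T @ y_r) / xtx
        rss = (y_r @ y_r) - beta**2 * xtx
        dof = n - p - 1
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / xtx)
    bad = (xtx <= 1e-12) | ~np.isfinite(se) | (se <= 0)
    beta[bad] = np.nan
    se[bad] = np.nan
    return beta, se


def _reml_delta(y: np.ndarray, C: np.ndarray, S: np.ndarray, U: np.ndarray) -> float:
    """REML-optimize delta = V_e/V_g for y = C*b + g + e, var = V_g(K + delta I)."""
    yt = U.T @ y
    Ct = U.T @ C
    n, p = C.shape

    def neg_reml(log_delta: float) -> float:
        d = np.exp(log_delta)
        w = S + d  # eigenvalues of K + delta I
        Wi = 1.0 / w
        CtWC = Ct.T @ (Ct * Wi[:, None])
        CtWy = Ct.T @ (yt * Wi)
        try:
            b = np.linalg.solve(CtWC, CtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Ct @ b
        rss = float(np.sum(r * r * Wi))
        sigma2 = rss / (n - p)
        _, logdet_CtWC = np.linalg.slogdet(CtWC)
        ll = -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_CtWC
                     + (n - p))
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def _mlm_scan(y: np.ndarray, X: np.ndarray, C: np.ndarray,
              K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EMMAX-style scan: one spectral decomposition, per-SNP GLS at fixed delta."""
    S, U = np.linalg.eigh((K + K.T) / 2)
    S = np.clip(S, 0.0, None)
    delta = _reml_delta(y, C, S, U)
    w = 1.0 / np.sqrt(S + delta)
    # rotate and whiten: the problem becomes homoskedastic OLS
    yt = (U.T @ y) * w
    Ct = (U.T @ C) * w[:, None]
    Xt = (U.T @ X) * w[:, None]
    return _ols_scan(yt, Xt, Ct)


def gwas_scan(geno: GenotypeMatrix, blup: BLUPTable, trait: str,
              covariates: np.ndarray | None = None, model: str = "ols",
              K: np.ndarray | None = None) -> pd.DataFrame:
    """Single-trait association scan; returns the standard summary-stats table.

    ``covariates`` are structure covariates (e.g. PCA scores), one row per
    line in genotype order; an intercept is always added.  SNPs collinear
    with the covariates get NaN effect and p.  Missing dosages are handled
    per SNP by exclusion (falling back to a per-SNP regression).
    """
    y, X = _align(geno, blup, trait)
    ok = np.isfinite(y)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} lines without a BLUP value excluded from the scan",
                      stacklevel=2)
        y = y[ok]
        geno = geno.subset_lines(np.where(ok)[0])
        X = geno.dosages
        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)[ok]
        if K is not None:
            K = K[np.ix_(ok, ok)]
    n = len(y)
    C = np.ones((n, 1))
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != n:
            raise ParameterError("covariate rows must match lines")
        C = np.hstack([C, covariates])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ParameterError("covariates are rank deficient")

    has_missing = np.isnan(X).any(axis=0)
    Ximp = X.copy()
    if has_missing.any():
        col_mean = np.nanmean(X, axis=0)
        nr, nc = np.where(np.isnan(X))
        Ximp[nr, nc] = col_mean[nc]

    if model == "ols":
        beta, se = _ols_scan(y, Ximp, C)
        # redo SNPs with missing calls excluding those lines
        for j in np.where(has_missing)[0]:
            ok = ~np.isnan(X[:, j])
            if ok.sum() <= C.shape[1] + 1:
                beta[j] = se[j] = np.nan
                continue
            b, s = _ols_scan(y[ok], X[ok, j:j + 1], C[ok])
            beta[j], se[j] = b[0], s[0]
    elif model == "mlm":
        if K is None:
            K = kinship(geno)
        beta, se = _mlm_scan(y, Ximp, C, K)
    else:
        raise ParameterError(f"unknown model {model!r}; use 'ols' or 'mlm'")

    dof = n - C.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2.0 * sstats.t.sf(np.abs(z), dof)
    maf = geno.maf()
    stats = pd.DataFrame({
        "CHR": geno.snps["chrom"],
        "POS": geno.snps["pos"],
        "ID": geno.snps["id"],
        "A1": geno.snps["alt"],
        "A2": geno.snps["ref"],
        "MAF": maf,
        "BETA": beta,
        "SE": se,
        "Z": z,
        "P": p,
        "N": n,
    })
    return validate_sumstats(stats[SUMSTATS_COLUMNS])


def significant_snps(stats: pd.DataFrame,
                     threshold: float = SIGNIFICANCE_THRESHOLD) -> pd.DataFrame:
    """SNPs with p strictly below the threshold, sorted by p ascending."""
    hit = stats[stats["P"] < threshold]
    return hit.sort_values(["P", "CHR", "POS"]).reset_index(drop=True)


def genomic_lambda(stats: pd.DataFrame) -> float:
    """Median-based genomic-control inflation factor of a scan."""
    chi2 = stats["Z"].dropna() ** 2
    return float(np.median(chi2) / sstats.chi2.ppf(0.5, 1))


def snp_pve(stats: pd.DataFrame, trait_variance: float,
            dosage_span: float = 2.0) -> pd.Series:
    """Percent of phenotypic variance explained per SNP.

    Computed as Var(dosage) * beta^2 / V_y * 100 with the binomial dosage
    variance implied by the allele frequency: for homozygous-inbred {0,2}
    coding Var(dosage) = 4 p (1-p); for HWE diploid allele counts it would
    be 2 p (1-p).  Clipped to [0, 100].
    """
    if trait_variance <= 0:
        raise ParameterError("trait variance must be positive")
    p = stats["MAF"].to_numpy()
    beta = stats["BETA"].to_numpy()
    var_x = dosage_span**2 * p * (1 - p)
    pve = 100.0 * var_x * beta**2 / trait_variance
    return pd.Series(np.clip(pve, 0.0, 100.0), index=stats.index, name="PVE")


def pve_summary(stats_by_trait: dict[str, pd.DataFrame],
                trait_variances: dict[str, float],
                threshold: float = SIGNIFICANCE_THRESHOLD) -> pd.DataFrame:
    """Min/median/mean/max PVE over significant SNPs per trait."""
    rows = []
    for trait, stats in stats_by_trait.items():
        sig = significant_snps(stats, threshold)
        if sig.empty:
            rows.append({"trait": trait, "n_snps": 0, "mean_pve": np.nan,
                         "min_pve": np.nan, "median_pve": np.nan, "max_pve": np.nan})
            continue
        pve = snp_pve(sig, trait_variances[trait])
        rows.append({"trait": trait, "n_snps": len(sig), "mean_pve": pve.mean(),
                     "min_pve": pve.min(), "median_pve": pve.median(),
                     "max_pve": pve.max()})
    return pd.DataFrame(rows).set_index("trait")
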