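"""LD scores, cross-trait LD-score regression and the multi-trait joint estimator.

LD-score regression models the expected product of two traits' Z-statistics
at SNP i as a linear function of its LD score l_i:

    E[Z1_i * Z2_i | l_i] = sqrt(N1*N2) * rho_g / M * l_i + rho*N_s/sqrt(N1*N2)

so the slope estimates the genetic covariance rho_g (per M SNPs) and the
intercept absorbs phenotypic correlation among overlapping samples.  The
univariate special case (Z^2 on l_i) estimates SNP heritability with an
intercept near 1.  Genetic correlation is r_g = rho_g / sqrt(h2_1 * h2_2).

The joint multi-trait estimator combines per-trait summary statistics with
the genetic covariance of SNP effects (Omega, from the LDSC fits) and the
per-SNP sampling covariance (Sigma_j, from SEs and LDSC intercepts).  For a
target trait t with omega_t the t-th column of Omega,

    W_jt = (Omega - omega_t omega_t' / Omega_tt + Sigma_j)^(-1)
    x_t  = omega_t / Omega_tt
    beta_t,j = x_t' W_jt beta_j / (x_t' W_jt x_t),   SE^2 = 1 / (x_t' W_jt x_t)

which reduces to the single-trait input when T = 1 or Omega is diagonal
with no sample overlap, and to inverse-variance meta-analysis when the
traits are perfectly genetically correlated with equal diagonals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .assoc_scan import ld_matrix
from .containers import (CrossTraitFit, GenotypeMatrix, LDScoreTable, MtagResult,
                         ParameterError, SUMSTATS_COLUMNS)


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def ld_scores(geno: GenotypeMatrix, window_bp: int = 1_000_000,
              adjusted: bool = True) -> LDScoreTable:
    """l_i = sum of r2 between SNP i and SNPs within ``window_bp`` (self included).

    With ``adjusted`` the small-sample bias correction
    r2_adj = r2 - (1 - r2)/(n - 2) is applied to cross terms, making l_i of
    an unlinked SNP unbiased for 1.
    """
    if window_bp <= 0:
        raise ParameterError("window must be positive")
    n = geno.n_lines
    scores = np.zeros(geno.n_snps)
    for chrom, sub in geno.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        idx, pos = idx[order], pos[order]
        r2 = ld_matrix(geno, idx)
        r2 = np.nan_to_num(r2, nan=0.0)
        if adjusted and n > 2:
            r2 = r2 - (1.0 - r2) / (n - 2)
        np.fill_diagonal(r2, 1.0)  # self term exact, never bias-corrected
        within = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        scores[idx] = (r2 * within).sum(axis=1)
    table = pd.DataFrame({"ID": geno.snps["id"], "L2": scores})
    return LDScoreTable(table=table, M=geno.n_snps, window_bp=window_bp)


# ---------------------------------------------------------------------------
# LD-score regression
# ---------------------------------------------------------------------------

def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   n_blocks: int = 20) -> tuple[float, float, float, float]:
    """Weighted least squares of y on [1, x] with block-jackknife SEs.

    Returns (slope, intercept, slope_se, intercept_se).
    """
    X = np.column_stack([np.ones_like(x), x])

    def fit(mask: np.ndarray) -> np.ndarray:
        Xw = X[mask] * w[mask, None]
        yw = y[mask] * w[mask]
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        return coef

    full = fit(np.ones(len(x), dtype=bool))
    blocks = np.array_split(np.arange(len(x)), min(n_blocks, len(x)))
    deleted = []
    for b in blocks:
        mask = np.ones(len(x), dtype=bool)
        mask[b] = False
        deleted.append(fit(mask))
    deleted = np.asarray(deleted)
    g = len(blocks)
    pseudo = g * full - (g - 1) * deleted
    se = pseudo.std(axis=0, ddof=1) / np.sqrt(g)
    return full[1], full[0], se[1], se[0]


def _aligned(stats: pd.DataFrame, lds: LDScoreTable) -> tuple[np.ndarray, np.ndarray, float]:
    l = lds.aligned_scores(stats["ID"])
    ok = np.isfinite(l) & np.isfinite(stats["Z"].to_numpy())
    if ok.sum() < 50:
        raise ParameterError("fewer than 50 usable SNPs; LDSC fit would be unstable")
    return stats["Z"].to_numpy()[ok], l[ok], float(stats["N"].mean())


def ldsc_h2(stats: pd.DataFrame, lds: LDScoreTable) -> tuple[float, float]:
    """Univariate LD-score regression: slope = N*h2/M, intercept ~ 1.

    Returns (h2 estimate, intercept).  Two-step weighted least squares: a
    first pass with 1/l_i weights gives a provisional h2, the second pass
    adds the heteroskedasticity weight 1/(1 + N*h2*l_i/M)^2 of the chi2
    variance under the model.
    """
    z, l, N = _aligned(stats, lds)
    lf = np.maximum(l, 1.0)
    w = 1.0 / np.sqrt(lf)
    slope, intercept, _, _ = _wls_jackknife(l, z**2, w)
    h2_0 = float(np.clip(slope * lds.M / N, 0.0, 1.0))
    mean_chi2 = 1.0 + N * h2_0 * l / lds.M
    w = 1.0 / np.sqrt(lf * mean_chi2**2)
    slope, intercept, _, _ = _wls_jackknife(l, z**2, w)
    h2 = slope * lds.M / N
    return float(h2), float(intercept)


def _harmonize(stats1: pd.DataFrame, stats2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Align two summary tables on SNP ID, flipping Z where alleles are swapped."""
    s1 = stats1.set_index("ID")
    s2 = stats2.set_index("ID")
    common = s1.index.intersection(s2.index)
    s1, s2 = s1.loc[common].copy(), s2.loc[common].copy()
    same = (s1["A1"] == s2["A1"]) & (s1["A2"] == s2["A2"])
    flipped = (s1["A1"] == s2["A2"]) & (s1["A2"] == s2["A1"])
    bad = ~(same | flipped)
    n_dropped = int(bad.sum()) + (len(stats1) - len(common)) + (len(stats2) - len(common))
    s1, s2 = s1[~bad], s2[~bad]
    flip = flipped[~bad]
    s2.loc[flip, ["Z", "BETA"]] *= -1.0
    a1 = s2.loc[flip, "A1"].copy()
    s2.loc[flip, "A1"] = s2.loc[flip, "A2"]
    s2.loc[flip, "A2"] = a1
    return s1.reset_index(), s2.reset_index(), n_dropped


def cross_trait_ldsc(stats1: pd.DataFrame, stats2: pd.DataFrame,
                     lds: LDScoreTable, h2_pair: tuple[float, float] | None = None,
                     ) -> CrossTraitFit:
    """Cross-trait LD-score regression of Z1*Z2 on l_i.

    slope = sqrt(N1*N2) * rho_g / M  =>  rho_g = slope * M / sqrt(N1*N2);
    the intercept estimates rho*N_s/sqrt(N1*N2) (sample-overlap term);
    r_g = rho_g / sqrt(h2_1 * h2_2) with heritabilities estimated by
    univariate LDSC on each input unless supplied.  |r_g| beyond 1.05 is
    clipped with a warning.
    """
    s1, s2, n_dropped = _harmonize(stats1, stats2)
    z1, l, N1 = _aligned(s1, lds)
    z2, _, N2 = _aligned(s2, lds)
    if h2_pair is None:
        h2_1, _ = ldsc_h2(s1, lds)
        h2_2, _ = ldsc_h2(s2, lds)
    else:
        h2_1, h2_2 = h2_pair
    lf = np.maximum(l, 1.0)
    w = 1.0 / np.sqrt(lf)
    slope, intercept, slope_se, intercept_se = _wls_jackknife(l, z1 * z2, w)
    # second pass: variance of z1*z2 under the model
    v1 = 1.0 + N1 * np.clip(h2_1, 0, 1) * l / lds.M
    v2 = 1.0 + N2 * np.clip(h2_2, 0, 1) * l / lds.M
    ez1z2 = slope * l + intercept
    w = 1.0 / np.sqrt(lf * (v1 * v2 + ez1z2**2))
    slope, intercept, slope_se, intercept_se = _wls_jackknife(l, z1 * z2, w)
    rho_g = slope * lds.M / np.sqrt(N1 * N2)
    denom = np.sqrt(max(h2_1, 1e-12) * max(h2_2, 1e-12))
    r_g = rho_g / denom
    r_g_se = (slope_se * lds.M / np.sqrt(N1 * N2)) / denom
    if abs(r_g) > 1.05:
        warnings.warn(f"r_g = {r_g:.3f} clipped to +/-1.05", stacklevel=2)
        r_g = float(np.clip(r_g, -1.05, 1.05))
    return CrossTraitFit(rho_g=float(rho_g), slope=float(slope), intercept=float(intercept),
                         N1=N1, N2=N2, r_g=float(r_g), slope_se=float(slope_se),
                         intercept_se=float(intercept_se), r_g_se=float(r_g_se),
                         h2_1=float(h2_1), h2_2=float(h2_2),
                         n_snps=len(l), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Omega / Sigma and the joint estimator
# ---------------------------------------------------------------------------

def _project_psd(A: np.ndarray, eps: float = 0.0) -> np.ndarray:
    w, v = np.linalg.eigh((A + A.T) / 2)
    return (v * np.clip(w, eps, None)) @ v.T


def estimate_omega_sigma(stats_list: list[pd.DataFrame], lds: LDScoreTable,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP effect covariance Omega and sampling-overlap matrix from LDSC.

    Omega (T x T, standardized per-SNP scale) has univariate slopes h2_t/M
    on the diagonal and rho_g/M off the diagonal; it is projected to the
    nearest PSD matrix if needed.  The returned overlap matrix holds the
    cross-trait LDSC intercepts off the diagonal (1 on the diagonal); the
    per-SNP sampling covariance used by ``mtag`` is derived from it and the
    per-SNP standardized SEs.
    """
    T = len(stats_list)
    if T < 2:
        raise ParameterError("need at least two traits")
    h2 = np.empty(T)
    for t, s in enumerate(stats_list):
        try:
            h2[t], _ = ldsc_h2(s, lds)
        except Exception as exc:  # noqa: BLE001 - reported with trait index
            raise ParameterError(f"univariate LDSC failed for trait {t}: {exc}") from exc
        # guard against a collapsed regression slope: the mean excess chi2
        # bounds the trait's per-SNP signal (method of moments); an Omega
        # diagonal far below it would make the joint estimator discard the
        # trait's own evidence
        z, l, N = _aligned(s, lds)
        h2_mom = float(np.clip((np.mean(z**2) - 1.0) * lds.M / (N * np.mean(l)), 0.0, 1.0))
        if h2[t] < h2_mom / 3.0:
            warnings.warn(
                f"trait {t}: LDSC slope h2={h2[t]:.3f} inconsistent with mean chi2 "
                f"(MoM h2={h2_mom:.3f}); using the moment estimate for Omega",
                stacklevel=2)
            h2[t] = h2_mom
    omega = np.diag(np.maximum(h2, 1e-8) / lds.M)
    overlap = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            try:
                fit = cross_trait_ldsc(stats_list[i], stats_list[j], lds,
                                       h2_pair=(h2[i], h2[j]))
            except Exception as exc:  # noqa: BLE001
                raise ParameterError(f"cross-trait LDSC failed for pair ({i},{j}): {exc}"
                                     ) from exc
            rho = fit.rho_g
            # soft-threshold nuisance estimates at ~2 jackknife SEs: an
            # off-diagonal indistinguishable from zero destabilizes the
            # joint weights far more than it informs them
            rho_se = fit.slope_se * lds.M / np.sqrt(fit.N1 * fit.N2)
            if abs(rho) < 2.0 * rho_se:
                rho = 0.0
            # sampling correlation from sample overlap = the cross-trait
            # regression intercept, kept inside the valid correlation range
            r_s = float(np.clip(fit.intercept, -0.95, 0.95))
            if abs(r_s) < 2.0 * fit.intercept_se:
                r_s = 0.0
            # moment guard for the genetic covariance, mirroring the h2 guard
            s_i, s_j, _ = _harmonize(stats_list[i], stats_list[j])
            z_i, z_j = s_i["Z"].to_numpy(), s_j["Z"].to_numpy()
            l_ij = lds.aligned_scores(s_i["ID"])
            ok = np.isfinite(l_ij)
            N_ij = np.sqrt(float(s_i["N"].mean()) * float(s_j["N"].mean()))
            rho_mom = float((np.mean(z_i[ok] * z_j[ok]) - r_s) * lds.M
                            / (N_ij * np.mean(l_ij[ok])))
            if abs(rho) < abs(rho_mom) / 3.0:
                warnings.warn(
                    f"pair ({i},{j}): LDSC slope rho_g={rho:.3f} inconsistent with "
                    f"mean Z1*Z2 (MoM rho_g={rho_mom:.3f}); using the moment estimate",
                    stacklevel=2)
                rho = rho_mom
            omega[i, j] = omega[j, i] = rho / lds.M
            overlap[i, j] = overlap[j, i] = r_s
    # keep pairwise correlations away from +/-1: a (clipped) perfect estimate
    # makes the joint estimator lean entirely on the partner trait
    d = np.sqrt(np.diag(omega))
    corr = omega / np.outer(d, d)
    off = ~np.eye(T, dtype=bool)
    corr[off] = np.clip(corr[off], -0.98, 0.98)
    omega = corr * np.outer(d, d)
    if np.min(np.linalg.eigvalsh(omega)) < 0:
        omega = _project_psd(omega)
    return omega, overlap


def mtag(stats_list: list[pd.DataFrame], omega: np.ndarray,
         sigma_overlap: np.ndarray | None = None,
         trait_names: list[str] | None = None) -> MtagResult:
    """Moment-based joint estimator across traits, per SNP.

    Inputs are per-trait summary tables in the standard dialect, aligned
    internally on SNP ID with allele harmonization.  ``omega`` is the T x T
    per-SNP genetic covariance on the standardized (Z/sqrt(N)) effect scale;
    ``sigma_overlap`` the T x T sampling-correlation matrix (identity =
    disjoint samples).  Joint effects are mapped back to each trait's input
    beta scale; joint p-values are two-sided normal.
    """
    T = len(stats_list)
    if omega.shape != (T, T):
        raise ParameterError("omega not conformable with the number of traits")
    if sigma_overlap is None:
        sigma_overlap = np.eye(T)
    if trait_names is None:
        trait_names = [f"trait_{t + 1}" for t in range(T)]

    if T == 1:
        out = stats_list[0].copy()
        return MtagResult(tables={trait_names[0]: out}, omega=omega.copy(),
                          sigma_overlap=sigma_overlap.copy(), traits=list(trait_names))

    base = stats_list[0]
    aligned = [base]
    for s in stats_list[1:]:
        a0, a = _harmonize(base, s)[:2]
        base = a0
        aligned.append(a)
    # re-align earlier tables to the final (possibly reduced) SNP set
    ids = base["ID"]
    aligned = [a.set_index("ID").loc[ids].reset_index() for a in aligned]

    m = len(ids)
    N = np.array([float(a["N"].mean()) for a in aligned])
    # standardized effects and SEs: beta_std = Z / sqrt(N), se_std = 1/sqrt(N)
    Z = np.column_stack([a["Z"].to_numpy() for a in aligned])
    beta_std = Z / np.sqrt(N)[None, :]
    se_std = np.ones_like(Z) / np.sqrt(N)[None, :]

    joint_z = np.full((m, T), np.nan)
    joint_beta_std = np.full((m, T), np.nan)
    joint_se_std = np.full((m, T), np.nan)
    eye = np.eye(T)
    for t in range(T):
        om_t = omega[:, t]
        x = om_t / omega[t, t]
        A = omega - np.outer(om_t, om_t) / omega[t, t]
        for j in range(m):
            s = se_std[j]
            sigma_j = sigma_overlap * np.outer(s, s)
            Winv = A + sigma_j
            try:
                W = np.linalg.inv(Winv)
            except np.linalg.LinAlgError:
                warnings.warn("singular weight matrix; ridge-stabilized", stacklevel=2)
                W = np.linalg.inv(Winv + 1e-10 * np.trace(Winv) / T * eye)
            denom = float(x @ W @ x)
            if denom <= 0:
                continue
            joint_beta_std[j, t] = float(x @ W @ beta_std[j]) / denom
            joint_se_std[j, t] = 1.0 / np.sqrt(denom)
        joint_z[:, t] = joint_beta_std[:, t] / joint_se_std[:, t]

    tables = {}
    for t, name in enumerate(trait_names):
        a = aligned[t]
        scale = a["SE"].to_numpy() * np.sqrt(N[t])  # beta_raw / beta_std per SNP
        out = a.copy()
        out["BETA"] = joint_beta_std[:, t] * scale
        out["SE"] = joint_se_std[:, t] * scale
        out["Z"] = joint_z[:, t]
        out["P"] = 2.0 * sstats.norm.sf(np.abs(joint_z[:, t]))
        tables[name] = out[SUMSTATS_COLUMNS].reset_index(drop=True)
    return MtagResult(tables=tables, omega=omega.copy(),
                      sigma_overlap=sigma_overlap.copy(), traits=list(trait_names))


def mtag_significant(result: MtagResult, gwas_sets: dict[str, set[str]],
                     threshold: float = 5.61e-6) -> dict[str, object]:
    """Per-trait significant sets, set algebra vs GWAS, and pleiotropy flags.

    Returns a dict with per-trait significant MTAG SNP IDs, the shared /
    MTAG-only / GWAS-only partition against the supplied GWAS significant
    sets, and SNPs significant for two or more traits flagged pleiotropic
    with their trait lists.
    """
    mtag_sets = {}
    for name, table in result.tables.items():
        mtag_sets[name] = set(table.loc[table["P"] < threshold, "ID"])
    mtag_union = set().union(*mtag_sets.values()) if mtag_sets else set()
    gwas_union = set().union(*gwas_sets.values()) if gwas_sets else set()
    trait_hits: dict[str, list[str]] = {}
    for name, ids in mtag_sets.items():
        for snp in ids:
            trait_hits.setdefault(snp, []).append(name)
    pleiotropic = {snp: sorted(ts) for snp, ts in trait_hits.items() if len(ts) >= 2}
    return {
        "mtag": mtag_sets,
        "shared": mtag_union & gwas_union,
        "mtag_only": mtag_union - gwas_union,
        "gwas_only": gwas_union - mtag_union,
        "pleiotropic": pleiotropic,
    }
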