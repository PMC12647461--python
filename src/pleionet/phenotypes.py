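"""Phenotype QC, multi-environment variance decomposition, BLUP and heritability.

The model for one trait observed on inbred lines in L environments with R
replicates is

    y_ijr = mu + env_j + line_i + (line x env)_ij + e_ijr

with environment fixed and line and line-by-environment random.  On
balanced data the variance components are estimated by equating ANOVA mean
squares to their expectations; on unbalanced data (e.g. after outlier
removal) a REML fit of the same model is used.  Broad-sense heritability on
a line-mean basis is

    H2 = V_g / (V_g + V_ge/L + V_e/(R*L)).

BLUPs of line genotypic values are the grand mean plus the line-mean
deviation shrunk by V_g / Var(line mean).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import BLUPTable, ParameterError, RawPhenotypeTable, VarianceComponents


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------

def remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear-interpolation (type-7) quantiles.  Returns the kept
    values and the indices of the removed ones.  Requires at least 4 finite
    values; an all-identical vector has zero IQR and nothing is removed.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise ParameterError("outlier rule needs at least 4 finite values")
    q1, q3 = np.quantile(values[finite], [0.25, 0.75])  # type-7 default
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = finite & ((values < lo) | (values > hi))
    return values[~out & finite], np.where(out)[0]


def qc_phenotypes(raw: RawPhenotypeTable) -> RawPhenotypeTable:
    """Apply the IQR outlier rule per trait x environment."""
    kept = []
    for (_, _), grp in raw.data.groupby(["trait", "env"], sort=False):
        vals = grp["value"].to_numpy()
        if np.isfinite(vals).sum() < 4:
            kept.append(grp)
            continue
        _, removed = remove_outliers(vals)
        mask = np.ones(len(grp), dtype=bool)
        mask[removed] = False
        kept.append(grp.iloc[mask])
    return RawPhenotypeTable(data=pd.concat(kept, ignore_index=True), truth=raw.truth)


# ---------------------------------------------------------------------------
# variance components + BLUP
# ---------------------------------------------------------------------------

def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["line", "env"], sort=False)["value"].count()
    n_lines = df["line"].nunique()
    n_envs = df["env"].nunique()
    return len(counts) == n_lines * n_envs and counts.nunique() == 1


def _anova_ems(df: pd.DataFrame) -> tuple[float, float, float, int, int]:
    """Expected-mean-squares estimates on balanced line x env x rep data."""
    lines = df["line"].unique()
    envs = df["env"].unique()
    n, L = len(lines), len(envs)
    R = int(df.groupby(["line", "env"])["value"].count().iloc[0])

    grand = df["value"].mean()
    cell = df.groupby(["line", "env"])["value"].mean()
    line_mean = df.groupby("line")["value"].mean()
    env_mean = df.groupby("env")["value"].mean()

    ss_line = L * R * float(((line_mean - grand) ** 2).sum())
    ss_env = n * R * float(((env_mean - grand) ** 2).sum())
    cell_df = cell.reset_index()
    cell_df["pred"] = (line_mean.reindex(cell_df["line"]).to_numpy()
                       + env_mean.reindex(cell_df["env"]).to_numpy() - grand)
    ss_inter = R * float(((cell_df["value"] - cell_df["pred"]) ** 2).sum())
    merged = df.merge(cell.rename("cell_mean"), on=["line", "env"])
    ss_err = float(((merged["value"] - merged["cell_mean"]) ** 2).sum())

    ms_line = ss_line / (n - 1)
    ms_inter = ss_inter / ((n - 1) * (L - 1)) if L > 1 else np.nan
    ms_err = ss_err / (n * L * (R - 1)) if R > 1 else np.nan

    # E[MS_line] = Ve + R*Vge + L*R*Vg ; E[MS_inter] = Ve + R*Vge ; E[MS_err] = Ve
    if R > 1 and L > 1:
        V_e = ms_err
        V_ge = max((ms_inter - ms_err) / R, 0.0)
        V_g = max((ms_line - ms_inter) / (L * R), 0.0)
    elif L > 1:  # no replication: Ve and Vge confounded; assign to Ve
        V_e = ms_inter
        V_ge = 0.0
        V_g = max((ms_line - ms_inter) / (L * R), 0.0)
    elif R > 1:  # single environment: Vge unidentifiable
        V_e = ms_err
        V_ge = 0.0
        V_g = max((ms_line - ms_err) / R, 0.0)
    else:
        raise ParameterError("V_e and V_ge unidentifiable without replication or multi-env")
    return V_g, V_ge, V_e, L, R


def _reml_mixedlm(df: pd.DataFrame) -> tuple[float, float, float, int, int]:
    """REML fit of the line + line x env random model (unbalanced data)."""
    import statsmodels.formula.api as smf

    L = df["env"].nunique()
    R = max(int(round(df.groupby(["line", "env"])["value"].count().mean())), 1)
    vc = {"gxe": "0 + C(env)"} if L > 1 else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(env)", df, groups=df["line"],
                            re_formula="1", vc_formula=vc or None)
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    V_g = max(float(np.asarray(fit.cov_re).ravel()[0]), 0.0)
    V_ge = max(float(fit.vcomp[0]), 0.0) if vc else 0.0
    V_e = max(float(fit.scale), 0.0)
    return V_g, V_ge, V_e, L, R


def fit_variance_components(raw: RawPhenotypeTable,
                            trait: str) -> tuple[VarianceComponents, BLUPTable]:
    """Estimate (V_g, V_ge, V_e) for one trait and BLUP the line values.

    Balanced data uses closed-form ANOVA expected mean squares; unbalanced
    data falls back to REML.  Negative estimates are truncated at zero.
    Lines never observed are excluded; the returned BLUP table contains the
    grand mean plus the shrunken line-mean deviation for each line.
    """
    df = raw.data[raw.data["trait"] == trait].dropna(subset=["value"]).copy()
    if df.empty:
        raise ParameterError(f"no observations for trait {trait}")
    n_lines = df["line"].nunique()
    L = df["env"].nunique()
    if n_lines < 10:
        raise ParameterError("need >= 10 lines to fit variance components")
    reps = df.groupby(["line", "env"])["value"].count()
    if L < 2 and reps.max() < 2:
        raise ParameterError("V_e and V_ge unidentifiable without replication or multi-env")

    if _is_balanced(df):
        V_g, V_ge, V_e, L, R = _anova_ems(df)
    else:
        V_g, V_ge, V_e, L, R = _reml_mixedlm(df)
    vc = VarianceComponents(V_g=V_g, V_ge=V_ge, V_e=V_e, L=L, R=R)

    # two-stage BLUP from env-adjusted line means
    env_mean = df.groupby("env")["value"].transform("mean")
    df["adj"] = df["value"] - env_mean
    line_dev = df.groupby("line")["adj"].mean()
    grand = float(df["value"].mean())
    var_mean = V_g + V_ge / L + V_e / (vc.R * L)
    shrink = V_g / var_mean if var_mean > 0 else 0.0
    blup_vals = grand + shrink * (line_dev - line_dev.mean())
    table = BLUPTable(values=blup_vals.to_frame(name=trait),
                      grand_means={trait: grand})
    return vc, table


def blup_all_traits(raw: RawPhenotypeTable) -> tuple[dict[str, VarianceComponents], BLUPTable]:
    """Fit every trait in the table; returns components per trait and a joint BLUP table."""
    comps: dict[str, VarianceComponents] = {}
    cols = []
    grand = {}
    for trait in raw.traits:
        vc, tbl = fit_variance_components(raw, trait)
        comps[trait] = vc
        cols.append(tbl.values[trait])
        grand[trait] = tbl.grand_means[trait]
    values = pd.concat(cols, axis=1)
    return comps, BLUPTable(values=values, grand_means=grand)


# ---------------------------------------------------------------------------
# heritability / CV / correlations
# ---------------------------------------------------------------------------

def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = V_g / (V_g + V_ge/L + V_e/(R*L))."""
    denom = vc.V_g + vc.V_ge / vc.L + vc.V_e / (vc.R * vc.L)
    if denom <= 0:
        raise ParameterError("zero denominator: all variance components are zero")
    return vc.V_g / denom


def coefficient_of_variation(values: np.ndarray, percent: bool = False) -> float:
    """Sample standard deviation divided by the mean (optionally as %)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ParameterError("CV undefined for zero mean")
    cv = values.std(ddof=1) / mean
    return 100.0 * cv if percent else cv


def trait_summary(raw: RawPhenotypeTable,
                  comps: dict[str, VarianceComponents],
                  categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-trait CV (on raw values) and H2 table."""
    rows = []
    for trait, vc in comps.items():
        vals = raw.data.loc[raw.data["trait"] == trait, "value"].dropna().to_numpy()
        rows.append({
            "trait": trait,
            "CV": coefficient_of_variation(vals),
            "H2": heritability(vc),
            "category": (categories or {}).get(trait, ""),
        })
    return pd.DataFrame(rows).set_index("trait")


def trait_correlations(blup: BLUPTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between trait BLUPs with two-sided p-values.

    Pairwise-complete observations; zero-variance traits yield NaN entries
    (flagged with a warning).  The correlation matrix is symmetric with a
    unit diagonal wherever defined.
    """
    traits = blup.traits
    t = len(traits)
    r = np.full((t, t), np.nan)
    p = np.full((t, t), np.nan)
    for i in range(t):
        for j in range(i, t):
            xi = blup.values[traits[i]]
            xj = blup.values[traits[j]]
            ok = xi.notna() & xj.notna()
            if ok.sum() < 3:
                continue
            a, b = xi[ok].to_numpy(), xj[ok].to_numpy()
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"zero-variance trait in pair ({traits[i]}, {traits[j]})",
                              stacklevel=2)
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                rr, pp = sstats.pearsonr(a, b)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    return rdf, pdf
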