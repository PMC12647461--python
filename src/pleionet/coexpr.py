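"""Relative expression (2^-ddCt) and gene-pair co-expression statistics.

RT-qPCR cycle thresholds are converted to relative expression with the
2^-ddCt method: dCt = Ct_target - Ct_reference, ddCt = dCt - dCt_calibrator,
relative expression = 2^(-ddCt).  Pearson correlations between the tissue
profiles of designated gene pairs are tested two-sided and corrected for
multiple testing with the Benjamini-Hochberg step-up within each
developmental stage, reproducing the gene1/gene2/r/FDR/stage table layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import ParameterError

STAGES = ("flare_opening", "tasseling")


@dataclass
class ExpressionMatrix:
    """Genes x tissues relative-expression values for one developmental stage."""

    values: pd.DataFrame  # index = gene, columns = tissues
    stage: str = "flare_opening"

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ParameterError("need >= 3 tissues for correlation to be defined")
        if (self.values.to_numpy() <= 0).any():
            raise ParameterError("relative expression must be positive")


def relative_expression(ct_target: float | np.ndarray, ct_reference: float | np.ndarray,
                        calibrator_delta: float | np.ndarray = 0.0) -> np.ndarray:
    """2^-ddCt relative expression from cycle thresholds.

    ddCt = (ct_target - ct_reference) - calibrator_delta; strictly
    decreasing in ddCt; ddCt = 0 maps to 1.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))
            and np.all(np.isfinite(calibrator_delta))):
        raise ParameterError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - calibrator_delta
    return 2.0 ** (-ddct)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min over j >= i of m * p(j) / j on the sorted p-values, capped
    at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def significance_stars(p: float) -> str:
    """Fig.-style significance markers at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pair_correlations(expr: ExpressionMatrix,
                      pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r, raw p and BH FDR per gene pair within one stage.

    Pairs with a constant expression vector are flagged undefined (NaN r/p)
    and excluded from the FDR correction.  Returns columns gene1, gene2, r,
    p, fdr, stars, stage.
    """
    rows = []
    for g1, g2 in pairs:
        for gname in (g1, g2):
            if gname not in expr.values.index:
                raise ParameterError(f"gene {gname} missing from the expression matrix")
        x = expr.values.loc[g1].to_numpy(dtype=float)
        y = expr.values.loc[g2].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ParameterError(f"pair ({g1}, {g2}) shares fewer than 3 tissues")
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"constant expression for pair ({g1}, {g2}); flagged undefined",
                          stacklevel=2)
            rows.append({"gene1": g1, "gene2": g2, "r": np.nan, "p": np.nan})
            continue
        r, p = sstats.pearsonr(x, y)
        rows.append({"gene1": g1, "gene2": g2, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "fdr"] = bh_fdr(out.loc[defined, "p"].to_numpy())
    out["stars"] = [significance_stars(q) if np.isfinite(q) else "" for q in out["fdr"]]
    out["stage"] = expr.stage
    return out


def select_pairs_from_network(net, genes_by_qtl: dict[str, list[str]],
                              min_inter_ld: float = 0.8, k: int = 30,
                              rng: np.random.Generator | None = None,
                              ) -> list[tuple[str, str]]:
    """Gene pairs drawn from QTL pairs with Inter-LD strictly above the threshold.

    QTL pairs are ranked by Inter-LD descending (ties by ids); one gene pair
    is taken per QTL pair (the first annotated gene of each region, or a
    random one when ``rng`` is given), deduplicated, and the top ``k``
    returned.  Fewer than ``k`` qualifying pairs returns them all with a
    warning.
    """
    edges = [(d["inter_ld"], u, v) for u, v, d in net.graph.edges(data=True)
             if d.get("edge_type") == "inter_ld" and d.get("inter_ld", 0.0) > min_inter_ld]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    out: list[tuple[str, str]] = []
    seen = set()
    for _, u, v in edges:
        gu = genes_by_qtl.get(u) or []
        gv = genes_by_qtl.get(v) or []
        if not gu or not gv:
            continue
        g1 = gu[int(rng.integers(len(gu)))] if rng is not None else gu[0]
        g2 = gv[int(rng.integers(len(gv)))] if rng is not None else gv[0]
        if g1 == g2:
            continue
        key = tuple(sorted((g1, g2)))
        if key in seen:
            continue
        seen.add(key)
        out.append((g1, g2))
        if len(out) == k:
            return out
    if len(out) < k:
        warnings.warn(f"only {len(out)} qualifying gene pairs (requested {k})",
                      stacklevel=2)
    return out


def table2_shape(results: pd.DataFrame, genes: pd.DataFrame | None = None,
                 fdr_max: float = 0.05) -> pd.DataFrame:
    """Significant pairs in the gene1/location/gene2/location/r/FDR/stage layout."""
    sig = results[results["fdr"] < fdr_max].copy()
    if genes is not None:
        loc = {r.gene_id: f"{r.chrom}:{r.start}-{r.end}" for r in genes.itertuples()}
        sig["gene1_location"] = sig["gene1"].map(loc)
        sig["gene2_location"] = sig["gene2"].map(loc)
        cols = ["gene1", "gene1_location", "gene2", "gene2_location", "r", "fdr", "stage"]
    else:
        cols = ["gene1", "gene2", "r", "fdr", "stage"]
    return sig[cols].reset_index(drop=True)
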