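"""Clumping of summary statistics into QTL regions and candidate-gene annotation.

Clumping is the greedy lead-SNP procedure: repeatedly take the most
significant unassigned SNP below the p threshold as a lead, then assign to
it every unassigned significant SNP on the same chromosome within the
clump window and in LD (r2 >= r2_min) with it.  Ties in p are broken by
(chrom, pos) ascending, making the output deterministic.  A QTL region's
interval is the span of its member SNPs (1-based, closed).

Candidate genes are genes whose interval intersects a window of
``window_bp`` up- and downstream of a significant SNP (boundary inclusive).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assoc_scan import SIGNIFICANCE_THRESHOLD, ld_matrix
from .containers import CandidateGene, GenotypeMatrix, ParameterError, QTLRegion


def clump(stats: pd.DataFrame, geno: GenotypeMatrix, trait: str = "",
          p_threshold: float = SIGNIFICANCE_THRESHOLD, r2_min: float = 0.2,
          window_bp: int = 500_000) -> list[QTLRegion]:
    """Greedy LD clumping of significant SNPs into QTL regions.

    Every significant SNP ends up in exactly one region.  Returns an empty
    list when nothing is significant.
    """
    sig = stats[stats["P"] < p_threshold]
    if sig.empty:
        return []
    id_to_col = {sid: j for j, sid in enumerate(geno.snps["id"])}
    missing = [s for s in sig["ID"] if s not in id_to_col]
    if missing:
        raise ParameterError(f"significant SNPs absent from genotypes, e.g. {missing[:5]}")

    sig = sig.sort_values(["P", "CHR", "POS"]).reset_index(drop=True)
    cols = np.array([id_to_col[s] for s in sig["ID"]])
    r2 = ld_matrix(geno, cols)

    unassigned = np.ones(len(sig), dtype=bool)
    regions: list[QTLRegion] = []
    chrom = sig["CHR"].to_numpy()
    pos = sig["POS"].to_numpy()
    k = 0
    while unassigned.any():
        lead = int(np.argmax(unassigned))  # first unassigned = best remaining p
        members = np.where(
            unassigned
            & (chrom == chrom[lead])
            & (np.abs(pos - pos[lead]) <= window_bp)
            & (np.nan_to_num(r2[lead], nan=0.0) >= r2_min)
        )[0]
        members = np.union1d(members, [lead])
        unassigned[members] = False
        k += 1
        member_pos = pos[members]
        regions.append(QTLRegion(
            id=f"QTL{k}" if not trait else f"{trait}_QTL{k}",
            trait=trait,
            chrom=str(chrom[lead]),
            start=int(member_pos.min()),
            end=int(member_pos.max()),
            lead_id=str(sig["ID"].iloc[lead]),
            lead_pos=int(pos[lead]),
            lead_p=float(sig["P"].iloc[lead]),
            member_ids=sig["ID"].iloc[members].tolist(),
            member_index=cols[members],
        ))
    return regions


def qtl_table(regions: list[QTLRegion]) -> pd.DataFrame:
    """QTL regions as the TSV-ready table."""
    cols = ["qtl_id", "trait", "chrom", "start", "end", "lead_id", "lead_pos",
            "lead_p", "n_members", "member_ids"]
    return pd.DataFrame([{
        "qtl_id": r.id, "trait": r.trait, "chrom": r.chrom, "start": r.start,
        "end": r.end, "lead_id": r.lead_id, "lead_pos": r.lead_pos,
        "lead_p": r.lead_p, "n_members": r.n_members,
        "member_ids": ",".join(r.member_ids),
    } for r in regions], columns=cols)


def regions_from_table(table: pd.DataFrame, geno: GenotypeMatrix) -> list[QTLRegion]:
    """Rebuild QTLRegion objects from a written QTL table (resume path)."""
    id_to_col = {sid: j for j, sid in enumerate(geno.snps["id"])}
    regions = []
    for row in table.itertuples():
        member_ids = str(row.member_ids).split(",") if row.n_members else []
        missing = [m for m in member_ids if m not in id_to_col]
        if missing:
            raise ParameterError(f"QTL members absent from genotypes, e.g. {missing[:5]}")
        regions.append(QTLRegion(
            id=row.qtl_id, trait=row.trait, chrom=str(row.chrom),
            start=int(row.start), end=int(row.end), lead_id=row.lead_id,
            lead_pos=int(row.lead_pos), lead_p=float(row.lead_p),
            member_ids=member_ids,
            member_index=np.array([id_to_col[m] for m in member_ids], dtype=int)))
    return regions


def annotate_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                   window_bp: int = 10_000) -> list[CandidateGene]:
    """Genes whose interval intersects [pos - window, pos + window] of any SNP.

    ``snps`` needs columns CHR, POS, ID and optionally TRAIT; ``genes`` the
    columns gene_id, chrom, start, end.  Intervals are 1-based closed and
    the window boundary is inclusive.  Genes hit by several SNPs are
    reported once with all traits and SNPs attached.
    """
    snp_chroms = set(snps["CHR"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if snp_chroms and not (snp_chroms & gene_chroms):
        raise ParameterError(
            f"chromosome naming mismatch: SNPs use {sorted(snp_chroms)[:5]}, "
            f"genes use {sorted(gene_chroms)[:5]}")

    hits: dict[str, CandidateGene] = {}
    for _, snp in snps.iterrows():
        chrom = str(snp["CHR"])
        lo, hi = snp["POS"] - window_bp, snp["POS"] + window_bp
        sub = genes[(genes["chrom"].astype(str) == chrom)
                    & (genes["end"] >= lo) & (genes["start"] <= hi)]
        for _, gene in sub.iterrows():
            if gene["start"] <= snp["POS"] <= gene["end"]:
                dist = 0
            else:
                dist = int(min(abs(gene["start"] - snp["POS"]),
                               abs(gene["end"] - snp["POS"])))
            trait = str(snp.get("TRAIT", "")) if "TRAIT" in snps.columns else ""
            g = hits.get(gene["gene_id"])
            if g is None:
                hits[gene["gene_id"]] = CandidateGene(
                    gene_id=gene["gene_id"], chrom=chrom,
                    start=int(gene["start"]), end=int(gene["end"]),
                    distance_bp=dist,
                    traits=[trait] if trait else [],
                    snp_ids=[str(snp["ID"])])
            else:
                g.distance_bp = min(g.distance_bp, dist)
                if trait and trait not in g.traits:
                    g.traits.append(trait)
                if str(snp["ID"]) not in g.snp_ids:
                    g.snp_ids.append(str(snp["ID"]))
    return sorted(hits.values(), key=lambda g: (g.chrom, g.start))


def ld_window_from_decay(decay: pd.DataFrame) -> float:
    """Distance at which mean r2 first falls to half its short-range maximum.

    ``decay`` is the curve from :func:`pleionet.assoc_scan.ld_decay`.
    Linear interpolation between bin midpoints; if the curve never drops
    below half-max, the maximum distance is returned with a warning.
    """
    curve = decay.dropna(subset=["mean_r2"])
    if curve.empty:
        raise ParameterError("decay curve has no populated bins")
    mid = ((curve["bin_start"] + curve["bin_end"]) / 2.0).to_numpy()
    r2 = curve["mean_r2"].to_numpy()
    peak = float(r2[0])  # short-range maximum = first populated bin
    half = peak / 2.0
    below = np.where(r2 <= half)[0]
    if below.size == 0:
        warnings.warn("LD never decays to half its short-range maximum; "
                      "returning the maximum distance", stacklevel=2)
        return float(curve["bin_end"].iloc[-1])
    j = int(below[0])
    if j == 0:
        return float(mid[0])
    x0, x1 = mid[j - 1], mid[j]
    y0, y1 = r2[j - 1], r2[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
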