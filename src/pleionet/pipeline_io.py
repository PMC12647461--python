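"""Configuration, shared format readers/writers and pipeline orchestration.

File formats at the package boundary are text standards: VCF v4.2 for
genotypes (read through cyvcf2; written by a small emitter for the {0,2}
inbred dosage matrix), GFF3 for gene annotation, and TSV for phenotypes
(line, env, rep, trait, value), summary statistics, BLUPs, QTL tables and
expression matrices.  Coordinates are 1-based in every file and converted
at the boundary.

``run_all`` chains the stages — phenotype QC/BLUP, per-trait GWAS,
LDSC/MTAG, clumping, gene annotation, network construction and
co-expression — writing each stage's outputs under one directory and a
manifest with content digests, so deterministic stages can be verified to
reproduce and completed stages can be skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (BLUPTable, GenotypeMatrix, ParameterError, RawPhenotypeTable,
                         SUMSTATS_COLUMNS, validate_sumstats)

logger = logging.getLogger("pleionet")


@dataclass
class PipelineConfig:
    """All thresholds and model choices of a full pipeline run.

    Defaults are the analysis constants: significance threshold 5.61e-6,
    Inter-LD edge threshold 0.4, candidate-gene window 10 kb, QC at MAF 0.05
    and missingness 0.20, LD decay to 600 kb, 11 principal components.
    """

    vcf: str = ""
    phenotypes: str = ""
    gff: str = ""
    expression: str = ""
    p_threshold: float = 5.61e-6
    min_inter_ld: float = 0.4
    coexpr_inter_ld: float = 0.8
    gene_window_bp: int = 10_000
    qc_maf: float = 0.05
    qc_missing: float = 0.20
    ld_decay_max_bp: int = 600_000
    clump_r2: float = 0.2
    clump_window_bp: int = 500_000
    ldsc_window_bp: int = 1_000_000
    model: str = "ols"
    n_pcs: int = 11
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ParameterError("p_threshold must lie in (0, 1)")
        if not (0 <= self.min_inter_ld):
            raise ParameterError("min_inter_ld must be >= 0")
        if not (0 <= self.qc_maf <= 0.5):
            raise ParameterError("qc_maf must lie in [0, 0.5]")
        if not (0 <= self.qc_missing <= 1):
            raise ParameterError("qc_missing must lie in [0, 1]")
        if self.model not in ("ols", "mlm"):
            raise ParameterError("model must be 'ols' or 'mlm'")
        if self.n_pcs < 0:
            raise ParameterError("n_pcs must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Emit the dosage matrix as VCF v4.2 with GT fields (0/0, 1/1 or ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.lines) + "\n")
        codes = {0.0: "0/0", 2.0: "1/1"}
        for j, snp in enumerate(geno.snps.itertuples()):
            d = geno.dosages[:, j]
            gts = "\t".join("./." if np.isnan(v) else codes[v] for v in d)
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into the dosage matrix.

    Non-biallelic records are skipped and counted (logged); genotypes are
    converted to alternate-allele dosage with heterozygotes counted as 1
    (never produced by the simulator but tolerated on input).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    chroms, poss, ids, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.genotype.array(), dtype=float)[:, :2]
        dose = gt.sum(axis=1)
        dose[np.any(gt < 0, axis=1)] = np.nan
        rows.append(dose)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"snp_{var.CHROM}_{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    if not rows:
        raise ParameterError(f"no biallelic SNPs in {path}")
    snps = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids,
                         "ref": refs, "alt": alts})
    return GenotypeMatrix(dosages=np.column_stack(rows), lines=lines, snps=snps)


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table as GFF3 (gene features only, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\tpleionet\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features from GFF3 into a gene table; other features ignored."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParameterError(f"{path}:{ln}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append({"gene_id": attrs.get("ID", f"gene_at_{parts[0]}_{parts[3]}"),
                         "chrom": parts[0], "start": int(parts[3]),
                         "end": int(parts[4]), "strand": parts[6]})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_pheno(raw: RawPhenotypeTable, path: str | Path) -> None:
    raw.data.to_csv(path, sep="\t", index=False)


def read_pheno(path: str | Path) -> RawPhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "env": str})
    return RawPhenotypeTable(data=df)


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    validate_sumstats(stats).to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "ID": str})
    return validate_sumstats(df[SUMSTATS_COLUMNS])


def write_blup(blup: BLUPTable, path: str | Path) -> None:
    out = blup.values.copy()
    out.index.name = "line"
    out.to_csv(path, sep="\t")


def read_blup(path: str | Path) -> BLUPTable:
    df = pd.read_csv(path, sep="\t", index_col="line")
    df.index = df.index.astype(str)
    return BLUPTable(values=df, grand_means={c: float(df[c].mean()) for c in df.columns})


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig, out_dir: str | Path,
            resume: bool = False) -> dict:
    """Run the full chain and return the manifest.

    Stages: pheno -> gwas (per trait) -> ldsc/mtag -> clump -> annotate ->
    network -> coexpr.  Each stage's outputs land under ``out_dir``; with
    ``resume=True`` a stage whose outputs already exist is skipped and its
    files are reused.  The manifest records the config digest, seed, and a
    sha256 digest plus wall-clock time per stage.
    """
    from . import assoc_scan, coexpr, multi_trait, network, peaks, phenotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.seed is None:
        logger.warning("no seed set in config; stochastic stages are unseeded")
    manifest: dict = {"config_digest": config.digest(), "version": __version__,
                      "seed": config.seed, "stages": {}}

    def stage(name: str, outputs: list[Path], fn) -> None:
        t0 = time.perf_counter()
        if resume and all(p.exists() for p in outputs):
            logger.info("stage %s: outputs present, skipping", name)
            status = "cached"
        else:
            logger.info("stage %s: running", name)
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise ParameterError(f"stage {name} failed: {exc}") from exc
            status = "ok"
        manifest["stages"][name] = {
            "status": status,
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    geno = read_vcf(config.vcf)
    geno, qc_report = assoc_scan.qc_genotypes(geno, max_missing=config.qc_missing,
                                              min_maf=config.qc_maf)
    raw = read_pheno(config.phenotypes)

    blup_path = out / "blup.tsv"
    vc_path = out / "variance_components.tsv"
    corr_path = out / "trait_correlations.tsv"

    state: dict = {}

    def do_pheno() -> None:
        clean = phenotypes.qc_phenotypes(raw)
        comps, blup = phenotypes.blup_all_traits(clean)
        write_blup(blup, blup_path)
        pd.DataFrame([{"trait": t, "V_g": c.V_g, "V_ge": c.V_ge, "V_e": c.V_e,
                       "L": c.L, "R": c.R,
                       "H2": phenotypes.heritability(c)}
                      for t, c in comps.items()]).to_csv(vc_path, sep="\t", index=False)
        rmat, _ = phenotypes.trait_correlations(blup)
        rmat.to_csv(corr_path, sep="\t")

    stage("pheno", [blup_path, vc_path, corr_path], do_pheno)
    blup = read_blup(blup_path)
    traits = blup.traits

    scores = None
    if config.n_pcs > 0:
        scores, _ = assoc_scan.pca(geno, k=config.n_pcs)
    K = assoc_scan.kinship(geno) if config.model == "mlm" else None

    stats_paths = {t: out / f"gwas_{t}.tsv" for t in traits}

    def do_gwas() -> None:
        for t in traits:
            stats = assoc_scan.gwas_scan(geno, blup, t, covariates=scores,
                                         model=config.model, K=K)
            write_sumstats(stats, stats_paths[t])

    stage("gwas", list(stats_paths.values()), do_gwas)
    stats_by_trait = {t: read_sumstats(p) for t, p in stats_paths.items()}

    mtag_paths = {t: out / f"mtag_{t}.tsv" for t in traits}
    omega_path = out / "omega_sigma.json"

    def do_mtag() -> None:
        lds = multi_trait.ld_scores(geno, window_bp=config.ldsc_window_bp)
        stats_list = [stats_by_trait[t] for t in traits]
        if len(traits) >= 2:
            omega, overlap = multi_trait.estimate_omega_sigma(stats_list, lds)
        else:
            omega, overlap = np.array([[1.0]]), np.array([[1.0]])
        result = multi_trait.mtag(stats_list, omega, overlap, trait_names=traits)
        for t in traits:
            write_sumstats(result.tables[t], mtag_paths[t])
        omega_path.write_text(json.dumps(
            {"traits": traits, "omega": omega.tolist(), "overlap": overlap.tolist()},
            indent=1))

    stage("mtag", [*mtag_paths.values(), omega_path], do_mtag)

    qtl_path = out / "qtl.tsv"
    state["qtls_by_trait"] = {}

    def do_clump() -> None:
        tables = []
        for t in traits:
            regions = peaks.clump(stats_by_trait[t], geno, trait=t,
                                  p_threshold=config.p_threshold,
                                  r2_min=config.clump_r2,
                                  window_bp=config.clump_window_bp)
            state["qtls_by_trait"][t] = regions
            if regions:
                tables.append(peaks.qtl_table(regions))
        table = (pd.concat(tables, ignore_index=True) if tables
                 else peaks.qtl_table([]))
        table.to_csv(qtl_path, sep="\t", index=False)

    stage("clump", [qtl_path], do_clump)
    if not state["qtls_by_trait"]:  # clump stage was cached; rebuild from the table
        table = pd.read_csv(qtl_path, sep="\t",
                            dtype={"chrom": str, "trait": str, "member_ids": str})
        regions = peaks.regions_from_table(table, geno) if not table.empty else []
        state["qtls_by_trait"] = {t: [] for t in traits}
        for r in regions:
            state["qtls_by_trait"].setdefault(r.trait, []).append(r)

    genes_path = out / "candidate_genes.tsv"
    genes = read_gff3(config.gff) if config.gff else pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand"])

    def do_annotate() -> None:
        sig_frames = []
        for t in traits:
            s = assoc_scan.significant_snps(stats_by_trait[t], config.p_threshold)
            if not s.empty:
                s = s.copy()
                s["TRAIT"] = t
                sig_frames.append(s)
        if sig_frames and not genes.empty:
            sig = pd.concat(sig_frames, ignore_index=True)
            cand = peaks.annotate_genes(sig, genes, window_bp=config.gene_window_bp)
        else:
            cand = []
        pd.DataFrame([{"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
                       "end": g.end, "distance_bp": g.distance_bp,
                       "traits": ",".join(g.traits), "snp_ids": ",".join(g.snp_ids)}
                      for g in cand]).to_csv(genes_path, sep="\t", index=False)

    stage("annotate", [genes_path], do_annotate)

    net_paths = [out / "network.graphml", out / "network.sif",
                 out / "network_edges.tsv", out / "network_nodes.tsv"]

    def do_network() -> None:
        net = network.build_network(state["qtls_by_trait"], geno,
                                    min_inter_ld=config.min_inter_ld)
        network.export_network(net, str(out / "network"))
        state["network"] = net

    stage("network", net_paths, do_network)

    coexpr_path = out / "coexpr.tsv"

    def do_coexpr() -> None:
        if not config.expression:
            pd.DataFrame(columns=["gene1", "gene2", "r", "p", "fdr", "stars",
                                  "stage"]).to_csv(coexpr_path, sep="\t", index=False)
            return
        expr_df = pd.read_csv(config.expression, sep="\t", index_col=0)
        stage_label = expr_df.attrs.get("stage", "flare_opening")
        expr = coexpr.ExpressionMatrix(values=expr_df, stage=stage_label)
        genes_list = list(expr.values.index)
        pairs = [(genes_list[i], genes_list[i + 1])
                 for i in range(0, len(genes_list) - 1, 2)]
        res = coexpr.pair_correlations(expr, pairs)
        res.to_csv(coexpr_path, sep="\t", index=False)

    stage("coexpr", [coexpr_path], do_coexpr)

    manifest["qc"] = {"n_input": qc_report.n_input,
                      "n_removed_missing": qc_report.n_removed_missing,
                      "n_removed_maf": qc_report.n_removed_maf,
                      "n_kept": qc_report.n_kept}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
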