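"""Synthetic maize-like inbred panel: genotypes, phenotypes, annotation, expression.

The generator emulates the statistical structure a dense-genotyped inbred
association panel presents to the downstream analysis: an LD-block genome
with fast decay, admixed subpopulations differentiated at a target Fst,
a MAF spectrum bounded away from zero, multi-environment phenotypes with
genotype, genotype-by-environment and residual variance components, and
pleiotropic causal regions shared between traits.  Every generator records
its ground truth (causal SNPs, effects, variance components, true genetic
correlations) next to the data so recovery can be tested.

Genotypes use a Balding-Nichols model for subpopulation allele frequencies
(Beta with parameters p(1-F)/F, (1-p)(1-F)/F around an ancestral frequency
p) and a Gaussian-copula block model for LD: within a block each line draws
one latent block factor, and each SNP's latent value is a mixture of the
block factor and independent noise, giving tunable within-block correlation
and near-zero correlation across blocks.  Lines are homozygous, so dosages
take values in {0, 2} only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import GenotypeMatrix, ParameterError, RawPhenotypeTable

TRAIT_CATEGORIES = ("plant_architecture", "flowering", "yield")

# Default panel: a desk-scale rendition of a large inbred association panel
# (thousands of lines, hundreds of thousands of SNPs, ~11 admixed subgroups)
# kept small enough that the full pipeline runs in seconds.
_DEFAULTS = dict(
    n_lines=500,
    n_snps=2000,
    n_chromosomes=5,
    chrom_length_bp=50_000_000,
    n_blocks_per_chrom=40,
    within_block_corr=0.85,
    n_subpops=4,
    fst=0.1,
    maf_range=(0.05, 0.5),
    seed=0,
)


@dataclass
class PanelSpec:
    """Parameters of the simulated inbred panel."""

    n_lines: int = _DEFAULTS["n_lines"]
    n_snps: int = _DEFAULTS["n_snps"]
    n_chromosomes: int = _DEFAULTS["n_chromosomes"]
    chrom_length_bp: int = _DEFAULTS["chrom_length_bp"]
    n_blocks_per_chrom: int = _DEFAULTS["n_blocks_per_chrom"]
    within_block_corr: float = _DEFAULTS["within_block_corr"]
    n_subpops: int = _DEFAULTS["n_subpops"]
    fst: float = _DEFAULTS["fst"]
    maf_range: tuple[float, float] = _DEFAULTS["maf_range"]
    seed: int = _DEFAULTS["seed"]
    #: Fraction of each line's ancestry mass on foreign subpopulations.
    admixture: float = 0.05

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ParameterError("n_lines must be >= 2")
        if self.n_snps < self.n_chromosomes:
            raise ParameterError("n_snps must be >= n_chromosomes")
        if not (0.0 <= self.within_block_corr <= 1.0):
            raise ParameterError("within_block_corr must lie in [0, 1]")
        if not (0.0 <= self.fst < 1.0):
            raise ParameterError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must satisfy 0 < min <= max <= 0.5")
        if self.n_subpops < 1:
            raise ParameterError("n_subpops must be >= 1")
        if not (0.0 <= self.admixture < 1.0):
            raise ParameterError("admixture must lie in [0, 1)")


@dataclass
class SharedRegion:
    """A causal region whose SNPs affect several traits with correlated effects.

    ``var_share``, if set, fixes the fraction of each affected trait's
    genetic variance contributed by this region (exact up to the LD-induced
    covariance between region and background contributions); left ``None``
    the region's weight is whatever the random effect draw gives.
    """

    snp_indices: np.ndarray
    traits: list[str]
    effect_corr: np.ndarray
    var_share: float | None = None

    def __post_init__(self) -> None:
        if self.var_share is not None and not (0.0 < self.var_share <= 1.0):
            raise ParameterError("var_share must lie in (0, 1]")
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        self.effect_corr = np.asarray(self.effect_corr, dtype=float)
        t = len(self.traits)
        if self.effect_corr.shape != (t, t):
            raise ParameterError("effect_corr must be square over the region's traits")
        if not np.allclose(np.diag(self.effect_corr), 1.0):
            raise ParameterError("effect_corr must have a unit diagonal")
        if np.min(np.linalg.eigvalsh((self.effect_corr + self.effect_corr.T) / 2)) < -1e-8:
            raise ParameterError("effect_corr must be positive semi-definite")


@dataclass
class TraitArchitecture:
    """Genetic architecture of a set of simulated traits.

    ``n_causal`` and ``h2_target`` may be a single value applied to every
    trait or a per-trait dict.  ``gxe_fraction`` splits the non-genetic part
    of the denominator of broad-sense heritability between the
    genotype-by-environment and residual components.
    """

    trait_names: list[str]
    n_causal: int | dict[str, int] = 50
    h2_target: float | dict[str, float] = 0.7
    shared_regions: list[SharedRegion] = field(default_factory=list)
    gxe_fraction: float = 0.2
    n_envs: int = 3
    n_reps: int = 2
    categories: dict[str, str] | None = None

    def causal_count(self, trait: str) -> int:
        return self.n_causal[trait] if isinstance(self.n_causal, dict) else self.n_causal

    def h2(self, trait: str) -> float:
        h2 = self.h2_target[trait] if isinstance(self.h2_target, dict) else self.h2_target
        if not (0.0 < h2 <= 1.0):
            raise ParameterError(f"h2_target for {trait} must lie in (0, 1]")
        return h2

    def variance_components(self, trait: str) -> tuple[float, float, float]:
        """(V_g, V_ge, V_e) implied by the trait's H2 target, with V_g = 1.

        Splits the non-genetic part of the H2 denominator between the
        genotype-by-environment and residual components per
        ``gxe_fraction``.
        """
        h2 = self.h2(trait)
        D = (1.0 - h2) / h2
        return 1.0, self.gxe_fraction * D * self.n_envs, \
            (1.0 - self.gxe_fraction) * D * self.n_reps * self.n_envs

    def plot_variance(self, trait: str) -> float:
        """Variance of a single observation: V_g + V_ge + V_e."""
        return sum(self.variance_components(trait))

    def __post_init__(self) -> None:
        if not self.trait_names:
            raise ParameterError("at least one trait required")
        if not (0.0 <= self.gxe_fraction < 1.0):
            raise ParameterError("gxe_fraction must lie in [0, 1)")
        if self.n_envs < 1 or self.n_reps < 1:
            raise ParameterError("n_envs and n_reps must be >= 1")
        for region in self.shared_regions:
            unknown = set(region.traits) - set(self.trait_names)
            if unknown:
                raise ParameterError(f"shared region names unknown traits: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _chrom_snp_counts(n_snps: int, n_chrom: int) -> list[int]:
    base = n_snps // n_chrom
    counts = [base] * n_chrom
    for i in range(n_snps - base * n_chrom):
        counts[i] += 1
    return counts


def _draw_subpop_freqs(rng: np.random.Generator, n: int, n_subpops: int,
                       fst: float, maf_lo: float) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, shape (n_subpops, n)."""
    p0 = rng.uniform(maf_lo, 1.0 - maf_lo, size=n)
    if fst <= 0 or n_subpops == 1:
        return np.tile(p0, (n_subpops, 1))
    a = p0 * (1.0 - fst) / fst
    b = (1.0 - p0) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_subpops, n))


def simulate_genotypes(spec: PanelSpec) -> GenotypeMatrix:
    """Simulate an inbred panel's dosage matrix under the block-copula LD model.

    Deterministic for a fixed ``spec.seed``.  SNPs whose realized MAF falls
    outside ``spec.maf_range`` are resampled (new ancestral frequency and new
    per-SNP latent noise, block factors kept); if a SNP still fails after 20
    rounds a warning is emitted and the SNP kept as-is.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_lines, spec.n_snps
    K = spec.n_subpops

    # chromosome / position / block layout
    counts = _chrom_snp_counts(m, spec.n_chromosomes)
    chroms, positions, block_ids = [], [], []
    block_offset = 0
    for c, cnt in enumerate(counts, start=1):
        n_blocks = min(spec.n_blocks_per_chrom, cnt) or 1
        # heterogeneous block sizes (stick-breaking), mirroring the wide
        # block-length spectrum of real LD maps
        wts = rng.exponential(1.0, size=n_blocks)
        sizes = np.maximum(np.round(wts / wts.sum() * cnt).astype(int), 1)
        while sizes.sum() > cnt:
            sizes[np.argmax(sizes)] -= 1
        sizes[np.argmax(sizes)] += cnt - sizes.sum()
        edges = np.concatenate([[0], np.cumsum(sizes)])
        # each block occupies a compact physical segment (<= ~400 kb, the
        # fast-decay regime of diverse inbred panels) separated by
        # recombination gaps that fill the rest of the chromosome
        spans = rng.integers(50_000, 400_000, size=n_blocks)
        total_span = int(spans.sum())
        if total_span > spec.chrom_length_bp:
            spans = np.maximum((spans * spec.chrom_length_bp // (2 * total_span)), 1000)
            total_span = int(spans.sum())
        gaps = rng.dirichlet(np.ones(n_blocks + 1)) * (spec.chrom_length_bp - total_span)
        starts = (np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(spans[:-1])])).astype(int)
        pos = np.empty(cnt, dtype=int)
        bid = np.zeros(cnt, dtype=int)
        for b in range(n_blocks):
            k = sizes[b]
            offs = np.sort(rng.choice(np.arange(spans[b]), size=k, replace=False))
            pos[edges[b]:edges[b + 1]] = starts[b] + 1 + offs
            bid[edges[b]:edges[b + 1]] = block_offset + b
        block_offset += n_blocks
        chroms.append(np.full(cnt, c))
        positions.append(pos)
        block_ids.append(bid)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    block_arr = np.concatenate(block_ids)
    n_blocks_total = block_offset

    # population structure: balanced primary subpop + Dirichlet admixture
    subpop = np.arange(n) % K
    if K > 1 and spec.admixture > 0:
        conc = 30.0
        alpha = np.full((n, K), conc * spec.admixture / max(K - 1, 1))
        alpha[np.arange(n), subpop] = conc * (1.0 - spec.admixture)
        q = np.vstack([rng.dirichlet(a) for a in alpha])
    else:
        q = np.zeros((n, K))
        q[np.arange(n), subpop] = 1.0

    # per line x block: ancestry draw and latent block factor
    anc = np.empty((n, n_blocks_total), dtype=int)
    cum_q = np.cumsum(q, axis=1)
    u = rng.random((n, n_blocks_total))
    for i in range(n):
        anc[i] = np.searchsorted(cum_q[i], u[i])
    z_block = rng.standard_normal((n, n_blocks_total))

    freqs = _draw_subpop_freqs(rng, m, K, spec.fst, spec.maf_range[0])
    c = spec.within_block_corr
    sc, se = np.sqrt(c), np.sqrt(1.0 - c)

    def realize(cols: np.ndarray) -> np.ndarray:
        """Draw dosages for the given SNP columns given current freqs."""
        eps = rng.standard_normal((n, len(cols)))
        z = sc * z_block[:, block_arr[cols]] + se * eps
        thresh = sstats.norm.ppf(freqs[:, cols])  # (K, len(cols))
        line_thresh = thresh[anc[:, block_arr[cols]], np.arange(len(cols))[None, :]]
        return np.where(z < line_thresh, 2.0, 0.0)

    all_cols = np.arange(m)
    dosages = np.empty((n, m))
    dosages[:, all_cols] = realize(all_cols)

    lo, hi = spec.maf_range
    for _round in range(20):
        p = dosages.mean(axis=0) / 2.0
        maf = np.minimum(p, 1 - p)
        bad = np.where((maf < lo) | (maf > hi))[0]
        if bad.size == 0:
            break
        freqs[:, bad] = _draw_subpop_freqs(rng, bad.size, K, spec.fst, lo)
        dosages[:, bad] = realize(bad)
    else:
        warnings.warn(
            f"{bad.size} SNPs still outside the requested MAF range after resampling",
            stacklevel=2,
        )

    snps = pd.DataFrame({
        "chrom": [str(c) for c in chrom_arr],
        "pos": pos_arr,
        "id": [f"snp_{c}_{p}" for c, p in zip(chrom_arr, pos_arr)],
        "ref": "A",
        "alt": "T",
        "block": block_arr,
    })
    lines = [f"L{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, lines=lines, snps=snps, subpop=subpop)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _effect_draw(rng: np.random.Generator, corr: np.ndarray, size: int) -> np.ndarray:
    """Correlated standard-normal effects, (size, T); exact at corr = 1."""
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    L = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((size, corr.shape[0])) @ L.T


def simulate_phenotypes(geno: GenotypeMatrix, arch: TraitArchitecture,
                        seed: int) -> RawPhenotypeTable:
    """Simulate multi-environment phenotypes on top of a genotype matrix.

    Genetic values come from additive causal effects (shared regions draw
    correlated effects across their traits); the genotype-by-environment and
    residual components are scaled so the expected broad-sense heritability
    H2 = V_g / (V_g + V_ge/L + V_e/(R*L)) equals each trait's target.  The
    returned table carries a ``truth`` ledger with causal SNPs, effects,
    variance components and the realized genetic-correlation matrix.
    """
    rng = np.random.default_rng(seed)
    n, m = geno.n_lines, geno.n_snps
    traits = arch.trait_names
    L, R = arch.n_envs, arch.n_reps

    shared_cols = {t: [] for t in traits}
    shared_effects = {t: [] for t in traits}
    shared_vs = {t: [] for t in traits}
    used = set()
    for region in arch.shared_regions:
        if np.any(region.snp_indices >= m):
            raise ParameterError("shared region references SNPs outside the genotype matrix")
        eff = _effect_draw(rng, region.effect_corr, len(region.snp_indices))
        for j, t in enumerate(region.traits):
            shared_cols[t].append(region.snp_indices)
            shared_effects[t].append(eff[:, j])
            shared_vs[t].append(region.var_share)
        used.update(region.snp_indices.tolist())

    free = np.setdiff1d(np.arange(m), np.fromiter(used, dtype=int, count=len(used)))
    # causal effects act on the standardized genotype (equal expected variance
    # per causal SNP regardless of MAF — the GCTA/LDSC architecture)
    X = geno.dosages - geno.dosages.mean(axis=0)
    sd_x = X.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    X = X / sd_x

    g = {}
    truth_traits = {}
    for t in traits:
        cols_shared = np.concatenate(shared_cols[t]) if shared_cols[t] else np.empty(0, int)
        n_private = arch.causal_count(t) - cols_shared.size
        if n_private < 0:
            raise ParameterError(f"trait {t}: shared regions exceed n_causal")
        cols_private = rng.choice(free, size=min(n_private, free.size), replace=False)
        beta_private = rng.standard_normal(cols_private.size)

        # scale each shared region to its requested share of genetic variance
        vs = shared_vs[t]
        region_effs = shared_effects[t]
        if any(v is not None for v in vs):
            if any(v is None for v in vs):
                raise ParameterError(
                    f"trait {t}: set var_share on all shared regions or none")
            total_vs = sum(vs)
            if total_vs > 1.0:
                raise ParameterError(f"trait {t}: var_share sums to {total_vs} > 1")
            scaled = []
            for region_cols, eff, v in zip(shared_cols[t], region_effs, vs):
                part = X[:, region_cols] @ eff
                sd_part = part.std(ddof=1)
                if sd_part <= 0:
                    raise ParameterError(f"trait {t}: degenerate shared region")
                scaled.append(eff * (np.sqrt(v) / sd_part))
            region_effs = scaled
            if cols_private.size:
                part = X[:, cols_private] @ beta_private
                sd_part = part.std(ddof=1)
                remainder = max(1.0 - total_vs, 0.0)
                beta_private = beta_private * (np.sqrt(remainder) / sd_part
                                               if sd_part > 0 else 0.0)

        cols = np.concatenate([cols_shared, cols_private])
        beta = np.concatenate(
            [np.concatenate(region_effs) if region_effs else np.empty(0),
             beta_private])
        gv = X[:, cols] @ beta
        sd = gv.std(ddof=1)
        if sd <= 0:
            raise ParameterError(f"trait {t}: degenerate genetic value (no causal variance)")
        beta = beta / sd
        gv = gv / sd  # realized V_g = 1
        g[t] = gv
        h2 = arch.h2(t)
        _, V_ge, V_e = arch.variance_components(t)
        truth_traits[t] = {
            "causal_ids": geno.snps["id"].iloc[cols].tolist(),
            "causal_index": cols.tolist(),
            "beta": (beta / sd_x[cols]).tolist(),  # per dosage unit
            "beta_std": beta.tolist(),  # per standardized genotype
            "V_g": 1.0,
            "V_ge": V_ge,
            "V_e": V_e,
            "h2_target": h2,
            "genetic_value": gv.tolist(),
            "category": (arch.categories or {}).get(t),
        }

    env_names = [f"E{e + 1}" for e in range(L)]
    env_eff = rng.normal(0.0, 0.5, size=L)
    records = []
    for t in traits:
        V_ge, V_e = truth_traits[t]["V_ge"], truth_traits[t]["V_e"]
        gxe = rng.normal(0.0, np.sqrt(V_ge), size=(n, L)) if V_ge > 0 else np.zeros((n, L))
        for e, env in enumerate(env_names):
            base = 10.0 + env_eff[e] + g[t] + gxe[:, e]
            for r in range(1, R + 1):
                eps = rng.normal(0.0, np.sqrt(V_e), size=n) if V_e > 0 else 0.0
                vals = base + eps
                records.append(pd.DataFrame({
                    "line": geno.lines, "env": env, "rep": r, "trait": t, "value": vals,
                }))
    data = pd.concat(records, ignore_index=True)

    G = np.column_stack([g[t] for t in traits])
    if len(traits) > 1:
        r_g_true = np.corrcoef(G, rowvar=False)
    else:
        r_g_true = np.ones((1, 1))
    truth = {
        "traits": truth_traits,
        "trait_names": traits,
        "r_g_true": r_g_true.tolist(),
        "n_envs": L,
        "n_reps": R,
        "gxe_fraction": arch.gxe_fraction,
    }
    return RawPhenotypeTable(data=data, truth=truth)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(spec: PanelSpec, n_genes: int, seed: int) -> pd.DataFrame:
    """Tile non-overlapping gene intervals over the panel's chromosomes.

    Returns a gene table (gene_id, chrom, start, end, strand) with 1-based
    closed coordinates; IDs are stable functions of chromosome and slot.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _chrom_snp_counts(n_genes, spec.n_chromosomes)
    rows = []
    for c, cnt in enumerate(counts, start=1):
        if cnt == 0:
            continue
        slot = spec.chrom_length_bp // cnt
        if slot < 3000:
            raise ParameterError(
                f"{cnt} genes do not fit on a {spec.chrom_length_bp} bp chromosome")
        for j in range(cnt):
            length = int(rng.integers(2000, min(5000, slot - 500)))
            start = j * slot + int(rng.integers(1, slot - length - 1))
            rows.append({
                "gene_id": f"gene_{c:02d}_{j + 1:04d}",
                "chrom": str(c),
                "start": start + 1,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(pairs: Sequence[tuple[str, str]], n_tissues: int = 12,
                        target_corr: float | Sequence[float] = 0.9,
                        seed: int = 0, stage: str = "flare_opening") -> "pd.DataFrame":
    """Simulate a genes x tissues relative-expression matrix.

    Each designated gene pair has expected Pearson correlation ~target_corr
    across tissues (a scalar applies to every pair).  Values are positive on
    the relative-expression scale (latent Gaussian around 10, sd 1).  If the
    implied gene-gene correlation matrix is not positive semi-definite (e.g.
    conflicting constraints through shared genes) it is projected to the
    nearest PSD matrix with a warning.
    """
    if n_tissues < 3:
        raise ParameterError("n_tissues must be >= 3 for correlation to be defined")
    targets = (list(target_corr) if np.ndim(target_corr) else [float(target_corr)] * len(pairs))
    if len(targets) != len(pairs):
        raise ParameterError("one target correlation required per pair")
    if any(abs(t) > 1 for t in targets):
        raise ParameterError("|target_corr| must be <= 1")

    genes = []
    for a, b in pairs:
        for gname in (a, b):
            if gname not in genes:
                genes.append(gname)
    G = len(genes)
    idx = {gname: i for i, gname in enumerate(genes)}
    corr = np.eye(G)
    for (a, b), t in zip(pairs, targets):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = t

    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        warnings.warn("pair correlation constraints conflict; projecting to nearest PSD",
                      stacklevel=2)
    Lmat = v * np.sqrt(np.clip(w, 0.0, None))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_tissues, G)) @ Lmat.T
    values = 10.0 + z
    df = pd.DataFrame(values.T, index=genes,
                      columns=[f"tissue_{k + 1:02d}" for k in range(n_tissues)])
    df.index.name = "gene"
    df.attrs["stage"] = stage
    return df
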