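"""Shared fixtures: small synthetic panels reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import pleionet as pn


@pytest.fixture(scope="session", autouse=True)
def _quiet():
    warnings.filterwarnings("ignore", category=UserWarning)
    warnings.filterwarnings("ignore", category=RuntimeWarning)
    warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_panel() -> pn.GenotypeMatrix:
    """120 lines x 400 SNPs, 2 chromosomes, mild structure."""
    spec = pn.PanelSpec(n_lines=120, n_snps=400, n_chromosomes=2,
                        chrom_length_bp=20_000_000, n_blocks_per_chrom=12,
                        n_subpops=2, fst=0.1, seed=7)
    return pn.simulate_genotypes(spec)


@pytest.fixture(scope="session")
def structured_panel() -> pn.GenotypeMatrix:
    """500 lines x 1000 SNPs with 4 admixed subpopulations."""
    spec = pn.PanelSpec(n_lines=500, n_snps=1000, n_chromosomes=4,
                        n_blocks_per_chrom=30, n_subpops=4, fst=0.12, seed=21)
    return pn.simulate_genotypes(spec)


@pytest.fixture(scope="session")
def pheno_fixture(structured_panel):
    """Two correlated traits (3 envs x 2 reps) with recorded truth."""
    corr = np.array([[1.0, 0.9], [0.9, 1.0]])
    rng = np.random.default_rng(3)
    shared = rng.choice(structured_panel.n_snps, 60, replace=False)
    arch = pn.TraitArchitecture(
        trait_names=["PH", "EH"], n_causal=60, h2_target=0.8,
        shared_regions=[pn.SharedRegion(snp_indices=shared, traits=["PH", "EH"],
                                        effect_corr=corr)],
        gxe_fraction=0.2, n_envs=3, n_reps=2)
    raw = pn.simulate_phenotypes(structured_panel, arch, seed=4)
    return raw


def line_values_table(geno: pn.GenotypeMatrix, values: np.ndarray,
                      trait: str = "T") -> pn.BLUPTable:
    """Wrap a per-line vector as a BLUP table for direct scanning."""
    s = pd.Series(np.asarray(values, dtype=float), index=geno.lines, name=trait)
    return pn.BLUPTable(values=s.to_frame(), grand_means={trait: float(s.mean())})


def single_env_phenotypes(geno: pn.GenotypeMatrix, arch: pn.TraitArchitecture,
                          seed: int) -> tuple[pn.RawPhenotypeTable, pn.BLUPTable]:
    """Simulate line-level phenotypes (1 env, 1 rep) and expose them directly."""
    raw = pn.simulate_phenotypes(geno, arch, seed=seed)
    piv = raw.data.pivot_table(index="line", columns="trait", values="value")
    piv = piv.reindex(geno.lines)
    blup = pn.BLUPTable(values=piv, grand_means={t: float(piv[t].mean())
                                                 for t in piv.columns})
    return raw, blup
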