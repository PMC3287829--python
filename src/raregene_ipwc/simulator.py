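"""Synthetic mini-exome generator.

Emulates the shape of the GAW17 mini-exome used to benchmark the screen:
697 unrelated individuals, a fixed genotype matrix with a rare-variant-heavy
MAF spectrum (74% of SNPs below 1% MAF), genes of varying SNP counts, and
many phenotype replicates simulated on the fixed genotypes — three
quantitative traits (Q1, Q2, Q4) built additively from causal SNP effects
beta plus Gaussian noise, and a dichotomous Affected status obtained by
liability thresholding so every replicate has exactly 209 cases out of 697.

Genotypes are drawn under Hardy-Weinberg equilibrium independently across
SNPs: no linkage disequilibrium, no haplotype structure, and (by default)
no population substructure. An optional two-subpopulation mode with
Balding-Nichols-diverged allele frequencies reproduces the confounding that
produces consistent false positives in structured samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    GenotypeMatrix,
    PhenotypeReplicateSet,
    SnpRecord,
)

__all__ = [
    "SimulationModel",
    "TruthTable",
    "PlantedClusterFixture",
    "simulate_genotypes",
    "simulate_phenotypes",
    "planted_cluster_fixture",
]

QUANT_TRAITS = ("Q1", "Q2", "Q4")


@dataclass
class SimulationModel:
    """Parameters of the synthetic mini-exome.

    Defaults mirror the benchmark cohort: 697 individuals of whom 209 are
    cases, 3,205 genes averaging ~7.6 SNPs each, 74% rare SNPs, and 200
    phenotype replicates on fixed genotypes.
    """

    n_individuals: int = 697
    n_genes: int = 3205
    snps_per_gene_mean: float = 7.6
    snps_per_gene_dispersion: float = 1.5
    rare_fraction: float = 0.74
    rare_maf_max: float = 0.01
    common_maf_max: float = 0.5
    synonymous_prob: float = 0.5
    #: trait -> {snp_id: beta}; SNPs absent here are noncausal (beta = 0)
    causal_betas: Dict[str, Dict[str, float]] = field(default_factory=dict)
    trait_noise_sd: float = 1.0
    liability_trait: str = "Q1"
    liability_noise_sd: float = 1.0
    case_fraction: float = 209 / 697
    n_replicates: int = 200
    seed: int = 0
    two_subpopulations: bool = False
    fst: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise ValueError("rare_fraction must lie in [0, 1]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        for trait, betas in self.causal_betas.items():
            for snp, beta in betas.items():
                if not math.isfinite(beta):
                    raise ValueError(f"beta for {snp} on {trait} is not finite")


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-SNP betas and per-gene totals.

    ``gene_effects[trait][gene]`` is the gene-wise total effect
    sum_i MAF_i * beta_i over the gene's SNPs (0 for noncausal genes).
    """

    snp_betas: Dict[str, Dict[str, float]]
    gene_effects: Dict[str, Dict[str, float]]
    causal_genes: Dict[str, List[str]]


@dataclass
class PlantedClusterFixture:
    """A single-gene matrix with a known rare-variant carrier set."""

    genotypes: GenotypeMatrix
    gene: str
    rare_snp_id: str
    carrier_indices: np.ndarray


def _draw_column(
    p: float, n: int, rng: np.random.Generator, model: SimulationModel
) -> np.ndarray:
    if model.two_subpopulations:
        # Balding-Nichols divergence of the two subpopulation frequencies
        a = p * (1 - model.fst) / model.fst
        b = (1 - p) * (1 - model.fst) / model.fst
        p1, p2 = rng.beta(a, b, 2)
        half = n // 2
        col = np.concatenate(
            [rng.binomial(2, p1, half), rng.binomial(2, p2, n - half)]
        )
    else:
        col = rng.binomial(2, p, n)
    return col.astype(np.int8)


def simulate_genotypes(
    model: SimulationModel, rng: Optional[np.random.Generator] = None
) -> GenotypeMatrix:
    """Draw the fixed genotype matrix with gene and synonymy annotation.

    Gene SNP counts are 1 + negative binomial (overdispersed, mean
    ``snps_per_gene_mean``); each SNP's MAF comes from the rare/common
    mixture (rare: log-uniform on [1/(2n), 1%), populating the very-rare
    tail below 0.5%; common: uniform on [1%, 50%]) and genotypes are HWE
    draws at that MAF. Columns are redrawn when monomorphic or when the
    realized sample MAF falls on the wrong side of the rare/common
    boundary — the spectrum's rare fraction describes observed
    frequencies — and dropped if persistently monomorphic. Dosages are
    folded to count the sample minor allele; each record's ``maf`` is the
    sample MAF.
    """
    if model.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    n = model.n_individuals

    extra_mean = max(model.snps_per_gene_mean - 1.0, 0.0)
    r = model.snps_per_gene_dispersion
    if extra_mean > 0:
        sizes = 1 + rng.negative_binomial(r, r / (r + extra_mean), model.n_genes)
    else:
        sizes = np.ones(model.n_genes, dtype=int)
    n_snps = int(sizes.sum())
    lo = 1.0 / (2.0 * n)
    rare_flags = rng.random(n_snps) < model.rare_fraction
    mafs = np.empty(n_snps)
    n_rare = int(rare_flags.sum())
    mafs[rare_flags] = np.exp(
        rng.uniform(np.log(lo), np.log(model.rare_maf_max), n_rare)
    )
    mafs[~rare_flags] = rng.uniform(
        model.rare_maf_max, model.common_maf_max, n_snps - n_rare
    )

    def acceptable(col: np.ndarray, rare: bool) -> bool:
        # polymorphic, and the realized sample MAF on the drawn side of the
        # rare/common boundary: the MAF-spectrum mixture describes observed
        # frequencies, which sampling at 2n alleles would otherwise blur
        if not col.any() or (col == 2).all():
            return False
        freq = col.sum() / (2.0 * n)
        freq = min(freq, 1.0 - freq)
        return freq < model.rare_maf_max if rare else freq >= model.rare_maf_max

    columns: List[np.ndarray] = []
    snps: List[SnpRecord] = []
    snp_idx = 0
    for g, size in enumerate(sizes):
        gene = f"G{g + 1:04d}"
        chrom = str(g % 22 + 1)
        for s in range(size):
            p = mafs[snp_idx]
            rare = bool(rare_flags[snp_idx])
            snp_idx += 1
            col = _draw_column(p, n, rng, model)
            ok = acceptable(col, rare)
            for _ in range(30):
                if ok:
                    break
                col = _draw_column(p, n, rng, model)
                ok = acceptable(col, rare)
            if not ok:
                if not col.any() or (col == 2).all():
                    continue  # persistently monomorphic: drop the SNP
                # polymorphic but persistently on the wrong side: keep it
            freq = col.sum() / (2.0 * n)
            if freq > 0.5:
                col = (2 - col).astype(np.int8)
            columns.append(col)
            snps.append(
                SnpRecord(
                    snp_id=f"{gene}_S{s + 1}",
                    gene=gene,
                    chromosome=chrom,
                    synonymous=bool(rng.random() < model.synonymous_prob),
                )
            )
    dosages = np.stack(columns, axis=1)
    ids = [f"I{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, snps)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    model: SimulationModel,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PhenotypeReplicateSet, TruthTable]:
    """Simulate replicated phenotypes on the fixed genotypes.

    Each quantitative trait is sum_i beta_i * dosage_i plus N(0, sd) noise,
    redrawn per replicate. Affected status thresholds a liability (the
    designated quantitative trait plus extra noise) at its
    (1 - case_fraction) sample quantile, so every replicate has exactly
    round(case_fraction * n) cases.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([int(model.seed), 1])
    )
    n = genotypes.n_individuals
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}

    genetic: Dict[str, np.ndarray] = {}
    for trait in QUANT_TRAITS:
        value = np.zeros(n)
        for snp_id, beta in model.causal_betas.get(trait, {}).items():
            if snp_id not in snp_pos:
                raise ValueError(f"causal SNP {snp_id!r} not in genotypes")
            value += beta * genotypes.dosages[:, snp_pos[snp_id]]
        genetic[trait] = value

    n_cases = int(round(model.case_fraction * n))
    reps: List[pd.DataFrame] = []
    for _ in range(model.n_replicates):
        data = {
            trait: genetic[trait] + rng.normal(0.0, model.trait_noise_sd, n)
            for trait in QUANT_TRAITS
        }
        liability = data[model.liability_trait] + rng.normal(
            0.0, model.liability_noise_sd, n
        )
        affected = np.zeros(n, dtype=int)
        affected[np.argsort(liability)[n - n_cases:]] = 1
        data["Affected"] = affected
        reps.append(
            pd.DataFrame(data, index=pd.Index(genotypes.individual_ids))
        )

    truth = build_truth_table(genotypes, model)
    return PhenotypeReplicateSet(reps), truth


def build_truth_table(genotypes: GenotypeMatrix, model: SimulationModel) -> TruthTable:
    """Gene-wise total effects sum_i MAF_i * beta_i from the causal map."""
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    mafs = genotypes.mafs()
    gene_effects: Dict[str, Dict[str, float]] = {}
    causal_genes: Dict[str, List[str]] = {}
    genes = sorted({s.gene for s in genotypes.snps if s.gene})
    for trait in QUANT_TRAITS:
        betas = model.causal_betas.get(trait, {})
        effects = {g: 0.0 for g in genes}
        for snp_id, beta in betas.items():
            if snp_id not in snp_pos:
                raise ValueError(f"causal SNP {snp_id!r} not in genotypes")
            idx = snp_pos[snp_id]
            gene = genotypes.snps[idx].gene
            effects[gene] = effects.get(gene, 0.0) + float(mafs[idx]) * beta
        gene_effects[trait] = effects
        causal_genes[trait] = sorted(g for g, e in effects.items() if e != 0.0)
    return TruthTable(
        snp_betas=dict(model.causal_betas),
        gene_effects=gene_effects,
        causal_genes=causal_genes,
    )


def planted_cluster_fixture(
    n_carriers: int,
    n_individuals: int = 697,
    n_background_snps: int = 3,
    background_mafs: Sequence[float] = (0.2, 0.3, 0.4),
    seed: int = 0,
) -> PlantedClusterFixture:
    """One gene with one rare SNP carried by a designated individual set.

    The rare SNP's carriers are heterozygous; the remaining SNPs are common
    background noise, mimicking a gene where one low-frequency variant
    (MAF ~ 1.5% for 20 carriers of 697) defines a coherent carrier group
    that the rare-variant-overweighting similarity should isolate into a
    single partition element.
    """
    if n_carriers == 0:
        raise ValueError("need at least 1 carrier")
    if n_carriers >= n_individuals:
        raise ValueError("carriers must be a strict subset of individuals")
    rng = np.random.default_rng(seed)
    carriers = np.sort(
        rng.choice(n_individuals, size=n_carriers, replace=False)
    )
    gene = "PLANTED"
    cols = [np.zeros(n_individuals, dtype=np.int8)]
    cols[0][carriers] = 1
    snps = [SnpRecord(snp_id=f"{gene}_RARE", gene=gene, chromosome="13",
                      synonymous=False)]
    for b in range(n_background_snps):
        p = background_mafs[b % len(background_mafs)]
        col = rng.binomial(2, p, n_individuals).astype(np.int8)
        if col.sum() > n_individuals:
            col = (2 - col).astype(np.int8)
        if not col.any() or (col == 2).all():
            col[rng.integers(n_individuals)] = 1
        cols.append(col)
        snps.append(
            SnpRecord(snp_id=f"{gene}_BG{b + 1}", gene=gene, chromosome="13",
                      synonymous=False)
        )
    ids = [f"I{i + 1:04d}" for i in range(n_individuals)]
    genotypes = GenotypeMatrix(np.stack(cols, axis=1), ids, snps)
    return PlantedClusterFixture(
        genotypes=genotypes,
        gene=gene,
        rare_snp_id=f"{gene}_RARE",
        carrier_indices=carriers,
    )
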